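"""Shared per-cohort precomputation for the extraction algorithms.

Building an :class:`ExtractionContext` once amortizes the work that every
drug--lab pair needs: min-max-scaled measurements indexed by lab, first
exposure dates indexed by drug, and per-visit demographics for matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr_model import Cohort
from .preprocess import minmax_scale_labs

__all__ = ["ExtractionContext"]


class ExtractionContext:
    """Indexed, scaled view of a cohort for fast per-pair extraction."""

    def __init__(self, cohort: Cohort):
        if "scaled_value" not in cohort.measurement.columns:
            cohort = minmax_scale_labs(cohort)
        self.cohort = cohort

        v = cohort.visit.merge(cohort.person, on="person_id", how="left")
        v = v.copy()
        v["admission_year"] = v["admit_date"].dt.year
        v["age"] = v["admission_year"] - v["birth_year"]
        self.visits = v.set_index("visit_id", drop=False)

        fe = cohort.first_exposures()
        self._fe_by_drug = {
            drug: g[["visit_id", "first_date"]].reset_index(drop=True)
            for drug, g in fe.groupby("drug_code")
        }
        self._meas_by_lab = {
            lab: g.reset_index(drop=True)
            for lab, g in cohort.measurement.groupby("lab_code")
        }
        self._daily_counts: dict[str, pd.DataFrame] = {}

    # -- lookups -------------------------------------------------------------
    def first_exposure(self, drug_code: str) -> pd.DataFrame:
        """(visit_id, first_date) for visits exposed to the drug."""
        if drug_code in self._fe_by_drug:
            return self._fe_by_drug[drug_code]
        return pd.DataFrame({"visit_id": pd.Series(dtype=object),
                             "first_date": pd.Series(dtype="datetime64[ns]")})

    def measurements(self, lab_code: str) -> pd.DataFrame:
        """All measurement rows of one lab (with scaled_value)."""
        if lab_code in self._meas_by_lab:
            return self._meas_by_lab[lab_code]
        return self.cohort.measurement.iloc[0:0]

    def visits_measuring(self, lab_code: str) -> np.ndarray:
        return self.measurements(lab_code)["visit_id"].unique()

    def exposed_visits(self, drug_code: str) -> np.ndarray:
        return self.first_exposure(drug_code)["visit_id"].to_numpy()

    def daily_prescriptions(self, drug_code: str) -> pd.DataFrame:
        """(visit_id, date) prescription-day rows for one drug."""
        if drug_code not in self._daily_counts:
            de = self.cohort.drug_exposure
            self._daily_counts[drug_code] = de.loc[
                de["drug_code"] == drug_code, ["visit_id", "date"]
            ].reset_index(drop=True)
        return self._daily_counts[drug_code]
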