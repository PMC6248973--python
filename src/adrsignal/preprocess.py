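"""Lab-value preprocessing shared by the extraction algorithms."""

from __future__ import annotations

import warnings

from .ehr_model import Cohort

__all__ = ["minmax_scale_labs"]


def minmax_scale_labs(cohort: Cohort) -> Cohort:
    """Min-max scale lab values per lab_code over the whole dataset.

    Adds a ``scaled_value`` column to ``measurement``:
    ``(value - min) / (max - min)`` within each lab_code, so descriptive
    statistics of different tests share a common [0, 1] scale. A lab whose
    values are all identical maps to 0.5 (with a warning). Raw values and
    normal ranges are kept untouched for abnormality flags.
    """
    meas = cohort.measurement.copy()
    if len(meas) == 0:
        meas["scaled_value"] = []
    else:
        grp = meas.groupby("lab_code")["value"]
        lo = grp.transform("min")
        hi = grp.transform("max")
        span = hi - lo
        degenerate = span == 0
        if degenerate.any():
            labs = sorted(meas.loc[degenerate, "lab_code"].unique())
            warnings.warn(
                f"constant lab value(s) for {labs}; scaled to 0.5", stacklevel=2
            )
        scaled = (meas["value"] - lo) / span.where(~degenerate)
        meas["scaled_value"] = scaled.fillna(0.5)
    return Cohort(
        person=cohort.person,
        visit=cohort.visit,
        drug_exposure=cohort.drug_exposure,
        measurement=meas,
    )
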