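import numpy as np
import pandas as pd
import pytest

from adrsignal.ehr_model import Cohort, DrugLabEvent
from adrsignal.extraction import ExtractionContext
from adrsignal.synth_ehr import PlantedAdr, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_sim():
    """Small cohort with no planted effects (the null substrate)."""
    cfg = SimConfig(n_patients=800, n_drugs=8, n_labs=6, exposure_prob=0.06, seed=42)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, ExtractionContext(cohort)


@pytest.fixture(scope="session")
def planted_sim():
    """Cohort with one strong planted ADR pair and one indication pair."""
    adr = DrugLabEvent("D0001", "L001", "increased")
    ind = DrugLabEvent("D0002", "L002", "increased")
    cfg = SimConfig(
        n_patients=2000,
        n_drugs=10,
        n_labs=6,
        exposure_prob=0.12,
        planted_adr=[PlantedAdr(adr, effect_size=2.0, onset_lag_days=2)],
        planted_indication=[ind],
        discontinue_prob=0.9,
        seed=7,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, ExtractionContext(cohort), adr, ind


def toy_cohort(
    visits: list[dict],
    measurements: list[dict],
    drug_days: list[dict],
    persons: list[dict] | None = None,
) -> Cohort:
    """Hand-built cohort for unit tests.

    ``visits``: dicts with visit_id, admit, stay (days), optional person
    fields (sex, birth_year). Measurements/drug rows address days as
    offsets from admission.
    """
    base = pd.Timestamp("2012-01-01")
    vrows, prows = [], []
    admit_by_visit = {}
    for v in visits:
        admit = base + pd.Timedelta(days=v.get("admit_offset", 0))
        admit_by_visit[v["visit_id"]] = admit
        pid = v.get("person_id", "p_" + v["visit_id"])
        vrows.append(
            {
                "person_id": pid,
                "visit_id": v["visit_id"],
                "admit_date": admit,
                "discharge_date": admit + pd.Timedelta(days=v["stay"] - 1),
            }
        )
        prows.append(
            {
                "person_id": pid,
                "sex": v.get("sex", "F"),
                "birth_year": v.get("birth_year", 1960),
            }
        )
    mrows = []
    for m in measurements:
        admit = admit_by_visit[m["visit_id"]]
        mrows.append(
            {
                "person_id": "p_" + m["visit_id"],
                "visit_id": m["visit_id"],
                "lab_code": m.get("lab_code", "LAB"),
                "date": admit + pd.Timedelta(days=m["day"]),
                "value": float(m["value"]),
                "normal_low": float(m.get("normal_low", 0.0)),
                "normal_high": float(m.get("normal_high", 10.0)),
            }
        )
    drows = []
    for d in drug_days:
        admit = admit_by_visit[d["visit_id"]]
        drows.append(
            {
                "person_id": "p_" + d["visit_id"],
                "visit_id": d["visit_id"],
                "drug_code": d.get("drug_code", "DRUG"),
                "date": admit + pd.Timedelta(days=d["day"]),
            }
        )
    return Cohort(
        person=pd.DataFrame(prows).drop_duplicates("person_id").reset_index(drop=True),
        visit=pd.DataFrame(vrows),
        drug_exposure=pd.DataFrame(
            drows,
            columns=["person_id", "visit_id", "drug_code", "date"],
        ),
        measurement=pd.DataFrame(
            mrows,
            columns=[
                "person_id",
                "visit_id",
                "lab_code",
                "date",
                "value",
                "normal_low",
                "normal_high",
            ],
        ),
    )
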