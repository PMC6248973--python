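"""Standard synthetic study configurations.

These are the package's reference experiments: a signal-recovery study
with planted ADR pairs, a null (no-effect) calibration study, and a PACE
discrimination study with both ADR (discontinuation) and indication
(intervention) plantings. They pin the simulation conditions used by the
validation suite and the reproduction script so that both exercise the
same cohorts.
"""

from __future__ import annotations

import numpy as np

from .ehr_model import (
    DrugLabEvent,
    ReferencePair,
    build_pair_universe,
    build_reference_dataset,
)
from .synth_ehr import PlantedAdr, SimConfig, drug_code, lab_code, simulate_cohort

__all__ = [
    "recovery_config",
    "null_config",
    "pace_discrimination_config",
    "make_reference",
]


def _spread_pairs(
    n_pairs: int, n_drugs: int, n_labs: int, seed: int, start_drug: int = 0
) -> list[DrugLabEvent]:
    """Deterministically spread planted pairs over distinct drugs."""
    rng = np.random.default_rng(seed)
    if start_drug + n_pairs > n_drugs:
        raise ValueError("need one distinct drug per planted pair")
    pairs = []
    for i in range(n_pairs):
        drug = drug_code(start_drug + i)
        lab = lab_code(int(rng.integers(n_labs)))
        direction = "increased" if rng.random() < 0.5 else "decreased"
        pairs.append(DrugLabEvent(drug, lab, direction))
    return pairs


def recovery_config(
    seed: int,
    n_patients: int = 2500,
    n_drugs: int = 60,
    n_labs: int = 10,
    n_planted: int = 30,
    effect_size: float = 1.0,
    onset_lag_days: int = 3,
    exposure_prob: float = 0.05,
    discontinue_prob: float = 0.5,
) -> SimConfig:
    """Signal-recovery study: planted 1-SD ADR shifts with discontinuation
    prescribing, ~125 exposed visits per drug at the default sizes.

    The default withdrawal propensity of 0.5 models the realistic case
    where the attending cancels the suspect drug after an abnormal result
    about half the time, so the prescribing-pattern detector is informative
    but not an oracle for the planted pairs.
    """
    planted = [
        PlantedAdr(p, effect_size=effect_size, onset_lag_days=onset_lag_days)
        for p in _spread_pairs(n_planted, n_drugs, n_labs, seed)
    ]
    return SimConfig(
        n_patients=n_patients,
        n_drugs=n_drugs,
        n_labs=n_labs,
        planted_adr=planted,
        discontinue_prob=discontinue_prob,
        exposure_prob=exposure_prob,
        seed=seed,
    )


def null_config(
    seed: int,
    n_patients: int = 1500,
    n_drugs: int = 50,
    n_labs: int = 10,
    exposure_prob: float = 0.04,
) -> SimConfig:
    """Calibration study: no planted effects anywhere.

    The full directional pair grid (n_drugs x n_labs x 2) provides the
    test-level replicates for type-I-error estimation.
    """
    return SimConfig(
        n_patients=n_patients,
        n_drugs=n_drugs,
        n_labs=n_labs,
        exposure_prob=exposure_prob,
        seed=seed,
    )


def pace_discrimination_config(
    seed: int,
    n_patients: int = 2000,
    n_adr: int = 15,
    n_indication: int = 15,
    n_labs: int = 10,
    effect_size: float = 1.0,
    exposure_prob: float = 0.06,
) -> SimConfig:
    """PACE study: ADR pairs (discontinuation) vs indication pairs
    (intervention), on disjoint drugs."""
    n_drugs = n_adr + n_indication
    adr = [
        PlantedAdr(p, effect_size=effect_size, onset_lag_days=3)
        for p in _spread_pairs(n_adr, n_drugs, n_labs, seed)
    ]
    indication = _spread_pairs(n_indication, n_drugs, n_labs, seed + 1, start_drug=n_adr)
    return SimConfig(
        n_patients=n_patients,
        n_drugs=n_drugs,
        n_labs=n_labs,
        planted_adr=adr,
        planted_indication=indication,
        discontinue_prob=0.9,
        exposure_prob=exposure_prob,
        seed=seed,
    )


def make_reference(
    config: SimConfig, seed: int, neg_ratio: float = 2.0, min_records: int = 5
):
    """Simulate a cohort and build its labeled reference dataset.

    Positives are the planted ADR pairs; nonpositives are sampled from the
    full directional pair universe at ``neg_ratio`` : 1 before the
    >= ``min_records``-record filter. Returns (cohort, reference list).
    """
    cohort, truth = simulate_cohort(config)
    drugs = [drug_code(i) for i in range(config.n_drugs)]
    lab_events = [
        (lab_code(i), d) for i in range(config.n_labs) for d in ("increased", "decreased")
    ]
    universe = build_pair_universe(drugs, lab_events)
    reference = build_reference_dataset(
        universe,
        [rp.pair for rp in truth],
        cohort=cohort,
        min_records=min_records,
        neg_ratio=neg_ratio,
        seed=seed,
    )
    return cohort, reference
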