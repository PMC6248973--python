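"""Synthetic inpatient EHR generator with planted drug effects.

Emulates the substrate the signal-detection algorithms consume: hospital
stays (geometric lengths, mean 8.6 days), daily drug prescriptions, daily
laboratory results drawn from per-lab Gaussian baselines with normal
ranges, and three kinds of drug--lab dependence:

* **planted ADR pairs** -- from ``onset_lag_days`` after first exposure the
  lab shifts by ``effect_size`` baseline SDs in the event direction; with
  probability ``discontinue_prob`` the attending cancels the drug on the
  day of the first abnormal post-exposure result (discontinuation
  prescribing pattern);
* **planted indication pairs** -- an abnormal lab result precedes and
  triggers the prescription (intervention pattern, the classic confounding-
  by-indication fixture);
* **all other pairs** -- no exposure--lab dependence (the null).

Output is byte-identical under a fixed seed and satisfies every invariant
the data model enforces (dates within visits, finite values, valid ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_model import (
    Cohort,
    DrugLabEvent,
    ReferencePair,
    write_ehr,
    write_reference_pairs,
)

__all__ = ["LabBaseline", "PlantedAdr", "SimConfig", "simulate_cohort", "simulate_to_dir"]


@dataclass(frozen=True)
class LabBaseline:
    """Gaussian baseline for one laboratory test."""

    mean: float
    sd: float
    normal_low: float
    normal_high: float

    def __post_init__(self) -> None:
        if not self.normal_low < self.normal_high:
            raise ValueError("normal_low must be < normal_high")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class PlantedAdr:
    """A drug--lab-event pair with a causal post-exposure shift.

    ``effect_size`` is in units of the lab's baseline SD; ``onset_lag_days``
    is the delay from first exposure to the shift (default 3, so that the
    PACE pre-event window falls entirely inside the exposure episode).
    """

    pair: DrugLabEvent
    effect_size: float = 1.0
    onset_lag_days: int = 3

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.onset_lag_days < 0:
            raise ValueError("onset_lag_days must be >= 0")


def default_baselines(n_labs: int) -> dict[str, LabBaseline]:
    """Deterministic per-lab baselines spanning different scales.

    Means cycle through clinically plausible magnitudes (electrolyte-like,
    enzyme-like, count-like scales); SD is 10% of the mean; the normal range
    is mean +/- 2 SD, leaving ~2.3% abnormal tail mass per side at baseline.
    """
    out = {}
    for i in range(n_labs):
        mean = float([4.5, 40.0, 140.0, 250.0, 1.1, 13.5, 95.0, 7.4][i % 8]) * (
            1.0 + 0.1 * (i // 8)
        )
        sd = 0.1 * mean
        out[lab_code(i)] = LabBaseline(mean, sd, mean - 2 * sd, mean + 2 * sd)
    return out


def drug_code(i: int) -> str:
    return f"D{i:04d}"


def lab_code(i: int) -> str:
    return f"L{i:03d}"


@dataclass
class SimConfig:
    n_patients: int = 1000
    n_drugs: int = 20
    n_labs: int = 10
    mean_stay_days: float = 8.6
    lab_baselines: dict[str, LabBaseline] | None = None
    planted_adr: list[PlantedAdr] = field(default_factory=list)
    planted_indication: list[DrugLabEvent] = field(default_factory=list)
    discontinue_prob: float = 0.5
    labs_per_stay: float | None = None  # mean distinct labs measured per stay; None = all
    exposure_prob: float = 0.05
    seed: int = 0

    def baselines(self) -> dict[str, LabBaseline]:
        if self.lab_baselines is not None:
            return self.lab_baselines
        return default_baselines(self.n_labs)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_drugs < 1 or self.n_labs < 1:
            raise ValueError("n_patients, n_drugs, n_labs must be positive")
        if not (0.0 <= self.exposure_prob <= 1.0 and 0.0 <= self.discontinue_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_stay_days <= 2:
            raise ValueError("mean_stay_days must exceed the 2-day minimum stay")
        adr_pairs = {p.pair for p in self.planted_adr}
        ind_pairs = set(self.planted_indication)
        if adr_pairs & ind_pairs:
            raise ValueError("planted_adr and planted_indication must be disjoint")
        n_planted = len(adr_pairs) + len(ind_pairs)
        if n_planted > self.n_drugs * self.n_labs * 2:
            raise ValueError("more planted pairs than drug x lab-event combinations")
        known = self.baselines().keys()
        for p in adr_pairs | ind_pairs:
            if p.lab_code not in known:
                raise ValueError(f"planted pair references unknown lab {p.lab_code!r}")
        ind_drugs = [p.drug_code for p in self.planted_indication]
        if len(ind_drugs) != len(set(ind_drugs)):
            raise ValueError("a drug may appear in at most one indication pair")
        if {p.drug_code for p in self.planted_indication} & {
            p.pair.drug_code for p in self.planted_adr
        }:
            raise ValueError("a drug cannot be both ADR-planted and indication-planted")


def _stays(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    # geometric with mean mean_stay_days, support >= 2 days
    return 1 + rng.geometric(1.0 / (cfg.mean_stay_days - 1.0), size=cfg.n_patients)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, list[ReferencePair]]:
    """Simulate one cohort (one visit per patient) and its truth labels.

    Returns the in-memory :class:`~adrsignal.ehr_model.Cohort` and the list
    of planted ADR pairs labeled positive.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    baselines = cfg.baselines()
    lab_codes = sorted(baselines)
    drug_codes = [drug_code(i) for i in range(cfg.n_drugs)]
    n_v = cfg.n_patients

    stays = _stays(rng, cfg)
    admit_offsets = rng.integers(0, 5 * 365, size=n_v)
    base_date = np.datetime64("2010-01-01")
    admit = base_date + admit_offsets
    discharge = admit + (stays - 1)
    sex = np.where(rng.random(n_v) < 0.5, "F", "M")
    birth_year = rng.integers(1930, 1996, size=n_v)

    person_ids = np.array([f"P{i:06d}" for i in range(n_v)])
    visit_ids = np.array([f"V{i:06d}" for i in range(n_v)])

    # which labs each visit measures (daily, for the whole stay)
    if cfg.labs_per_stay is None:
        measured = np.ones((n_v, len(lab_codes)), dtype=bool)
    else:
        p_lab = min(1.0, cfg.labs_per_stay / len(lab_codes))
        measured = rng.random((n_v, len(lab_codes))) < p_lab

    # exposure and episode start (day offset within the stay)
    exposed = rng.random((n_v, cfg.n_drugs)) < cfg.exposure_prob
    start_u = rng.random((n_v, cfg.n_drugs))
    # regular drugs start uniformly in [1, stay-1]: a nonempty pre window exists
    start = 1 + np.floor(start_u * (stays - 1)[:, None]).astype(int)

    ind_by_drug = {p.drug_code: p for p in cfg.planted_indication}
    ind_event_u = rng.random((n_v, len(cfg.planted_indication)))
    ind_event_day = {}
    for j, p in enumerate(cfg.planted_indication):
        di = drug_codes.index(p.drug_code)
        # event precedes / coincides with drug start (intervention pattern)
        e = np.floor(ind_event_u[:, j] * np.maximum(stays - 2, 1)).astype(int)
        ind_event_day[p.drug_code] = e
        start[:, di] = e  # prescriptions begin on the event day

    # ---- laboratory values (long form) -------------------------------------
    lab_idx = {c: i for i, c in enumerate(lab_codes)}
    n_meas_labs = measured.sum(axis=1)
    rows_per_visit = n_meas_labs * stays
    visit_rep = np.repeat(np.arange(n_v), rows_per_visit)

    lab_col_parts, day_parts = [], []
    for v in range(n_v):
        labs_v = np.flatnonzero(measured[v])
        lab_col_parts.append(np.repeat(labs_v, stays[v]))
        day_parts.append(np.tile(np.arange(stays[v]), len(labs_v)))
    lab_col = np.concatenate(lab_col_parts) if lab_col_parts else np.array([], dtype=int)
    day = np.concatenate(day_parts) if day_parts else np.array([], dtype=int)

    means = np.array([baselines[c].mean for c in lab_codes])
    sds = np.array([baselines[c].sd for c in lab_codes])
    values = rng.normal(means[lab_col], sds[lab_col])

    # planted ADR step shift from onset_lag_days after first exposure
    for p in cfg.planted_adr:
        di = drug_codes.index(p.pair.drug_code)
        li = lab_idx[p.pair.lab_code]
        onset = start[:, di] + p.onset_lag_days
        mask = (
            (lab_col == li)
            & exposed[visit_rep, di]
            & (day >= onset[visit_rep])
        )
        shift = p.effect_size * sds[li]
        values[mask] += shift if p.pair.direction == "increased" else -shift

    # planted indication: the abnormal result that triggers prescribing
    for p in cfg.planted_indication:
        di = drug_codes.index(p.drug_code)
        li = lab_idx[p.lab_code]
        e = ind_event_day[p.drug_code]
        bl = baselines[p.lab_code]
        mask = (
            (lab_col == li)
            & exposed[visit_rep, di]
            & (day >= e[visit_rep])
            & (day <= e[visit_rep] + 1)
        )
        values[mask] = (
            bl.normal_high + 1.5 * bl.sd
            if p.direction == "increased"
            else bl.normal_low - 1.5 * bl.sd
        )

    # keep values in a plausible physiologic band
    lo_clip = means[lab_col] - 5 * sds[lab_col]
    hi_clip = means[lab_col] + 5 * sds[lab_col]
    values = np.clip(values, lo_clip, hi_clip)

    # ---- event-triggered discontinuation ------------------------------------
    # cease the drug's prescriptions the day after the first abnormal result
    # observed at/after exposure start (cause-blind: the attending reacts to
    # the abnormal value, whatever produced it)
    stop_day = np.full((n_v, cfg.n_drugs), np.iinfo(np.int64).max)
    for p in cfg.planted_adr:
        di = drug_codes.index(p.pair.drug_code)
        li = lab_idx[p.pair.lab_code]
        bl = baselines[p.pair.lab_code]
        abnormal = (
            values > bl.normal_high if p.pair.direction == "increased" else values < bl.normal_low
        )
        mask = (
            (lab_col == li)
            & exposed[visit_rep, di]
            & (day >= start[visit_rep, di])
            & abnormal
        )
        first_abn = np.full(n_v, np.iinfo(np.int64).max)
        np.minimum.at(first_abn, visit_rep[mask], day[mask])
        has_event = first_abn < np.iinfo(np.int64).max
        stop = rng.random(n_v) < cfg.discontinue_prob
        hit = has_event & stop & exposed[:, di]
        # same-day cancellation: the abnormal result comes back and the order
        # stops, so the event day itself is the first unprescribed day (but
        # the episode keeps at least its first day)
        cease = np.maximum(first_abn[hit], start[hit, di] + 1)
        stop_day[hit, di] = np.minimum(stop_day[hit, di], cease)

    # ---- drug exposure records (daily) --------------------------------------
    vis_list, drug_list, day_list = [], [], []
    for di in range(cfg.n_drugs):
        vs = np.flatnonzero(exposed[:, di])
        for v in vs:
            last = min(stays[v] - 1, stop_day[v, di] - 1)
            if last < start[v, di]:
                continue
            days_v = np.arange(start[v, di], last + 1)
            vis_list.append(np.full(len(days_v), v))
            drug_list.append(np.full(len(days_v), di))
            day_list.append(days_v)
    if vis_list:
        dv = np.concatenate(vis_list)
        dd = np.concatenate(drug_list)
        dday = np.concatenate(day_list)
    else:
        dv = dd = dday = np.array([], dtype=int)

    person = pd.DataFrame(
        {"person_id": person_ids, "sex": sex, "birth_year": birth_year}
    )
    visit = pd.DataFrame(
        {
            "person_id": person_ids,
            "visit_id": visit_ids,
            "admit_date": pd.to_datetime(admit),
            "discharge_date": pd.to_datetime(discharge),
        }
    )
    order = np.lexsort((dday, dd, dv))
    drug_exposure = pd.DataFrame(
        {
            "person_id": person_ids[dv[order]],
            "visit_id": visit_ids[dv[order]],
            "drug_code": np.array(drug_codes)[dd[order]],
            "date": pd.to_datetime(admit[dv[order]] + dday[order]),
        }
    )
    lab_code_arr = np.array(lab_codes)
    nl = np.array([baselines[c].normal_low for c in lab_codes])
    nh = np.array([baselines[c].normal_high for c in lab_codes])
    measurement = pd.DataFrame(
        {
            "person_id": person_ids[visit_rep],
            "visit_id": visit_ids[visit_rep],
            "lab_code": lab_code_arr[lab_col],
            "date": pd.to_datetime(admit[visit_rep] + day),
            "value": np.round(values, 6),
            "normal_low": nl[lab_col],
            "normal_high": nh[lab_col],
        }
    )

    cohort = Cohort(
        person=person,
        visit=visit,
        drug_exposure=drug_exposure,
        measurement=measurement,
    )
    truth = [ReferencePair(p.pair, 1) for p in sorted(cfg.planted_adr, key=lambda q: q.pair)]
    return cohort, truth


def simulate_to_dir(config: SimConfig, out_dir: str | Path) -> tuple[Cohort, list[ReferencePair]]:
    """Simulate and write the four cohort CSVs plus ``truth_pairs.csv``."""
    out_dir = Path(out_dir)
    cohort, truth = simulate_cohort(config)
    write_ehr(cohort, out_dir)
    write_reference_pairs(truth, out_dir / "truth_pairs.csv")
    return cohort, truth
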