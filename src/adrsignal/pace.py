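"""PACE: prescription pattern around the clinical event.

For each drug--laboratory-event pair, the event date of a visit is the
first abnormal result of the lab in the event direction. Prescription
counts of the drug are aggregated over all events on relative days -3, -2,
0 and +1 (day -1 is treated as a washout day around the event and enters
neither window). The prescription change index

    PCI = (count(day 0) + count(day +1) + 0.5) / (count(-3) + count(-2) + 0.5)

compares mean daily prescribing after vs before the event, with a 0.5
continuity term guarding empty windows. PCI <= 0.667 (= 1/1.5) is a
discontinuation pattern (the drug is withdrawn after the event -- ADR
behaviour), PCI > 1.500 an intervention pattern (the drug is started in
response to the event -- confounding by indication) and anything between
is maintenance. The signal criterion uses the strict form PCI < 0.667.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehr_model import Cohort, DrugLabEvent
from .extraction import ExtractionContext

__all__ = [
    "PaceResult",
    "event_dates",
    "pace_counts",
    "pci",
    "classify_pattern",
    "pace_signal",
    "pace_features",
    "DISCONTINUATION_CUTOFF",
    "INTERVENTION_CUTOFF",
    "PACE_FEATURE_NAMES",
]

DISCONTINUATION_CUTOFF = 1.0 / 1.5  # = 0.667 as printed
INTERVENTION_CUTOFF = 1.5

#: relative days entering the pre- and post-event windows (day -1 excluded)
PRE_DAYS = (-3, -2)
POST_DAYS = (0, 1)

PACE_FEATURE_NAMES = [
    "pace_n_minus3",
    "pace_n_minus2",
    "pace_n_day0",
    "pace_n_plus1",
    "pace_pci",
]


@dataclass
class PaceResult:
    pair: DrugLabEvent
    n_minus3: int = 0
    n_minus2: int = 0
    n_day0: int = 0
    n_plus1: int = 0
    pci: float = math.nan
    pattern: str | None = None  # discontinuation | maintenance | intervention
    n_events: int = 0

    @property
    def features(self) -> dict[str, float]:
        if self.n_events == 0:
            return {name: math.nan for name in PACE_FEATURE_NAMES}
        return {
            "pace_n_minus3": float(self.n_minus3),
            "pace_n_minus2": float(self.n_minus2),
            "pace_n_day0": float(self.n_day0),
            "pace_n_plus1": float(self.n_plus1),
            "pace_pci": self.pci,
        }


def event_dates(
    pair: DrugLabEvent, cohort: Cohort | ExtractionContext
) -> pd.DataFrame:
    """First abnormal result (event direction) per visit: the event date.

    Returns a frame with columns (visit_id, event_date); visits with no
    abnormal value of the lab contribute no event.
    """
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    meas = ctx.measurements(pair.lab_code)
    if meas.empty:
        return pd.DataFrame(columns=["visit_id", "event_date"])
    abnormal = pair.is_abnormal(meas["value"], meas["normal_low"], meas["normal_high"])
    ab = meas[np.asarray(abnormal)]
    if ab.empty:
        return pd.DataFrame(columns=["visit_id", "event_date"])
    ev = ab.groupby("visit_id", as_index=False)["date"].min()
    return ev.rename(columns={"date": "event_date"})


def pace_counts(
    pair: DrugLabEvent,
    events: pd.DataFrame,
    cohort: Cohort | ExtractionContext,
) -> PaceResult:
    """Aggregate the drug's prescription counts on days -3, -2, 0, +1.

    Counts are summed over all events; a relative day falling outside the
    stay simply has no prescription record and contributes zero.
    """
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    res = PaceResult(pair=pair, n_events=len(events))
    if len(events) == 0:
        return res
    rx = ctx.daily_prescriptions(pair.drug_code)
    if rx.empty:
        return res
    m = rx.merge(events, on="visit_id")
    rel = (m["date"] - m["event_date"]).dt.days
    res.n_minus3 = int((rel == -3).sum())
    res.n_minus2 = int((rel == -2).sum())
    res.n_day0 = int((rel == 0).sum())
    res.n_plus1 = int((rel == 1).sum())
    return res


def classify_pattern(value: float) -> str:
    """Pattern from a PCI value: <= 0.667 discontinuation, > 1.500 intervention."""
    if value <= DISCONTINUATION_CUTOFF:
        return "discontinuation"
    if value > INTERVENTION_CUTOFF:
        return "intervention"
    return "maintenance"


def pci(res: PaceResult) -> PaceResult:
    """Compute the prescription change index and classify the pattern."""
    pre_total = res.n_minus3 + res.n_minus2
    post_total = res.n_day0 + res.n_plus1
    # mean daily post / mean daily pre; the window lengths are equal (2 days)
    # so the day counts cancel, leaving the continuity-corrected totals
    res.pci = (post_total + 0.5) / (pre_total + 0.5)
    res.pattern = classify_pattern(res.pci)
    return res


def pace_signal(res: PaceResult) -> bool:
    """PACE signal: PCI strictly below 0.667.

    Note the published boundary conventions differ: the *pattern* cutoff is
    PCI <= 0.667 while the *signal* criterion is PCI < 0.667; a pair exactly
    at the boundary is a discontinuation pattern but not a signal.
    """
    if math.isnan(res.pci):
        return False
    return res.pci < DISCONTINUATION_CUTOFF


def pace_features(
    pair: DrugLabEvent, cohort: Cohort | ExtractionContext
) -> PaceResult:
    """Full PACE pipeline for one pair: events -> counts -> PCI/pattern."""
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    ev = event_dates(pair, ctx)
    res = pace_counts(pair, ev, ctx)
    if res.n_events:
        pci(res)
    return res
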