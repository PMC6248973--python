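"""CERT: within-patient comparison of extreme lab values before vs after drug exposure.

For each drug--laboratory-event pair, every patient-visit exposed to the
drug contributes one paired observation: the extreme (maximum for
"increased" events, minimum for "decreased") lab value in the pre-exposure
window [admission, first exposure) and in the post-exposure window
[first exposure, discharge]. Pairs of extremes are compared by a paired
t-test (n > 30 or normally distributed differences, Shapiro-Wilk at
alpha = 0.05) or Wilcoxon's signed-rank test, and the change in
normal-range abnormality by McNemar's test (exact binomial when the
discordant total is under 25). Descriptive statistics are computed on
min-max-scaled extremes; abnormality flags use raw values against each
record's normal range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from .ehr_model import Cohort, DrugLabEvent
from .extraction import ExtractionContext

__all__ = [
    "PairedExtremes",
    "CertResult",
    "paired_extremes",
    "cert_features",
    "cert_signal",
    "count_usable_records",
    "descriptive_stats",
    "CERT_FEATURE_NAMES",
]

CERT_FEATURE_NAMES = [
    "cert_pre_mean",
    "cert_pre_median",
    "cert_pre_sd",
    "cert_pre_kurtosis",
    "cert_pre_skewness",
    "cert_pre_n_normal",
    "cert_pre_n_abnormal",
    "cert_post_mean",
    "cert_post_median",
    "cert_post_sd",
    "cert_post_kurtosis",
    "cert_post_skewness",
    "cert_post_n_normal",
    "cert_post_n_abnormal",
    "cert_p_paired",
    "cert_p_mcnemar",
    "cert_abs_pct_change",
    "cert_pct_normal_to_abnormal",
]


@dataclass
class PairedExtremes:
    """Per-patient paired pre/post extremes for one drug--lab-event pair."""

    pair: DrugLabEvent
    pre_scaled: np.ndarray
    post_scaled: np.ndarray
    pre_abnormal: np.ndarray  # bool, raw extreme outside normal range (event direction)
    post_abnormal: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pre_scaled)


@dataclass
class CertResult:
    pair: DrugLabEvent
    n_pairs: int
    features: dict[str, float] = field(default_factory=dict)
    test_used: str | None = None  # "t" | "wilcoxon"
    mcnemar_used: str | None = None  # "asymptotic" | "exact"
    p_paired: float = math.nan
    p_mcnemar: float = math.nan
    p_paired_adj: float = math.nan
    p_mcnemar_adj: float = math.nan


def descriptive_stats(values: np.ndarray, prefix: str) -> dict[str, float]:
    """Mean / median / SD / excess kurtosis / skewness of a sample.

    SD uses ddof=1; skewness is the adjusted Fisher-Pearson sample skewness
    and kurtosis the bias-corrected sample excess kurtosis, so both need
    enough observations (3 and 4 respectively) and a nonzero variance --
    otherwise NaN, which the feature matrix treats as missing.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = {
        f"{prefix}_mean": float(np.mean(values)) if n else math.nan,
        f"{prefix}_median": float(np.median(values)) if n else math.nan,
        f"{prefix}_sd": float(np.std(values, ddof=1)) if n > 1 else math.nan,
        f"{prefix}_kurtosis": math.nan,
        f"{prefix}_skewness": math.nan,
    }
    if n > 3 and np.std(values) > 0:
        out[f"{prefix}_kurtosis"] = float(stats.kurtosis(values, fisher=True, bias=False))
    if n > 2 and np.std(values) > 0:
        out[f"{prefix}_skewness"] = float(stats.skew(values, bias=False))
    return out


def _window_extremes(
    meas: pd.DataFrame, fe: pd.DataFrame, direction: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-visit extreme rows in the pre and post windows.

    Pre window is [admission, first exposure) and post [first exposure,
    discharge]; only visits with data in both windows survive. Ties within
    a day resolve to the more extreme value by construction of the extreme.
    """
    m = meas.merge(fe, on="visit_id", how="inner")
    if m.empty:
        empty = m.iloc[0:0]
        return empty, empty
    pre = m[m["date"] < m["first_date"]]
    post = m[m["date"] >= m["first_date"]]
    idx_fun = "idxmax" if direction == "increased" else "idxmin"
    pre_ix = getattr(pre.groupby("visit_id")["value"], idx_fun)()
    post_ix = getattr(post.groupby("visit_id")["value"], idx_fun)()
    both = pre_ix.index.intersection(post_ix.index)
    return m.loc[pre_ix[both].to_numpy()], m.loc[post_ix[both].to_numpy()]


def paired_extremes(
    pair: DrugLabEvent, cohort: Cohort | ExtractionContext
) -> PairedExtremes:
    """Collect per-patient (pre extreme, post extreme) observations for a pair."""
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    meas = ctx.measurements(pair.lab_code)
    fe = ctx.first_exposure(pair.drug_code)
    pre_rows, post_rows = _window_extremes(meas, fe, pair.direction)
    return PairedExtremes(
        pair=pair,
        pre_scaled=pre_rows["scaled_value"].to_numpy(dtype=float),
        post_scaled=post_rows["scaled_value"].to_numpy(dtype=float),
        pre_abnormal=np.asarray(
            pair.is_abnormal(
                pre_rows["value"], pre_rows["normal_low"], pre_rows["normal_high"]
            )
        ),
        post_abnormal=np.asarray(
            pair.is_abnormal(
                post_rows["value"], post_rows["normal_low"], post_rows["normal_high"]
            )
        ),
    )


def count_usable_records(
    pairs: Iterable[DrugLabEvent], cohort: Cohort | ExtractionContext
) -> dict[DrugLabEvent, int]:
    """Number of patients contributing a usable pre/post extreme pair.

    This is the denominator the paired test uses and the record count the
    reference-dataset >=5-record filter applies.
    """
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    out: dict[DrugLabEvent, int] = {}
    for pair in pairs:
        meas = ctx.measurements(pair.lab_code)
        fe = ctx.first_exposure(pair.drug_code)
        m = meas.merge(fe, on="visit_id", how="inner")
        if m.empty:
            out[pair] = 0
            continue
        pre_visits = set(m.loc[m["date"] < m["first_date"], "visit_id"])
        post_visits = set(m.loc[m["date"] >= m["first_date"], "visit_id"])
        out[pair] = len(pre_visits & post_visits)
    return out


def _paired_test(pre: np.ndarray, post: np.ndarray) -> tuple[float, str]:
    diffs = post - pre
    n = len(diffs)
    if n < 2 or np.allclose(diffs, 0.0):
        return 1.0, "t"
    if n > 30:
        use_t = True
    elif n >= 3:
        use_t = stats.shapiro(diffs).pvalue >= 0.05 if np.ptp(diffs) > 0 else True
    else:
        use_t = True  # too few observations to assess normality
    if use_t:
        p = float(stats.ttest_rel(post, pre).pvalue)
        return (1.0 if math.isnan(p) else p), "t"
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return 1.0, "wilcoxon"
    return float(stats.wilcoxon(nonzero).pvalue), "wilcoxon"


def _mcnemar(pre_abn: np.ndarray, post_abn: np.ndarray) -> tuple[float, str]:
    b = int(np.sum(~pre_abn & post_abn))  # normal -> abnormal
    c = int(np.sum(pre_abn & ~post_abn))  # abnormal -> normal
    n00 = int(np.sum(~pre_abn & ~post_abn))
    n11 = int(np.sum(pre_abn & post_abn))
    exact = (b + c) < 25
    if b + c == 0:
        return 1.0, "exact" if exact else "asymptotic"
    res = sm_mcnemar([[n00, b], [c, n11]], exact=exact, correction=True)
    return float(res.pvalue), "exact" if exact else "asymptotic"


def cert_features(pe: PairedExtremes, bonferroni_m: int = 1) -> CertResult:
    """Compute Table-style CERT features f1-f18 plus raw/adjusted p-values.

    ``bonferroni_m`` is the number of pairs analyzed in the run (the
    multiple-testing family size); adjusted p-values are ``min(1, m * p)``.
    With no paired observations, every feature is NaN (missing).
    """
    res = CertResult(pair=pe.pair, n_pairs=pe.n_pairs)
    if pe.n_pairs == 0:
        res.features = {name: math.nan for name in CERT_FEATURE_NAMES}
        return res

    feats: dict[str, float] = {}
    feats.update(descriptive_stats(pe.pre_scaled, "cert_pre"))
    feats["cert_pre_n_normal"] = float(np.sum(~pe.pre_abnormal))
    feats["cert_pre_n_abnormal"] = float(np.sum(pe.pre_abnormal))
    feats.update(descriptive_stats(pe.post_scaled, "cert_post"))
    feats["cert_post_n_normal"] = float(np.sum(~pe.post_abnormal))
    feats["cert_post_n_abnormal"] = float(np.sum(pe.post_abnormal))

    res.p_paired, res.test_used = _paired_test(pe.pre_scaled, pe.post_scaled)
    res.p_mcnemar, res.mcnemar_used = _mcnemar(pe.pre_abnormal, pe.post_abnormal)
    res.p_paired_adj = min(1.0, bonferroni_m * res.p_paired)
    res.p_mcnemar_adj = min(1.0, bonferroni_m * res.p_mcnemar)
    feats["cert_p_paired"] = res.p_paired
    feats["cert_p_mcnemar"] = res.p_mcnemar

    pre_mean = float(np.mean(pe.pre_scaled))
    post_mean = float(np.mean(pe.post_scaled))
    feats["cert_abs_pct_change"] = (
        abs(post_mean - pre_mean) / abs(pre_mean) * 100.0 if pre_mean != 0 else math.nan
    )
    feats["cert_pct_normal_to_abnormal"] = (
        100.0 * float(np.sum(~pe.pre_abnormal & pe.post_abnormal)) / pe.n_pairs
    )
    res.features = {name: feats[name] for name in CERT_FEATURE_NAMES}
    return res


def cert_signal(res: CertResult, n_threshold: int = 400) -> bool:
    """CERT400 decision: >400 paired patients and an adjusted p below 0.05."""
    if res.n_pairs <= n_threshold:
        return False
    ps = [p for p in (res.p_paired_adj, res.p_mcnemar_adj) if not math.isnan(p)]
    return any(p < 0.05 for p in ps)


def apply_bonferroni(results: Mapping[DrugLabEvent, CertResult]) -> None:
    """Re-adjust p-values across a family of analyzed pairs, in place."""
    m = len(results)
    for res in results.values():
        res.p_paired_adj = min(1.0, m * res.p_paired) if not math.isnan(res.p_paired) else math.nan
        res.p_mcnemar_adj = (
            min(1.0, m * res.p_mcnemar) if not math.isnan(res.p_mcnemar) else math.nan
        )
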