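"""CLEAR: exposed (risk) vs matched non-exposed (control) abnormality comparison.

Each visit exposed to the drug (with at least one post-exposure result of
the lab) anchors a stratum of up to ``k`` non-exposed control visits
matched on sex, age within 5 years, the same lab being measured, and
admission year. Controls receive a pseudo index date at the case's
admission-to-exposure lag (clipped to their stay) so exposed and control
observation windows are aligned in hospital time -- the time-dependent-
covariate correction that motivates the design. The exposure--abnormality
association is estimated by conditional logistic regression on the matched
strata; descriptive features mirror CERT but per group, and the matched
2x2 table feeds Fisher's exact test and the disproportionality measures.

Matching keys and ratio are conventional choices and are arguments of
:func:`match_controls`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cert import descriptive_stats
from .dispro import DisproResult, TwoByTwo, basic_stats, bcpnn_ic
from .ehr_model import Cohort, DrugLabEvent
from .extraction import ExtractionContext

__all__ = [
    "MatchedCohort",
    "ClearResult",
    "match_controls",
    "conditional_logistic",
    "clear_features",
    "clear_signal",
    "CLEAR_FEATURE_NAMES",
]

CLEAR_FEATURE_NAMES = [
    "clear_risk_mean",
    "clear_risk_median",
    "clear_risk_sd",
    "clear_risk_kurtosis",
    "clear_risk_skewness",
    "clear_risk_n_normal",
    "clear_risk_n_abnormal",
    "clear_risk_abs_pct_change",
    "clear_risk_pct_normal_to_abnormal",
    "clear_ctrl_mean",
    "clear_ctrl_median",
    "clear_ctrl_sd",
    "clear_ctrl_kurtosis",
    "clear_ctrl_skewness",
    "clear_ctrl_n_normal",
    "clear_ctrl_n_abnormal",
    "clear_ctrl_abs_pct_change",
    "clear_ctrl_pct_normal_to_abnormal",
    "clear_p_clogit",
    "clear_p_fisher",
    "clear_yule_lo",
    "clear_prr_lo",
    "clear_ror_lo",
    "clear_ic_lo",
    "clear_eb05",
]

#: member columns: stratum, visit_id, exposed, index_date, outcome,
#: pre/post extreme (scaled), pre/post abnormal, has_pre
_MEMBER_COLUMNS = [
    "stratum",
    "visit_id",
    "exposed",
    "index_date",
    "outcome",
    "pre_extreme",
    "post_extreme",
    "pre_abnormal",
    "post_abnormal",
    "has_pre",
]


@dataclass
class MatchedCohort:
    pair: DrugLabEvent
    members: pd.DataFrame  # one row per stratum member, columns _MEMBER_COLUMNS

    @property
    def n_strata(self) -> int:
        if self.members.empty:
            return 0
        return int(self.members["stratum"].nunique())

    def two_by_two(self) -> TwoByTwo | None:
        """a = exposed abnormal, b = exposed normal, c/d = control equivalents."""
        if self.members.empty:
            return None
        m = self.members
        exp, out = m["exposed"].to_numpy(), m["outcome"].to_numpy()
        return TwoByTwo(
            a=int(np.sum(exp & out)),
            b=int(np.sum(exp & ~out)),
            c=int(np.sum(~exp & out)),
            d=int(np.sum(~exp & ~out)),
        )


@dataclass
class ClearResult:
    pair: DrugLabEvent
    features: dict[str, float] = field(default_factory=dict)
    odds_ratio: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)
    p_clogit: float = math.nan
    p_fisher: float = math.nan
    n_strata: int = 0
    separation: bool = False
    table: TwoByTwo | None = None


def match_controls(
    pair: DrugLabEvent,
    cohort: Cohort | ExtractionContext,
    k: int = 4,
    seed: int | None = None,
    age_window: int = 5,
) -> MatchedCohort:
    """Build matched strata (1 exposed case : up to ``k`` controls) for a pair.

    Controls are non-exposed visits measuring the same lab, matched on sex,
    admission year and age within ``age_window`` years; they are sampled
    without replacement within a stratum (a visit may serve several strata).
    Cases need at least one post-exposure result of the lab; controls at
    least one result at/after their pseudo index date. Strata with zero
    eligible controls are dropped.
    """
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    rng = np.random.default_rng(seed)
    empty = MatchedCohort(pair, pd.DataFrame(columns=_MEMBER_COLUMNS))

    meas = ctx.measurements(pair.lab_code)
    fe = ctx.first_exposure(pair.drug_code)
    if meas.empty or fe.empty:
        return empty

    exposed_ids = set(fe["visit_id"])
    # cases: exposed visits with >= 1 post-exposure result of the lab
    case_meas = meas.merge(fe, on="visit_id")
    case_post = case_meas[case_meas["date"] >= case_meas["first_date"]]
    case_ids = case_post["visit_id"].unique()
    if len(case_ids) == 0:
        return empty

    visits = ctx.visits
    pool_ids = [v for v in meas["visit_id"].unique() if v not in exposed_ids]
    if not pool_ids:
        return empty
    pool = visits.loc[pool_ids]
    pool_by_key = {key: g for key, g in pool.groupby(["sex", "admission_year"])}

    # per-control-visit latest measurement date of this lab (eligibility check)
    last_date = meas.groupby("visit_id")["date"].max()

    case_info = visits.loc[case_ids]
    case_first = fe.set_index("visit_id")["first_date"]

    rows: list[tuple] = []
    stratum = 0
    for vid in case_ids:
        info = case_info.loc[vid]
        lag = (case_first[vid] - info["admit_date"]).days
        key = (info["sex"], info["admission_year"])
        g = pool_by_key.get(key)
        if g is None:
            continue
        cand = g[(g["age"] - info["age"]).abs() <= age_window]
        if cand.empty:
            continue
        # pseudo index date = control admission + case lag, clipped to the stay
        stay = (cand["discharge_date"] - cand["admit_date"]).dt.days
        idx_dates = cand["admit_date"] + pd.to_timedelta(
            np.minimum(lag, stay.to_numpy()), unit="D"
        )
        ok = last_date.reindex(cand["visit_id"]).to_numpy() >= idx_dates.to_numpy()
        cand = cand[ok]
        idx_dates = idx_dates[ok]
        if cand.empty:
            continue
        take = min(k, len(cand))
        sel = rng.choice(len(cand), size=take, replace=False)
        sel.sort()
        rows.append((stratum, vid, True, case_first[vid]))
        for i in sel:
            rows.append((stratum, cand["visit_id"].iloc[i], False, idx_dates.iloc[i]))
        stratum += 1

    if not rows:
        return empty
    members = pd.DataFrame(rows, columns=["stratum", "visit_id", "exposed", "index_date"])
    members = _attach_outcomes(members, meas, pair)
    return MatchedCohort(pair, members)


def _attach_outcomes(
    members: pd.DataFrame, meas: pd.DataFrame, pair: DrugLabEvent
) -> pd.DataFrame:
    """Compute pre/post extremes, abnormality flags and the outcome per member."""
    members = members.reset_index(drop=True)
    members["member"] = members.index
    m = members[["member", "visit_id", "index_date"]].merge(meas, on="visit_id")
    post = m[m["date"] >= m["index_date"]]
    pre = m[m["date"] < m["index_date"]]
    idx_fun = "idxmax" if pair.direction == "increased" else "idxmin"

    def extremes(rows: pd.DataFrame) -> pd.DataFrame:
        if rows.empty:
            return pd.DataFrame(
                columns=["scaled_value", "value", "normal_low", "normal_high"]
            )
        ix = getattr(rows.groupby("member")["value"], idx_fun)()
        return rows.loc[ix.to_numpy()].set_index(ix.index)

    post_x = extremes(post)
    pre_x = extremes(pre)

    members["post_extreme"] = members["member"].map(post_x["scaled_value"])
    members["pre_extreme"] = members["member"].map(pre_x["scaled_value"])
    members["has_pre"] = members["member"].isin(pre_x.index)

    def abnormal(x: pd.DataFrame) -> pd.Series:
        if x.empty:
            return pd.Series(dtype=bool)
        return pd.Series(
            pair.is_abnormal(x["value"], x["normal_low"], x["normal_high"]),
            index=x.index,
        )

    members["post_abnormal"] = (
        members["member"].map(abnormal(post_x)).fillna(False).astype(bool)
    )
    members["pre_abnormal"] = (
        members["member"].map(abnormal(pre_x)).fillna(False).astype(bool)
    )
    # outcome: any post-index value abnormal in the event direction; because
    # the extreme is taken in that direction this equals extreme-abnormality
    members["outcome"] = members["post_abnormal"]
    return members[_MEMBER_COLUMNS + ["member"]]


def conditional_logistic(mc: MatchedCohort) -> tuple[float, tuple[float, float], float]:
    """Stratified conditional logistic regression with exposure as covariate.

    Returns (odds_ratio, (lo, hi), p). Non-informative strata (no outcome
    variation) carry no information and are dropped by the conditional
    likelihood. Complete separation is flagged by returning an infinite
    odds ratio with a missing p-value.
    """
    if mc.members.empty:
        return math.nan, (math.nan, math.nan), math.nan
    m = mc.members
    informative = m.groupby("stratum")["outcome"].transform(lambda s: s.nunique() > 1)
    m = m[informative]
    if m.empty:
        return math.nan, (math.nan, math.nan), math.nan

    from statsmodels.discrete.conditional_models import ConditionalLogit

    y = m["outcome"].astype(int).to_numpy()
    x = m["exposed"].astype(float).to_numpy()[:, None]
    groups = m["stratum"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = ConditionalLogit(y, x, groups=groups)
            fit = model.fit(disp=False, maxiter=100)
        except Exception:
            return math.inf, (math.nan, math.nan), math.nan
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if math.isfinite(beta) and abs(beta) <= 15.0:
        # polish: the default optimizer stops ~1e-4 short of the maximizer
        from scipy.optimize import minimize_scalar

        opt = minimize_scalar(
            lambda b: -float(model.loglike(np.array([b]))),
            bounds=(beta - 0.5, beta + 0.5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        beta = float(opt.x)
        hess = float(np.asarray(model.hessian(np.array([beta]))).ravel()[0])
        if hess < 0:
            se = math.sqrt(-1.0 / hess)
    # separation: the profile likelihood is maximized at +/- infinity; the
    # optimizer stalls at a large estimate with an exploding Wald SE
    if not math.isfinite(beta) or abs(beta) > 15.0 or not math.isfinite(se) or se > 20.0:
        return math.inf if beta > 0 else 0.0, (math.nan, math.nan), math.nan
    ci = (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))
    p = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else math.nan
    return math.exp(beta), ci, p


def _group_features(group: pd.DataFrame, prefix: str) -> dict[str, float]:
    post = group["post_extreme"].to_numpy(dtype=float)
    feats = descriptive_stats(post, prefix)
    feats[f"{prefix}_n_normal"] = float(np.sum(~group["outcome"]))
    feats[f"{prefix}_n_abnormal"] = float(np.sum(group["outcome"]))

    both = group[group["has_pre"]]
    if len(both):
        pre_mean = float(both["pre_extreme"].mean())
        post_mean = float(both["post_extreme"].mean())
        feats[f"{prefix}_abs_pct_change"] = (
            abs(post_mean - pre_mean) / abs(pre_mean) * 100.0
            if pre_mean != 0
            else math.nan
        )
        feats[f"{prefix}_pct_normal_to_abnormal"] = (
            100.0 * float(np.sum(~both["pre_abnormal"] & both["post_abnormal"])) / len(both)
        )
    else:
        feats[f"{prefix}_abs_pct_change"] = math.nan
        feats[f"{prefix}_pct_normal_to_abnormal"] = math.nan
    return feats


def clear_features(
    mc: MatchedCohort, dispro_stats: DisproResult | None = None
) -> ClearResult:
    """CLEAR features f19-f43: group descriptives, tests, disproportionality.

    ``dispro_stats`` supplies features 39-43 (typically computed on the
    matched 2x2 with a GPS prior fitted across all pairs); when omitted,
    the frequentist and BCPNN statistics are computed here from the matched
    table and EB05 is left missing.
    """
    res = ClearResult(pair=mc.pair, n_strata=mc.n_strata)
    feats = {name: math.nan for name in CLEAR_FEATURE_NAMES}
    if mc.members.empty:
        res.features = feats
        return res

    m = mc.members
    feats.update(_group_features(m[m["exposed"]], "clear_risk"))
    ctrl = m[~m["exposed"]]
    if len(ctrl):
        feats.update(_group_features(ctrl, "clear_ctrl"))

    res.odds_ratio, res.ci95, res.p_clogit = conditional_logistic(mc)
    res.separation = math.isinf(res.odds_ratio) or res.odds_ratio == 0.0

    t = mc.two_by_two()
    res.table = t
    if t is not None:
        _, res.p_fisher = stats.fisher_exact([[t.a, t.b], [t.c, t.d]])
        if dispro_stats is None:
            dispro_stats = bcpnn_ic(t, basic_stats(t))

    feats["clear_p_clogit"] = res.p_clogit
    feats["clear_p_fisher"] = res.p_fisher
    if dispro_stats is not None:
        feats["clear_yule_lo"] = dispro_stats.yule_lo
        feats["clear_prr_lo"] = dispro_stats.prr_lo
        feats["clear_ror_lo"] = dispro_stats.ror_lo
        feats["clear_ic_lo"] = dispro_stats.ic_lo
        feats["clear_eb05"] = dispro_stats.eb05
    res.features = feats
    return res


def clear_signal(res: ClearResult) -> bool:
    """CLEAR decision: conditional-logistic p < 0.05 and OR > 1."""
    if math.isnan(res.p_clogit) or not math.isfinite(res.odds_ratio):
        return False
    return res.p_clogit < 0.05 and res.odds_ratio > 1.0
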