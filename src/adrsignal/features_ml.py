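"""Feature assembly, ML model training and the evaluation protocol.

The 48-feature vector of a drug--laboratory-event pair concatenates the
CERT (18), CLEAR (25) and PACE (5) outputs in their canonical order.
Features are z-standardized per column (by default over the entire
dataset, replicating the published preprocessing -- a documented leakage
caveat; a strict train-fitted mode is available) and missing values are
imputed to 0 after standardization (the column mean).

Four classifier families are supported with the published chosen
hyperparameters as defaults and the published grids available for
exhaustive 10-fold-CV search: L1 logistic regression, random forest,
RBF SVM (with cross-validated Platt calibration of decision scores) and
a ReLU multilayer perceptron trained with Adam.

The evaluation protocol fits ``reps x folds`` models per family on
development-set folds, applies every model to the held-out test set, and
summarizes each metric as mean +/- SD; model families are compared by
one-way ANOVA on their AUROC samples followed by Tukey's HSD. Rule-based
comparators (CERT400, CLEAR, PACE, CCP2, CCP3 and the six
disproportionality criteria) are evaluated on the whole labeled dataset.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cert as cert_mod
from . import clear as clear_mod
from . import pace as pace_mod
from .cert import CERT_FEATURE_NAMES, CertResult
from .clear import CLEAR_FEATURE_NAMES, ClearResult
from .dispro import (
    DisproResult,
    GpsPrior,
    TwoByTwo,
    basic_stats,
    bcpnn_ic,
    comparator_signals,
    dispro_result,
    eb05 as gps_eb05,
    fit_gps,
)
from .ehr_model import Cohort, DrugLabEvent, ReferencePair
from .extraction import ExtractionContext
from .pace import PACE_FEATURE_NAMES, PaceResult
from .preprocess import minmax_scale_labs  # noqa: F401  (public re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "ModelSpec",
    "MODEL_FAMILIES",
    "PUBLISHED_GRIDS",
    "EvalMetrics",
    "PairExtraction",
    "extract_pair_features",
    "assemble_features",
    "standardize_features",
    "minmax_scale_labs",
    "make_model",
    "tune_and_train",
    "predict_signal",
    "evaluate",
    "repeated_cv_evaluation",
    "compare_auroc",
    "feature_importance",
    "comparator_evaluation",
]

#: the 48 features in canonical (Table) order
FEATURE_NAMES: list[str] = CERT_FEATURE_NAMES + CLEAR_FEATURE_NAMES + PACE_FEATURE_NAMES
assert len(FEATURE_NAMES) == 48

MODEL_FAMILIES = ("l1_logreg", "random_forest", "svm_rbf", "neural_net")

#: published hyperparameter search spaces
PUBLISHED_GRIDS: dict[str, dict[str, list]] = {
    "l1_logreg": {"penalty": ["l1", "l2"], "C": [0.001, 0.01, 0.1, 1, 10, 100]},
    "random_forest": {
        "n_estimators": [50, 100, 150, 200, 250, 300, 500],
        "max_depth": [20, 25, 30, 35, 40],
        "min_samples_leaf": [1, 10, 20, 50, 100],
    },
    "svm_rbf": {"C": [0.001, 0.01, 0.1, 1, 10, 100], "gamma": [0.001, 0.01, 0.1, 1, "auto"]},
    "neural_net": {"n_hidden_layers": [1, 2, 3, 4]},
}

#: published chosen values (the ModelSpec defaults)
PUBLISHED_CHOICES: dict[str, dict] = {
    "l1_logreg": {"penalty": "l1", "C": 1},
    "random_forest": {"n_estimators": 250, "max_depth": 25, "min_samples_leaf": 10},
    "svm_rbf": {"C": 10, "gamma": 0.01},
    "neural_net": {"n_hidden_layers": 3},
}

#: MLP layer widths by depth (widths are unpublished implementation choices)
_NN_WIDTHS = {1: (64,), 2: (64, 32), 3: (64, 32, 16), 4: (64, 32, 16, 8)}


@dataclass
class ModelSpec:
    family: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        merged = dict(PUBLISHED_CHOICES[self.family])
        merged.update(self.params)
        self.params = merged


class PlattCalibratedSVC:
    """RBF SVM with a single sigmoid fitted on cross-validated decision scores.

    ``ensemble=False`` refits one SVM on all data and calibrates it with one
    monotone sigmoid, so the probability ranking equals the margin ranking.
    The calibration fold count adapts to the smallest class so tiny
    training sets remain fittable.
    """

    def __init__(self, C: float = 10.0, gamma=0.01, random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C, "gamma": self.gamma, "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _svc(self):
        from sklearn.svm import SVC

        return SVC(C=self.C, gamma=self.gamma, random_state=self.random_state)

    def fit(self, X, y):
        from sklearn.calibration import CalibratedClassifierCV

        y = np.asarray(y)
        counts = np.bincount(y.astype(int))
        cv = int(min(3, counts[counts > 0].min()))
        if cv >= 2:
            self.model_ = CalibratedClassifierCV(
                self._svc(), method="sigmoid", cv=cv, ensemble=False
            ).fit(X, y)
            self.svc_ = self.model_.calibrated_classifiers_[0].estimator
        else:  # a one-member class: calibrate on the training margins directly
            from sklearn.linear_model import LogisticRegression

            self.svc_ = self._svc().fit(X, y)
            margins = self.svc_.decision_function(X)[:, None]
            self.model_ = LogisticRegression().fit(margins, y)
            self._margin_input = True
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        if getattr(self, "_margin_input", False):
            return self.model_.predict_proba(self.svc_.decision_function(X)[:, None])
        return self.model_.predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def make_model(spec: ModelSpec, seed: int | None = None):
    """Instantiate a scikit-learn estimator for a spec (probability-capable)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier

    seed = spec.seed if seed is None else seed
    p = spec.params
    if spec.family == "l1_logreg":
        return LogisticRegression(
            penalty=p["penalty"], C=p["C"], solver="liblinear", max_iter=2000,
            random_state=seed,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "svm_rbf":
        return PlattCalibratedSVC(C=p["C"], gamma=p["gamma"], random_state=seed)
    widths = _NN_WIDTHS[p["n_hidden_layers"]]
    # loss-plateau stopping rather than a held-out validation split: the
    # reference datasets are small enough that a 10% split starves both
    # training and the stopping rule; the conservative learning rate needs
    # a generous epoch budget to converge
    return MLPClassifier(
        hidden_layer_sizes=widths,
        activation="relu",
        solver="adam",
        learning_rate_init=1e-4,
        max_iter=2000,
        early_stopping=False,
        n_iter_no_change=50,
        random_state=seed,
    )


# ---------------------------------------------------------------------------
# per-pair feature extraction
# ---------------------------------------------------------------------------


@dataclass
class PairExtraction:
    """All algorithm outputs for one pair (the raw feature sources)."""

    pair: DrugLabEvent
    cert: CertResult
    clear: ClearResult
    pace: PaceResult
    dispro: DisproResult
    table: TwoByTwo | None


def _cohort_two_by_two(
    pair: DrugLabEvent, ctx: ExtractionContext
) -> TwoByTwo | None:
    """Whole-cohort exposure x event table (alternative 2x2 construction)."""
    exposed = set(ctx.exposed_visits(pair.drug_code))
    ev = pace_mod.event_dates(pair, ctx)
    event_visits = set(ev["visit_id"])
    all_visits = set(ctx.visits["visit_id"])
    a = len(exposed & event_visits)
    b = len(exposed - event_visits)
    c = len(event_visits - exposed)
    d = len(all_visits - exposed - event_visits)
    if a + b + c + d == 0:
        return None
    return TwoByTwo(a, b, c, d)


def extract_pair_features(
    cohort: Cohort | ExtractionContext,
    pairs: Sequence[DrugLabEvent],
    seed: int = 0,
    k_controls: int = 4,
    two_by_two: str = "matched",
) -> dict[DrugLabEvent, PairExtraction]:
    """Run CERT, CLEAR, PACE and the disproportionality stage on every pair.

    ``two_by_two`` selects the table feeding the disproportionality
    measures: the CLEAR matched counts (default) or whole-cohort
    exposure x event counts. The GPS prior is fitted across all pairs'
    tables in a second pass; Bonferroni adjustment of the CERT p-values
    uses the number of pairs analyzed as the family size.
    """
    if two_by_two not in ("matched", "cohort"):
        raise ValueError("two_by_two must be 'matched' or 'cohort'")
    ctx = cohort if isinstance(cohort, ExtractionContext) else ExtractionContext(cohort)
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=len(pairs))

    out: dict[DrugLabEvent, PairExtraction] = {}
    tables: dict[DrugLabEvent, TwoByTwo] = {}
    for pair, pseed in zip(pairs, pair_seeds):
        pe = cert_mod.paired_extremes(pair, ctx)
        cres = cert_mod.cert_features(pe)
        mc = clear_mod.match_controls(pair, ctx, k=k_controls, seed=int(pseed))
        t = mc.two_by_two() if two_by_two == "matched" else _cohort_two_by_two(pair, ctx)
        dres = DisproResult()
        if t is not None:
            basic_stats(t, dres)
            bcpnn_ic(t, dres)
            tables[pair] = t
        clres = clear_mod.clear_features(mc, dres if t is not None else None)
        pres = pace_mod.pace_features(pair, ctx)
        out[pair] = PairExtraction(pair, cres, clres, pres, dres, t)

    cert_mod.apply_bonferroni({p: ex.cert for p, ex in out.items()})

    if len(tables) >= 10:
        prior = fit_gps(list(tables.values()), seed=seed)
        for pair, t in tables.items():
            gps_eb05(prior, t, out[pair].dispro)
            out[pair].clear.features["clear_eb05"] = out[pair].dispro.eb05
    else:
        logger.warning("fewer than 10 usable 2x2 tables; GPS prior not fitted")
    return out


def assemble_features(
    extractions: Mapping[DrugLabEvent, PairExtraction],
    pairs: Sequence[ReferencePair],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Raw 48-column feature matrix, missing mask and label vector.

    One row per reference pair, columns in canonical order. Values are the
    raw (unstandardized) features; the mask marks missing entries.
    """
    rows, mask_rows, labels = [], [], []
    index = []
    for rp in pairs:
        ex = extractions[rp.pair]
        feats = {}
        feats.update(ex.cert.features)
        feats.update(ex.clear.features)
        feats.update(ex.pace.features)
        unknown = set(feats) - set(FEATURE_NAMES)
        if unknown:
            raise KeyError(f"unknown feature key(s): {sorted(unknown)}")
        row = [feats.get(name, math.nan) for name in FEATURE_NAMES]
        rows.append(row)
        mask_rows.append([math.isnan(v) for v in row])
        labels.append(rp.label)
        index.append((rp.pair.drug_code, rp.pair.lab_code, rp.pair.direction))
    idx = pd.MultiIndex.from_tuples(index, names=["drug_code", "lab_code", "direction"])
    X = pd.DataFrame(rows, columns=FEATURE_NAMES, index=idx)
    mask = pd.DataFrame(mask_rows, columns=FEATURE_NAMES, index=idx)
    return X, mask, np.array(labels, dtype=int)


def standardize_features(
    raw: pd.DataFrame, fit_rows: np.ndarray | None = None
) -> pd.DataFrame:
    """Z-standardize per column and impute missing to 0 (the column mean).

    ``fit_rows`` restricts the mean/SD estimation (the strict, no-leakage
    mode: fit on the development rows only); by default moments come from
    the entire matrix, replicating the published preprocessing.
    """
    fit = raw if fit_rows is None else raw.iloc[fit_rows]
    mu = fit.mean(axis=0, skipna=True)
    sd = fit.std(axis=0, ddof=0, skipna=True)
    sd = sd.replace(0.0, 1.0).fillna(1.0)
    mu = mu.fillna(0.0)
    z = (raw - mu) / sd
    return z.fillna(0.0)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    auroc: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        scores: np.ndarray | None = None,
    ) -> "EvalMetrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=bool)
        tp = int(np.sum((y_true == 1) & y_pred))
        fp = int(np.sum((y_true == 0) & y_pred))
        tn = int(np.sum((y_true == 0) & ~y_pred))
        fn = int(np.sum((y_true == 1) & ~y_pred))

        def ratio(num: int, den: int) -> float:
            return num / den if den else math.nan

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        npv = ratio(tn, tn + fn)
        f1 = (
            2 * ppv * sens / (ppv + sens)
            if not (math.isnan(ppv) or math.isnan(sens)) and (ppv + sens) > 0
            else math.nan
        )
        if scores is None:
            scores = y_pred.astype(float)
        from sklearn.metrics import roc_auc_score

        auroc = (
            float(roc_auc_score(y_true, scores))
            if len(np.unique(y_true)) == 2
            else math.nan
        )
        return cls(sens, spec, ppv, npv, f1, auroc, tp, fp, tn, fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "auroc": self.auroc,
        }


def _cv_auc(model_factory, X, y, folds, seed) -> float:
    """Mean cross-validated AUROC; single-class folds are skipped."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            warnings.warn("skipping single-class CV fold", stacklevel=2)
            continue
        model = model_factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
    return float(np.mean(aucs)) if aucs else math.nan


def _grid_configs(grid: Mapping[str, list]) -> list[dict]:
    configs = [{}]
    for key, values in grid.items():
        configs = [dict(c, **{key: v}) for c in configs for v in values]
    return configs


def tune_and_train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int | None = None,
):
    """Exhaustive grid search (10-fold CV, max mean AUROC), refit on all data.

    With an empty grid the spec's parameters are used directly. Returns
    ``(fitted_model, best_params, cv_results)``; ties resolve to the first
    grid configuration in enumeration order (deterministic under a seed).
    """
    seed = spec.seed if seed is None else seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    grid = spec.grid or {}
    configs = _grid_configs(grid) if grid else [dict(spec.params)]

    results = []
    best_auc, best_params = -math.inf, None
    for cfg in configs:
        trial = ModelSpec(spec.family, params={**spec.params, **cfg}, seed=seed)
        auc = _cv_auc(lambda: make_model(trial, seed), X, y, folds, seed)
        results.append({**cfg, "mean_cv_auroc": auc})
        if not math.isnan(auc) and auc > best_auc:
            best_auc, best_params = auc, trial.params
    if best_params is None:
        best_params = dict(spec.params)
    final = make_model(ModelSpec(spec.family, params=best_params, seed=seed), seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return final, best_params, pd.DataFrame(results)


def predict_signal(
    model, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Positive iff predicted probability strictly exceeds ``threshold``."""
    scores = model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return scores > threshold, scores


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> EvalMetrics:
    """Confusion-matrix metrics plus rank-based (trapezoidal) AUROC."""
    return EvalMetrics.from_predictions(y_true, y_pred, scores)


def repeated_cv_evaluation(
    X_dev: np.ndarray,
    y_dev: np.ndarray,
    specs: Sequence[ModelSpec],
    X_test: np.ndarray,
    y_test: np.ndarray,
    reps: int = 10,
    folds: int = 10,
    seed: int = 0,
    keep_models: bool = False,
) -> dict[str, dict]:
    """reps x folds fold-models per family, each scored on the test set.

    Every repetition reshuffles a stratified K-fold on the development set;
    each fold's training portion fits one model, which is then applied to
    the held-out test matrix. Returns, per family, the metric table
    (one row per model), the mean +/- SD summary, and optionally the
    fitted models (for feature-importance aggregation).
    """
    from sklearn.model_selection import StratifiedKFold

    X_dev = np.asarray(X_dev, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_dev = np.asarray(y_dev, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)

    out: dict[str, dict] = {}
    for spec in specs:
        records, models = [], []
        for rep, rseed in enumerate(rep_seeds):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rseed))
            for fold, (tr, _va) in enumerate(skf.split(X_dev, y_dev)):
                if len(np.unique(y_dev[tr])) < 2:
                    warnings.warn("skipping single-class training fold", stacklevel=2)
                    continue
                model = make_model(spec, seed=int((rseed + fold) % (2**31 - 1)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X_dev[tr], y_dev[tr])
                pred, scores = predict_signal(model, X_test)
                m = evaluate(y_test, pred, scores)
                records.append({"rep": rep, "fold": fold, **m.as_dict()})
                if keep_models:
                    models.append(model)
        table = pd.DataFrame(records)
        metric_cols = ["sensitivity", "specificity", "ppv", "npv", "f1", "auroc"]
        summary = table[metric_cols].agg(["mean", "std"])
        out[spec.family] = {"table": table, "summary": summary, "models": models}
    return out


def compare_auroc(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA on per-model AUROCs, then Tukey HSD on all ordered pairs.

    The Tukey table lists every ordered (I, J) pair with the mean
    difference I - J, its standard error, the studentized-range adjusted
    p-value and the 95% family-wise confidence interval (the published
    summary-table layout).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    f_stat, p_value = stats.f_oneway(*samples)

    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)

    from itertools import combinations

    uniq = [str(g) for g in tk.groupsunique]
    rows = []
    for (i, j), diff, (lo, hi), p, se in zip(
        combinations(range(len(uniq)), 2),
        tk.meandiffs,
        tk.confint,
        tk.pvalues,
        tk.std_pairs,
    ):
        # statsmodels reports meandiff = mean(group_j) - mean(group_i)
        for gi, gj, sign in ((uniq[j], uniq[i], 1.0), (uniq[i], uniq[j], -1.0)):
            rows.append(
                {
                    "model_i": gi,
                    "model_j": gj,
                    "mean_diff": sign * float(diff),
                    "std_err": float(se),
                    "p_adj": float(p),
                    "ci_lower": float(sign * hi if sign < 0 else sign * lo),
                    "ci_upper": float(sign * lo if sign < 0 else sign * hi),
                }
            )
    tukey = pd.DataFrame(rows).sort_values(["model_i", "model_j"]).reset_index(drop=True)
    return {"anova_f": float(f_stat), "anova_p": float(p_value), "tukey": tukey}


def feature_importance(
    models_by_family: Mapping[str, Sequence], feature_names: Sequence[str] = FEATURE_NAMES
) -> pd.DataFrame:
    """Aggregate Gini importances (RF) and L1 coefficients over CV models.

    Returns one row per feature with the mean normalized Gini importance,
    the mean signed L1 coefficient and its mean magnitude, plus ranks.
    """
    n = len(feature_names)
    out = pd.DataFrame(index=pd.Index(feature_names, name="feature"))
    rf_models = models_by_family.get("random_forest", [])
    if rf_models:
        imp = np.mean([m.feature_importances_ for m in rf_models], axis=0)
        total = imp.sum()
        out["gini_importance"] = imp / total if total > 0 else np.full(n, 1.0 / n)
        out["gini_rank"] = out["gini_importance"].rank(ascending=False).astype(int)
    lr_models = models_by_family.get("l1_logreg", [])
    if lr_models:
        coefs = np.mean([m.coef_.ravel() for m in lr_models], axis=0)
        out["l1_coefficient"] = coefs
        out["l1_magnitude"] = np.abs(coefs)
        out["l1_rank"] = out["l1_magnitude"].rank(ascending=False).astype(int)
    return out


# ---------------------------------------------------------------------------
# rule-based comparator evaluation
# ---------------------------------------------------------------------------

COMPARATOR_NAMES = [
    "CERT400",
    "CLEAR",
    "PACE",
    "CCP2",
    "CCP3",
    "CHI",
    "PRR",
    "ROR",
    "YULE",
    "BCPNN",
    "GPS",
]


def comparator_decisions(ex: PairExtraction) -> dict[str, bool]:
    """All eleven rule-based detector decisions for one pair."""
    cert_p = cert_mod.cert_signal(ex.cert, n_threshold=0)  # p-criterion only
    cert400 = cert_mod.cert_signal(ex.cert, n_threshold=400)
    clear_sig = clear_mod.clear_signal(ex.clear)
    pace_sig = pace_mod.pace_signal(ex.pace)
    pci_low = (not math.isnan(ex.pace.pci)) and ex.pace.pci < pace_mod.DISCONTINUATION_CUTOFF
    disp = comparator_signals(ex.dispro)
    return {
        "CERT400": cert400,
        "CLEAR": clear_sig,
        "PACE": pace_sig,
        "CCP2": (cert_p or clear_sig) and pci_low,
        "CCP3": cert_p and clear_sig and pace_sig,
        **{k: bool(v) and not math.isnan(getattr(ex.dispro, _DISPRO_FIELD[k]))
           for k, v in disp.items()},
    }


_DISPRO_FIELD = {
    "CHI": "chi2_p",
    "PRR": "prr_lo",
    "ROR": "ror_lo",
    "YULE": "yule_lo",
    "BCPNN": "ic_lo",
    "GPS": "eb05",
}


def comparator_evaluation(
    extractions: Mapping[DrugLabEvent, PairExtraction],
    pairs: Sequence[ReferencePair],
) -> pd.DataFrame:
    """Evaluate every rule-based detector on the whole labeled dataset."""
    y = np.array([rp.label for rp in pairs], dtype=int)
    decisions = {name: [] for name in COMPARATOR_NAMES}
    for rp in pairs:
        d = comparator_decisions(extractions[rp.pair])
        for name in COMPARATOR_NAMES:
            decisions[name].append(d[name])
    rows = {}
    for name in COMPARATOR_NAMES:
        pred = np.array(decisions[name], dtype=bool)
        rows[name] = evaluate(y, pred).as_dict()
    return pd.DataFrame(rows).T[
        ["sensitivity", "specificity", "ppv", "npv", "f1", "auroc"]
    ]
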