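"""Treatment-response prediction from short-term metabolite changes.

The predictive analysis takes per-subject differentiated scores over a week
pair (follow-up minus baseline: dHDRS, d(tCho), dNAA, dGlx), screens them
with bidirectional stepwise logistic regression (Wald entry p < 0.05,
removal p > 0.10) against the week-6 RD / n-RD response label with the
clinical covariates competing for selection, and evaluates the resulting
linear predictor by ROC analysis (Mann–Whitney AUC, DeLong 95 % CI, Youden
operating point) plus validation-set confusion matrices with RD as the
positive class.

:class:`ResponsePredictionModel` wraps the whole procedure in a
statsmodels-style model object whose :meth:`~ResponsePredictionModel.fit`
returns a results object carrying the selected terms, their uncertainties
and odds ratios, a ``summary()`` table, ROC diagnostics and validation
helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import COVARIATES, UndefinedTestError, response_group

__all__ = [
    "DIFF_FEATURES",
    "build_diff_table",
    "stepwise_logistic",
    "StepwiseLogisticResults",
    "roc_analysis",
    "RocResult",
    "ConfusionMatrix",
    "evaluate_validation",
    "ResponsePredictionModel",
    "ResponsePredictionResults",
]

DIFF_FEATURES = ("d_hdrs", "d_tcho", "d_naa", "d_glx")


# ---------------------------------------------------------------------------
# differentiated-score table


def build_diff_table(
    cohort: pd.DataFrame, week_pair: tuple = (0, 3), label_week: int = 6
) -> pd.DataFrame:
    """Per-patient differentiated scores over ``week_pair``.

    All differentiated changes are follow-up minus baseline.  The response
    label is recomputed from the realised HDRS scores at week 0 and
    ``label_week`` (n-RD iff the reduction is >= 50 %).  Healthy controls
    are excluded; a subject contributes only if both visits of the pair and
    the label week exist.
    """
    base_w, follow_w = week_pair
    patients = cohort[cohort["group"] != "HC"]
    rows = []
    for sid, sub in patients.groupby("subject_id"):
        sub = sub.set_index("week")
        if base_w not in sub.index or follow_w not in sub.index:
            continue
        if label_week not in sub.index:
            continue
        b = sub.loc[base_w]
        f = sub.loc[follow_w]
        label = response_group(b["hdrs"], sub.loc[label_week, "hdrs"])
        rows.append(
            {
                "subject_id": sid,
                "group": b["group"],
                "label": label,
                "d_hdrs": f["hdrs"] - b["hdrs"],
                "d_naa": f["naa"] - b["naa"],
                "d_tcho": f["tcho"] - b["tcho"],
                "d_glx": f["glx"] - b["glx"],
                "age": b["age"],
                "gender": b["gender"],
                "age_onset": b["age_onset"],
                "duration": b["duration"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stepwise logistic regression


class StepwiseLogisticResults:
    """Final model of the bidirectional Wald-based stepwise selection.

    ``terms`` lists the retained predictors in selection order; the
    coefficient table exposes beta, SE, Wald chi-square, p, OR and the 95 %
    CI per term (Wald intervals on the log-odds scale).
    """

    def __init__(self, terms, fit, data, outcome, separation=False):
        self.terms = list(terms)
        self._fit = fit
        self._data = data
        self.outcome = outcome
        self.separation = separation

    @property
    def params(self) -> pd.Series:
        return self._fit.params

    @property
    def bse(self) -> pd.Series:
        return self._fit.bse

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for term in self.terms:
            beta = self._fit.params[term]
            se = self._fit.bse[term]
            wald = (beta / se) ** 2 if se > 0 else np.inf
            p = self._fit.pvalues[term]
            or_ = np.exp(beta)
            lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
            rows.append(
                {
                    "term": term,
                    "beta": beta,
                    "se": se,
                    "wald": wald,
                    "p": p,
                    "or": or_,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(
            data[self.terms].to_numpy(dtype=float), has_constant="add"
        )
        return x @ self._fit.params.to_numpy()

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(data)))

    def summary(self) -> str:
        tab = self.coefficient_table()
        lines = [
            f"Stepwise logistic regression — outcome: {self.outcome}",
            f"retained terms: {', '.join(self.terms) if self.terms else '(none)'}",
        ]
        if self.separation:
            lines.append("WARNING: separation detected; ridge-penalised fallback fit")
        lines.append(
            f"{'term':>12} {'beta':>9} {'S.E.':>8} {'Wald':>9} {'P':>9} {'OR (95% CI)':>24}"
        )
        for _, row in tab.iterrows():
            lines.append(
                f"{row['term']:>12} {row['beta']:>9.3f} {row['se']:>8.3f} "
                f"{row['wald']:>9.3f} {row['p']:>9.4g} "
                f"{row['or']:>8.3f} ({row['or_ci_low']:.3f}~{row['or_ci_high']:.3f})"
            )
        return "\n".join(lines)


def _fit_logit(y: np.ndarray, x: pd.DataFrame):
    """Logit MLE with a separation-aware fallback (small ridge penalty)."""
    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.bse)) and np.all(np.abs(fit.params) < 50):
                return fit, False
        except Exception:
            pass
        fit = sm.Logit(y, design).fit_regularized(
            method="l1", alpha=1e-4, disp=0, maxiter=500
        )
    return fit, True


def stepwise_logistic(
    data: pd.DataFrame,
    outcome: str = "label",
    candidates=None,
    positive: str = "RD",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    force=(),
) -> StepwiseLogisticResults:
    """Bidirectional stepwise selection on Wald p-values.

    Starting from the forced terms (empty by default — covariates compete
    for selection), each round adds the candidate with the smallest Wald p
    below ``p_enter``, then removes any included term whose Wald p exceeds
    ``p_remove``, until the model is stable.  Term order breaks ties, so the
    procedure is deterministic.
    """
    if candidates is None:
        candidates = [c for c in data.columns if c not in (outcome, "subject_id", "group")]
    candidates = list(candidates)
    df = data[[outcome, *candidates]].dropna()
    y = (df[outcome] == positive).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedTestError("both outcome classes must be present")
    if len(df) <= len(candidates) + 1:
        raise UndefinedTestError("need more subjects than candidate terms")

    included = list(force)
    separation_seen = False
    for _ in range(50):
        changed = False
        # forward step
        best_term, best_p, best_sep = None, p_enter, False
        for term in candidates:
            if term in included:
                continue
            fit, sep = _fit_logit(y, df[included + [term]])
            if sep:
                # the added term separates the classes: maximally predictive
                p = 0.0
            else:
                try:
                    p = float(fit.pvalues[term])
                except Exception:
                    p = 1.0
            if np.isfinite(p) and p < best_p:
                best_term, best_p, best_sep = term, p, sep
        if best_term is not None:
            included.append(best_term)
            separation_seen |= best_sep
            changed = True
        # backward step (skipped under separation: Wald p unreliable there)
        if included:
            fit, sep = _fit_logit(y, df[included])
            separation_seen |= sep
            removable = [t for t in included if t not in force]
            if removable and not sep:
                pvals = {t: float(fit.pvalues.get(t, 0.0)) for t in removable}
                worst = max(pvals, key=pvals.get)
                if pvals[worst] > p_remove:
                    included.remove(worst)
                    changed = True
        if not changed:
            break

    fit, sep = _fit_logit(y, df[included] if included else df[[]])
    separation_seen |= sep
    return StepwiseLogisticResults(
        terms=included, fit=fit, data=df, outcome=outcome, separation=separation_seen
    )


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC (ties count half) and its DeLong variance."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = _midrank(all_scores)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n  # structural components over positives
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(scores, labels, positive="RD") -> RocResult:
    """Empirical ROC of ``scores`` for predicting the positive class.

    AUC uses the Mann–Whitney formulation with ties counted half; the 95 %
    CI is DeLong's; the operating threshold maximises the Youden index
    (predict positive when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive if labels.dtype.kind in "OUS" else labels.astype(bool)
    pos = scores[is_pos]
    neg = scores[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedTestError("ROC requires both classes present")
    auc, var = _delong_auc_variance(pos, neg)
    half = 1.96 * np.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)
    best = (-np.inf, None)
    for thr in np.unique(scores):
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        youden = sens + spec - 1.0
        if youden > best[0] + 1e-12:
            best = (youden, (thr, sens, spec))
    thr, sens, spec = best[1]
    return RocResult(auc, float(ci_low), float(ci_high), sens, spec, float(thr))


# ---------------------------------------------------------------------------
# validation-set evaluation


@dataclass
class ConfusionMatrix:
    """2x2 prediction table with RD as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy_pct(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.total, 2)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted RD": [self.tp, self.fp], "predicted n-RD": [self.fn, self.tn]},
            index=["actual RD", "actual n-RD"],
        )


def evaluate_validation(
    model: StepwiseLogisticResults,
    validation: pd.DataFrame,
    threshold: float,
    outcome: str = "label",
    positive: str = "RD",
) -> ConfusionMatrix:
    """Apply a fixed (test-set-derived) threshold on the model's linear
    predictor to an independent validation table."""
    missing = [t for t in model.terms if t not in validation.columns]
    if missing:
        raise KeyError(f"validation table missing features: {missing}")
    df = validation[[outcome, *model.terms]].dropna()
    n_dropped = len(validation) - len(df)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} validation rows dropped for missing features", UserWarning
        )
    scores = model.linear_predictor(df)
    actual_pos = (df[outcome] == positive).to_numpy()
    pred_pos = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(actual_pos & pred_pos)),
        fn=int(np.sum(actual_pos & ~pred_pos)),
        fp=int(np.sum(~actual_pos & pred_pos)),
        tn=int(np.sum(~actual_pos & ~pred_pos)),
    )


# ---------------------------------------------------------------------------
# the model object


class ResponsePredictionModel:
    """Stepwise-logistic prediction of the week-6 RD / n-RD label from
    short-term differentiated scores.

    Parameters
    ----------
    diffs : DataFrame
        Differentiated-score table (see :func:`build_diff_table`).
    features : sequence of str
        Candidate predictors among the differentiated scores.
    covariates : sequence of str
        Clinical covariates; by default they compete for selection, set
        ``force_covariates=True`` to keep them in the model throughout.
    """

    def __init__(
        self,
        diffs: pd.DataFrame,
        features=("d_hdrs", "d_tcho", "d_naa"),
        covariates=COVARIATES,
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        force_covariates: bool = False,
    ):
        self.diffs = diffs
        self.features = list(features)
        self.covariates = list(covariates)
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.force_covariates = force_covariates

    @classmethod
    def from_cohort(
        cls, cohort: pd.DataFrame, week_pair: tuple = (0, 3), **kwargs
    ) -> "ResponsePredictionModel":
        return cls(build_diff_table(cohort, week_pair), **kwargs)

    def fit(self) -> "ResponsePredictionResults":
        selection = stepwise_logistic(
            self.diffs,
            outcome="label",
            candidates=self.features + self.covariates,
            p_enter=self.p_enter,
            p_remove=self.p_remove,
            force=tuple(self.covariates) if self.force_covariates else (),
        )
        return ResponsePredictionResults(self, selection)


class ResponsePredictionResults:
    """Fitted response-prediction model: selected terms, ROC diagnostics and
    validation-set evaluation."""

    def __init__(self, model: ResponsePredictionModel, selection: StepwiseLogisticResults):
        self.model = model
        self.selection = selection

    @property
    def terms(self):
        return self.selection.terms

    def coefficient_table(self) -> pd.DataFrame:
        return self.selection.coefficient_table()

    def training_scores(self) -> tuple[np.ndarray, np.ndarray]:
        df = self.selection._data
        return self.selection.linear_predictor(df), df["label"].to_numpy()

    def roc(self) -> RocResult:
        scores, labels = self.training_scores()
        return roc_analysis(scores, labels)

    def validate(
        self, validation: pd.DataFrame, threshold: float | None = None
    ) -> ConfusionMatrix:
        """Confusion matrix on an independent set; the threshold defaults to
        the training set's Youden optimum."""
        if threshold is None:
            threshold = self.roc().threshold
        return evaluate_validation(self.selection, validation, threshold)

    def summary(self) -> str:
        lines = [self.selection.summary()]
        if self.terms:
            roc = self.roc()
            lines.append(
                f"training ROC: AUC = {roc.auc:.3f} "
                f"(95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
                f"sens = {roc.sensitivity:.3f}, spec = {roc.specificity:.3f} "
                f"at threshold {roc.threshold:.3f}"
            )
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        scores, labels = self.training_scores()
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve((labels == "RD").astype(int), scores)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"AUC = {self.roc().auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
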