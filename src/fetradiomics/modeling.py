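"""ROC analysis, two-parameter logistic combination and cross-validation.

Mirrors the diagnostic-evaluation protocol used for FET PET genotype
prediction: each parameter is scored by ROC analysis with the decision
cut-off chosen where accuracy is maximal; parameters are then combined
pairwise (never more than two, to limit model complexity) by maximum-
likelihood logistic regression; combination models are evaluated by
Fisher's exact test on the 2x2 confusion table with Bonferroni correction
over the number of models tested, and validated by stratified 5- and
10-fold cross-validation with pooled held-out accuracy.

The positive class throughout is IDH-mutant (label 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RocResult",
    "ComboModelResult",
    "roc_single",
    "fit_combo",
    "fisher_exact_2x2",
    "bonferroni",
    "crossvalidate",
    "run_model_search",
    "STANDARD_PARAM_NAMES",
]

STANDARD_PARAM_NAMES = ["tbr_mean", "tbr_max", "ttp_min", "slope_suv_per_h"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    direction: str  # "higher-is-positive" | "lower-is-positive"


@dataclass(frozen=True)
class ComboModelResult:
    parameters: tuple[str, ...]
    coefficients: np.ndarray  # on the original predictor scale
    intercept: float
    prob_cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    fisher_p: float
    fisher_p_bonferroni: float | None
    separation_flag: bool
    n_used: int
    cv_accuracy: dict[int, float] | None = None


def _validate(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    return values, labels


def _rank_auc(values, labels):
    """AUC via the rank statistic; tied scores count one half."""
    ranks = stats.rankdata(values)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(auc, n1, n0):
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _accuracy_sweep(values, labels, higher_is_positive):
    """Accuracy-maximal cut-off over midpoints of consecutive unique scores,
    including the two extreme (classify-all) cut-offs.

    Ties resolve to higher specificity, then to the lower cut-off.
    """
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n = len(labels)
    n1 = labels.sum()
    n0 = n - n1
    best = None
    for c in cutoffs:
        pred = values > c if higher_is_positive else values < c
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        acc = (tp + tn) / n
        sens = tp / n1
        spec = tn / n0
        key = (acc, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, acc, sens, spec)
    _, cutoff, acc, sens, spec = best
    return float(cutoff), float(acc), float(sens), float(spec)


def roc_single(values, labels, min_n: int = 4) -> RocResult:
    """Single-parameter ROC analysis with accuracy-optimal cut-off.

    Both score directions are evaluated and the one with AUC >= 0.5 is
    reported; the standard error follows Hanley & McNeil, the 95% CI is the
    normal approximation clipped to [0, 1], and p tests AUC = 0.5.
    """
    values, labels = _validate(values, labels)
    if len(values) < min_n:
        raise ValueError(f"need at least {min_n} subjects")
    auc = _rank_auc(values, labels)
    direction = "higher-is-positive"
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "lower-is-positive"
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    se = _hanley_mcneil_se(auc, n1, n0)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc > 0.5 else 1.0
    cutoff, acc, sens, spec = _accuracy_sweep(
        values, labels, higher_is_positive=(direction == "higher-is-positive")
    )
    return RocResult(auc, se, ci, p, cutoff, acc, sens, spec, direction)


# ---------------------------------------------------------------------------
# Logistic combination models


def _fit_logistic(X, y, ridge=0.0):
    """Maximum-likelihood logistic fit (optionally tiny-ridge penalised) via
    Newton/BFGS on the standardized design; returns params incl. intercept."""
    import statsmodels.api as sm

    Xd = sm.add_constant(X, has_constant="add")
    if ridge == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xd)
            res = model.fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise RuntimeError("non-finite estimates")
            return np.asarray(res.params), float(res.llf), bool(res.mle_retvals["converged"])
    # ridge fallback for separation / non-convergence

    def negll(beta):
        eta = Xd @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta + ridge * beta[1:] @ beta[1:])

    def grad(beta):
        from scipy.special import expit

        mu = expit(Xd @ beta)
        g = Xd.T @ (mu - y)
        g[1:] += 2.0 * ridge * beta[1:]
        return g

    res = optimize.minimize(negll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS")
    beta = res.x
    eta = Xd @ beta
    llf = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    return beta, llf, True


class _ComboFit:
    """Fitted two-predictor logistic model with its training-set cut-off."""

    def __init__(self, x1, x2, labels, names=("x1", "x2"), ridge_fallback=1e-6):
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        labels = np.asarray(labels, dtype=int)
        ok = np.isfinite(x1) & np.isfinite(x2)
        self.n_used = int(ok.sum())
        x1, x2, labels = x1[ok], x2[ok], labels[ok]
        if len(np.unique(labels)) < 2:
            raise ValueError("both classes must be present")
        X = np.column_stack([x1, x2])
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.sd_
        self.separation_flag = False
        try:
            beta, self.llf, converged = _fit_logistic(Z, labels)
            if not converged or np.any(np.abs(beta) > 1e3):
                raise RuntimeError("separation suspected")
        except Exception:
            beta, self.llf, _ = _fit_logistic(Z, labels, ridge=ridge_fallback)
            self.separation_flag = True
        self.beta_std_ = beta
        # back-transform to the original predictor scale
        self.coef_ = beta[1:] / self.sd_
        self.intercept_ = float(beta[0] - np.sum(beta[1:] * self.mean_ / self.sd_))
        self.names = tuple(names)
        probs = self.predict_proba(x1, x2)
        roc = roc_single(probs, labels, min_n=2)
        # probabilities are oriented toward the positive class already;
        # keep the higher-is-positive sweep regardless of AUC direction
        self.prob_cutoff, self.accuracy, self.sensitivity, self.specificity = _accuracy_sweep(
            probs, labels, higher_is_positive=True
        )
        self.labels_ = labels
        self.train_probs_ = probs

    def predict_proba(self, x1, x2):
        from scipy.special import expit

        X = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
        return expit(self.intercept_ + X @ self.coef_)

    def predict(self, x1, x2):
        return (self.predict_proba(x1, x2) > self.prob_cutoff).astype(int)

    @property
    def deviance(self):
        return -2.0 * self.llf


def fit_combo(
    x1, x2, labels, names=("x1", "x2"), m_bonferroni: int | None = None
) -> ComboModelResult:
    """Two-parameter logistic combination model.

    Predictors are z-scored internally (coefficients reported on the
    original scale); fitted probabilities are scored by the same
    accuracy-maximal cut-off rule as single parameters; the confusion table
    at that cut-off feeds Fisher's exact test.  Subjects with non-finite
    predictors are dropped.  Perfect separation or non-convergence triggers
    a flagged ridge (1e-6) refit.
    """
    fit = _ComboFit(x1, x2, labels, names)
    pred = (fit.train_probs_ > fit.prob_cutoff).astype(int)
    y = fit.labels_
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    p = fisher_exact_2x2(np.array([[tp, fn], [fp, tn]]))
    return ComboModelResult(
        parameters=fit.names,
        coefficients=fit.coef_,
        intercept=fit.intercept_,
        prob_cutoff=fit.prob_cutoff,
        accuracy=fit.accuracy,
        sensitivity=fit.sensitivity,
        specificity=fit.specificity,
        fisher_p=p,
        fisher_p_bonferroni=bonferroni(p, m_bonferroni) if m_bonferroni else None,
        separation_flag=fit.separation_flag,
        n_used=fit.n_used,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test: sum of hypergeometric probabilities of
    all tables with the observed margins that are no more probable than the
    observed one."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table < 0) or not np.allclose(table, np.round(table)):
            raise ValueError("counts must be non-negative integers")
        table = np.round(table).astype(int)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def crossvalidate(x1, x2, labels, k: int, seed: int) -> float:
    """Pooled stratified k-fold cross-validated accuracy of the pair model.

    Per fold the logistic model *and* its probability cut-off come from the
    training folds only; held-out subjects are then classified and the
    pooled fraction correct is returned.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ok = np.isfinite(x1) & np.isfinite(x2)
    x1, x2, labels = x1[ok], x2[ok], labels[ok]
    n1 = labels.sum()
    n0 = len(labels) - n1
    if k > min(n0, n1):
        raise ValueError(f"k={k} exceeds the smaller class size {min(n0, n1)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(np.zeros(len(labels)), labels):
        fit = _ComboFit(x1[train], x2[train], labels[train])
        pred = fit.predict(x1[test], x2[test])
        correct += int(np.sum(pred == labels[test]))
    return correct / len(labels)


def run_model_search(
    table: pd.DataFrame,
    standard_params: list[str] | None = None,
    texture_params: list[str] | None = None,
    cv_folds: tuple[int, ...] = (5, 10),
    cv_seed: int = 17,
    m_bonferroni: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exhaustive search over single parameters and allowed pairs.

    Singles: ROC analysis of every standard and texture parameter.  Pairs:
    logistic combinations of the six standard-standard pairs and every
    standard-texture pair.  ``m_bonferroni`` defaults to the number of
    combination models evaluated.  Cross-validation is run for the
    accuracy-ranked best pair only (matching how the protocol validates
    "the best model").  Returns a ranked DataFrame.
    """
    if standard_params is None:
        standard_params = [c for c in STANDARD_PARAM_NAMES if c in table.columns]
    if texture_params is None:
        excluded = set(standard_params) | {"subject_id", "label", "btv_voxels", "btv_ml"}
        texture_params = [
            c for c in table.columns if c not in excluded and table[c].dtype.kind == "f"
        ]
    # columns that are entirely degenerate (all-NaN or constant) cannot enter models
    texture_params = [
        c for c in texture_params if np.isfinite(table[c]).sum() >= 4 and table[c].nunique() > 1
    ]
    labels = table["label"].to_numpy(dtype=int)

    rows = []
    for name in standard_params + texture_params:
        vals = table[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if len(np.unique(labels[ok])) < 2:
            continue
        roc = roc_single(vals[ok], labels[ok])
        rows.append(
            {
                "param1": name,
                "param2": "",
                "kind": "single",
                "accuracy": roc.accuracy,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "auc": roc.auc,
                "auc_se": roc.auc_se,
                "p": roc.p,
            }
        )

    pairs = []
    for i, a in enumerate(standard_params):
        for b in standard_params[i + 1 :]:
            pairs.append((a, b))
    for a in standard_params:
        for b in texture_params:
            pairs.append((a, b))
    m = m_bonferroni if m_bonferroni is not None else len(pairs)

    for a, b in pairs:
        res = fit_combo(table[a].to_numpy(float), table[b].to_numpy(float), labels, names=(a, b))
        rows.append(
            {
                "param1": a,
                "param2": b,
                "kind": "pair",
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "auc": np.nan,
                "auc_se": np.nan,
                "p": res.fisher_p,
                "fisher_p_bonf": bonferroni(res.fisher_p, m),
                "separation_flag": res.separation_flag,
            }
        )

    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["accuracy", "kind"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    for k in cv_folds:
        df[f"cv{k}"] = np.nan
    best_pair = df[df["kind"] == "pair"]
    if not best_pair.empty:
        top = best_pair.iloc[0]
        x1 = table[top["param1"]].to_numpy(float)
        x2 = table[top["param2"]].to_numpy(float)
        for k in cv_folds:
            try:
                df.loc[top.name, f"cv{k}"] = crossvalidate(x1, x2, labels, k=k, seed=cv_seed)
            except ValueError:
                # smaller class too small for k folds: leave NaN
                continue
    return df
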