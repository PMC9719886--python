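"""Univariable screening and forward logistic modeling.

The study screens candidate predictors of nodal metastasis at a univariable
threshold of P < 0.001, then builds multivariable binary logistic models by
forward selection, entering candidates in ascending univariable-p order and
retaining each only if it improves the model by a likelihood-ratio test.
Because raw ROD values are small and a *smaller* ROD means *greater*
similarity (hence higher metastasis odds), ROD predictors enter the models
through the transform ``10 * (1 - rod)``, which makes the association
positive and puts the odds ratio on an interpretable per-unit scale.

The logistic fit itself is iteratively reweighted least squares (Newton
scoring with step-halving, so the log-likelihood is non-decreasing across
iterations), with Wald standard errors from the observed information and
``OR = exp(beta)``, ``CI = exp(beta +/- 1.96 SE)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatsError, compare_groups

__all__ = [
    "ModelError",
    "SeparationError",
    "CollinearityError",
    "Candidate",
    "LogisticModelSpec",
    "LogisticFit",
    "rod_transform",
    "fit_logistic",
    "likelihood_ratio_test",
    "univariable_screen",
    "forward_select",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ModelError(ValueError):
    """Invalid modeling input."""


class SeparationError(ModelError):
    """Complete or quasi-complete separation: MLE does not exist."""


class CollinearityError(ModelError):
    """Collinear predictors in the design matrix."""


def rod_transform(rod):
    """Similarity scale for ROD predictors: ``10 * (1 - rod)``.

    A ROD of 0 (node identical to lesion) maps to 10; a ROD of 1 maps to 0.
    Raises ``ValueError`` for negative input (RODs are nonnegative by
    construction).
    """
    r = np.asarray(rod, dtype=float)
    if np.any(r < 0):
        raise ValueError("ROD values must be >= 0")
    out = 10.0 * (1.0 - r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Candidate:
    """A candidate predictor for screening / selection.

    ``kind`` selects the univariable screen test ('continuous' ->
    Mann-Whitney, 'categorical' -> Fisher / chi-squared); ``transform`` is
    'identity' or 'rod_transform' (applied when the candidate enters a
    logistic design).
    """

    name: str
    kind: str = "continuous"
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ModelError(f"unknown candidate kind {self.kind!r}")
        if self.transform not in ("identity", "rod_transform"):
            raise ModelError(f"unknown transform {self.transform!r}")

    def design_column(self, cohort: pd.DataFrame) -> np.ndarray:
        x = cohort[self.name].to_numpy(dtype=float)
        if self.transform == "rod_transform":
            x = rod_transform(x)
        return x


@dataclass(frozen=True)
class LogisticModelSpec:
    """Outcome, candidates and selection rules for forward modeling."""

    outcome: str
    candidates: Tuple[Candidate, ...]
    entry_threshold: float = 0.001
    stay_alpha: float = 0.05
    max_terms: Optional[int] = None  # default: floor(events / 10)

    def __post_init__(self) -> None:
        if not 0.0 < self.entry_threshold <= 1.0:
            raise ModelError("entry_threshold must lie in (0, 1]")
        names = [c.name for c in self.candidates]
        if len(names) != len(set(names)):
            raise ModelError("candidate names must be distinct")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit summary (intercept first)."""

    terms: Tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    loglik_trace: Tuple[float, ...]
    converged: bool
    n_obs: int
    n_iter: int

    def summary_frame(self) -> pd.DataFrame:
        """Per-term table in the style of a published OR table."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    for j, nm in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ModelError(f"predictor {nm!r} is constant")
    if len(names) >= 2:
        corr = np.corrcoef(X, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise CollinearityError(
                        f"predictors {names[i]!r} and {names[j]!r} are collinear"
                    )
    full = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise CollinearityError(f"design matrix with terms {list(names)} is rank-deficient")


def fit_logistic(
    design,
    outcome,
    names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Fit a binary logistic model by IRLS with an intercept.

    Parameters
    ----------
    design : DataFrame or 2-D array
        Predictor columns (no intercept; one is added).
    outcome : 1-D binary array
    names : sequence of str, optional
        Predictor names (taken from DataFrame columns when available).

    Notes
    -----
    Newton scoring with step-halving guarantees a non-decreasing
    log-likelihood trace.  If the coefficients diverge (complete or
    quasi-complete separation) the fit is returned with
    ``converged=False`` after raising no silent garbage: callers should
    inspect the flag; ``SeparationError`` is raised only when the Hessian
    becomes numerically singular.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns) if names is None else list(names)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != y.size:
        raise ModelError("design and outcome lengths differ")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ModelError(f"outcome must be binary 0/1 with both classes, got {classes}")
    _check_design(X, names)

    Xd = np.column_stack([np.ones(X.shape[0]), X])
    k = Xd.shape[1]
    beta = np.zeros(k)

    def loglik(b):
        eta = Xd @ b
        # log(1 + e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        score = Xd.T @ (y - p)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular (complete separation or "
                "degenerate design)"
            ) from exc
        # step-halving keeps the log-likelihood monotone
        alpha = 1.0
        new_ll = loglik(beta + alpha * step)
        while new_ll < ll - 1e-12 and alpha > 1e-8:
            alpha /= 2.0
            new_ll = loglik(beta + alpha * step)
        beta = beta + alpha * step
        trace.append(new_ll)
        if abs(new_ll - ll) < tol and np.max(np.abs(score)) < 1e-6:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if np.max(np.abs(beta)) > 30:
        # fitted log-odds this extreme mean separation: flag, don't trust SEs
        converged = False

    eta = Xd @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("observed information not invertible") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # diverged (separated) fits overflow to inf
        odds_ratio = np.exp(beta)
        ci_low = np.exp(beta - Z_95 * se)
        ci_high = np.exp(beta + Z_95 * se)
    return LogisticFit(
        terms=tuple(["intercept"] + list(names)),
        coef=beta,
        se=se,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=pvals,
        log_likelihood=ll,
        loglik_trace=tuple(trace),
        converged=converged,
        n_obs=int(y.size),
        n_iter=it,
    )


def likelihood_ratio_test(fit_full: LogisticFit, fit_reduced: LogisticFit) -> float:
    """LRT p-value for nested fits (full vs reduced)."""
    df = len(fit_full.terms) - len(fit_reduced.terms)
    if df <= 0:
        raise ModelError("fit_full must have more terms than fit_reduced")
    lr = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    return float(sps.chi2.sf(max(lr, 0.0), df))


def _null_fit(y: np.ndarray) -> LogisticFit:
    """Intercept-only fit (closed form)."""
    y = np.asarray(y, dtype=float)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ModelError("outcome has a single class")
    b0 = math.log(pbar / (1 - pbar))
    n = y.size
    ll = float(n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
    se0 = math.sqrt(1.0 / (n * pbar * (1 - pbar)))
    return LogisticFit(
        terms=("intercept",),
        coef=np.array([b0]),
        se=np.array([se0]),
        odds_ratio=np.array([math.exp(b0)]),
        ci_low=np.array([math.exp(b0 - Z_95 * se0)]),
        ci_high=np.array([math.exp(b0 + Z_95 * se0)]),
        p_values=np.array([2.0 * sps.norm.sf(abs(b0 / se0))]),
        log_likelihood=ll,
        loglik_trace=(ll,),
        converged=True,
        n_obs=int(n),
        n_iter=0,
    )


def univariable_screen(
    cohort: pd.DataFrame,
    candidates: Sequence[Candidate],
    threshold: float = 0.001,
    outcome: str = "group",
) -> List[Tuple[Candidate, float]]:
    """Univariable p per candidate, filtered at ``threshold``, ascending.

    Continuous candidates are screened with the Mann-Whitney U test between
    outcome groups, categorical ones with Fisher / chi-squared, mirroring the
    univariable comparison tables.
    """
    results = []
    for cand in candidates:
        comp = compare_groups(cohort, cand.name, cand.kind, group_col=outcome)
        results.append((cand, comp.p_value))
    passed = [(c, p) for c, p in results if p < threshold]
    passed.sort(key=lambda cp: cp[1])
    return passed


def forward_select(
    spec: LogisticModelSpec, cohort: pd.DataFrame
) -> Tuple[List[str], LogisticFit, List[dict]]:
    """Forward selection with a likelihood-ratio stay test.

    Candidates passing the univariable screen enter in ascending-p order;
    each is retained only if the LRT p of its addition is below
    ``spec.stay_alpha``.  The number of retained terms is capped at
    ``floor(events / 10)`` (events = size of the smaller outcome class)
    unless ``spec.max_terms`` overrides it.  Returns the selected candidate
    names, the final fit (intercept-only if nothing is selected), and a
    trace recording every decision.
    """
    y = cohort[spec.outcome].to_numpy(dtype=float)
    events = int(min((y == 1).sum(), (y == 0).sum()))
    cap = spec.max_terms if spec.max_terms is not None else max(events // 10, 1)

    screened = univariable_screen(
        cohort, spec.candidates, spec.entry_threshold, outcome=spec.outcome
    )
    trace: List[dict] = []
    selected: List[Candidate] = []
    current = _null_fit(y)
    for step, (cand, up) in enumerate(screened, start=1):
        entry = {"step": step, "candidate": cand.name, "univariable_p": up}
        if len(selected) >= cap:
            entry.update(action="skipped", reason=f"events-per-variable cap ({cap}) reached")
            trace.append(entry)
            continue
        cols = {c.name: c.design_column(cohort) for c in selected + [cand]}
        design = pd.DataFrame(cols)
        try:
            fit = fit_logistic(design, y)
        except CollinearityError as exc:
            entry.update(action="rejected", reason=f"collinear: {exc}")
            trace.append(entry)
            continue
        if not fit.converged:
            entry.update(action="rejected", reason="non-convergent fit (separation)")
            trace.append(entry)
            continue
        p_lrt = likelihood_ratio_test(fit, current)
        entry["lrt_p"] = p_lrt
        if p_lrt < spec.stay_alpha:
            selected.append(cand)
            current = fit
            entry.update(action="retained")
        else:
            entry.update(action="rejected", reason="likelihood-ratio stay test failed")
        trace.append(entry)

    if not screened:
        trace.append(
            {
                "step": 0,
                "candidate": None,
                "action": "empty-model",
                "reason": f"no candidate passed the univariable screen "
                f"(threshold {spec.entry_threshold})",
            }
        )
    return [c.name for c in selected], current, trace
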