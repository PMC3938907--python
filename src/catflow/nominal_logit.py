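"""Nominal (multinomial) logistic regression by maximum likelihood.

Fits ``log(pi_j / pi_ref) = x' beta_j`` for outcome levels ``j`` against a
reference level, by Newton-Raphson with analytic score and observed
information and step-halving.  Rows may carry a per-row mask of *permitted*
outcome levels: structurally impossible outcomes (e.g. becoming a never
smoker after smoking) are excluded from the soft-max normalisation, which is
equivalent to fixing their coefficients at minus infinity so the fitted
probability is exactly zero.

Both model-based and cluster-robust (sandwich) covariance matrices are
computed; with one row per cluster the sandwich reduces to the HC0
heteroskedasticity-robust estimator.

Fit diagnostics used for lag selection and predictability assessment live
here too: McFadden's pseudo R-squared, percentage log-likelihood increases,
the proportion of correct modal predictions, and variance inflation factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignResponse",
    "NominalFit",
    "fit",
    "robust_vcov",
    "rrr_table",
    "mcfadden_r2",
    "pseudo_r2",
    "percent_ll_increase",
    "proportion_correct",
    "vif",
]

logger = logging.getLogger(__name__)

# linear predictors beyond this are treated as evidence of separation
_SEPARATION_ETA = 30.0


@dataclass
class DesignResponse:
    """Design matrix and categorical response for a nominal-logit fit.

    Attributes
    ----------
    X:
        n × p real design matrix, intercept column included.
    y:
        n vector of observed outcome level codes (indices into ``levels``).
    levels:
        Outcome level labels, length J.
    cluster:
        n vector of cluster (subject) identifiers for the robust variance;
        defaults to one cluster per row.
    allowed:
        n × J boolean mask of permitted outcome levels; ``False`` marks a
        structural zero.  Defaults to all permitted.
    weights:
        Optional non-negative frequency weights (counts-table fitting).
    colnames:
        Names for the columns of ``X``.
    """

    X: np.ndarray
    y: np.ndarray
    levels: tuple[str, ...]
    cluster: np.ndarray | None = None
    allowed: np.ndarray | None = None
    weights: np.ndarray | None = None
    colnames: tuple[str, ...] | None = None
    row_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        J = len(self.levels)
        if self.y.shape != (n,):
            raise ValueError("y length does not match X")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= J):
            raise ValueError("y contains codes outside 0..J-1")
        if self.allowed is None:
            self.allowed = np.ones((n, J), dtype=bool)
        else:
            self.allowed = np.asarray(self.allowed, dtype=bool)
            if self.allowed.shape != (n, J):
                raise ValueError("allowed mask has wrong shape")
        if not self.allowed[np.arange(n), self.y].all():
            bad = int(np.flatnonzero(~self.allowed[np.arange(n), self.y])[0])
            raise ValueError(
                f"row {bad}: observed outcome {self.levels[self.y[bad]]!r} is "
                "masked as structurally impossible; recode the data first "
                "(e.g. reclassify_monotone)"
            )
        if self.cluster is None:
            self.cluster = np.arange(n)
        else:
            self.cluster = np.asarray(self.cluster)
            if self.cluster.shape != (n,):
                raise ValueError("cluster length does not match X")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,) or (self.weights < 0).any():
                raise ValueError("weights must be a non-negative n-vector")
        if self.colnames is None:
            self.colnames = tuple(f"x{k}" for k in range(p))
        else:
            self.colnames = tuple(self.colnames)
            if len(self.colnames) != p:
                raise ValueError("colnames length does not match X columns")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class NominalFit:
    """Result of a nominal-logit maximum-likelihood fit.

    ``beta`` has one row per non-reference level (in ``coef_levels`` order)
    and one column per design column; the reference level's coefficients are
    implicitly zero.  ``vcov_model`` and ``vcov_robust`` cover the stacked
    coefficient vector ``beta.ravel()`` (level-major).
    """

    beta: np.ndarray
    reference: str
    levels: tuple[str, ...]
    coef_levels: tuple[str, ...]
    colnames: tuple[str, ...]
    vcov_model: np.ndarray
    vcov_robust: np.ndarray
    loglik: float
    loglik_null: float
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int
    free_mask: np.ndarray | None = None  # (K, p) bool; False = constrained to 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.free_mask is None:
            self.free_mask = np.ones(self.beta.shape, dtype=bool)

    @property
    def n_params(self) -> int:
        return self.beta.size

    def se(self, vcov: str = "robust") -> np.ndarray:
        """Standard errors, shaped like ``beta``."""
        V = self.vcov_robust if vcov == "robust" else self.vcov_model
        return np.sqrt(np.clip(np.diag(V), 0.0, None)).reshape(self.beta.shape)

    def predict_proba(
        self, X: np.ndarray, allowed: np.ndarray | None = None
    ) -> np.ndarray:
        """Fitted probabilities for each row of ``X`` over all J levels."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if allowed is None:
            allowed = np.ones((X.shape[0], len(self.levels)), dtype=bool)
        eta = _linear_predictors(X, self.beta, self.levels, self.coef_levels)
        return _softmax_masked(eta, np.asarray(allowed, dtype=bool))

    def summary_frame(self, level_of_ci: float = 0.95) -> pd.DataFrame:
        """TSV-ready coefficient summary on the RRR scale."""
        return rrr_table(self, level_of_ci=level_of_ci)


def _coef_level_order(levels: Sequence[str], reference: str) -> tuple[str, ...]:
    if reference not in levels:
        raise ValueError(f"reference {reference!r} is not an outcome level")
    return tuple(l for l in levels if l != reference)


def _linear_predictors(
    X: np.ndarray,
    beta: np.ndarray,
    levels: Sequence[str],
    coef_levels: Sequence[str],
) -> np.ndarray:
    """n × J linear predictors; reference level fixed at zero."""
    n = X.shape[0]
    eta = np.zeros((n, len(levels)))
    for k, lvl in enumerate(coef_levels):
        eta[:, list(levels).index(lvl)] = X @ beta[k]
    return eta

def _softmax_masked(eta: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Row-wise soft-max restricted to permitted levels (others exactly 0)."""
    work = np.where(allowed, eta, -np.inf)
    m = work.max(axis=1, keepdims=True)
    ex = np.exp(work - m)
    ex[~allowed] = 0.0
    return ex / ex.sum(axis=1, keepdims=True)


def _loglik(eta, allowed, y, w) -> float:
    work = np.where(allowed, eta, -np.inf)
    m = work.max(axis=1)
    lse = m + np.log(np.exp(work - m[:, None]).sum(axis=1))
    return float(np.sum(w * (eta[np.arange(len(y)), y] - lse)))


def _score_info(X, P, Yind, w, need_info=True):
    """Score vector and observed information for the stacked coefficients."""
    n, p = X.shape
    K = Yind.shape[1]
    E = Yind - P  # n × K residuals on the coef levels
    g = ((w[:, None] * E).T @ X).reshape(-1)
    if not need_info:
        return g, None
    A = np.empty((K * p, K * p))
    for j in range(K):
        for k in range(j, K):
            d = w * (P[:, j] * ((1.0 if j == k else 0.0) - P[:, k]))
            block = X.T @ (d[:, None] * X)
            A[j * p:(j + 1) * p, k * p:(k + 1) * p] = block
            if k != j:
                A[k * p:(k + 1) * p, j * p:(j + 1) * p] = block.T
    return g, A


def _solve_with_ridge(A: np.ndarray, g: np.ndarray, ridge: float):
    dim = A.shape[0]
    scale = max(np.trace(A) / dim, 1.0)
    lam = ridge
    for _ in range(8):
        try:
            return np.linalg.solve(A + lam * scale * np.eye(dim), g), lam
        except np.linalg.LinAlgError:
            lam = max(lam * 10.0, 1e-10)
    raise np.linalg.LinAlgError(
        "information matrix is singular even after ridge inflation; "
        "check for collinear predictors or pass a larger ridge option"
    )


def fit(
    data: DesignResponse,
    reference: str | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    ridge: float = 0.0,
    compute_null: bool = True,
    constraints: Sequence[tuple[str, str]] = (),
    metadata: dict | None = None,
) -> NominalFit:
    """Maximum-likelihood nominal-logit fit.

    Parameters
    ----------
    data:
        Design, response, permitted-level mask, clusters and weights.
    reference:
        Reference outcome level (defaults to the first level).
    max_iter, tol:
        Newton-Raphson is run until the maximum absolute score falls below
        ``tol`` or ``max_iter`` iterations; step-halving guarantees the
        likelihood never decreases.
    ridge:
        Diagonal inflation (relative to the information's mean diagonal)
        applied when solving the Newton step; automatically escalated if the
        information is singular.
    compute_null:
        Also fit the intercepts-only model on the same rows and mask, for
        McFadden's pseudo R-squared.
    constraints:
        ``(outcome_level, column_name)`` pairs whose coefficient is fixed at
        zero.  Needed when a structurally-masked outcome leaves a predictor
        without variation on the rows where that outcome is possible (e.g.
        lag indicators of ever-smoking in the never-smoker equation), which
        would otherwise make the information matrix singular.
    """
    if reference is None:
        reference = data.levels[0]
    coef_levels = _coef_level_order(data.levels, reference)
    levels = tuple(data.levels)
    K, p = len(coef_levels), data.X.shape[1]
    coef_idx = [levels.index(l) for l in coef_levels]
    Yind = np.column_stack([(data.y == j).astype(float) for j in coef_idx])
    # masked-out coef levels must not generate score: their P is 0 and their
    # Y indicator is 0 by the DesignResponse invariant, so no special case.
    free = np.ones((K, p), dtype=bool)
    for lvl, col in constraints:
        if lvl == reference:
            continue
        free[coef_levels.index(lvl), data.colnames.index(col)] = False
    free_idx = np.flatnonzero(free.ravel())

    beta = np.zeros((K, p))
    w = data.weights
    X, allowed, y = data.X, data.allowed, data.y

    eta = _linear_predictors(X, beta, levels, coef_levels)
    ll = _loglik(eta, allowed, y, w)
    converged = False
    separation_warned = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = _softmax_masked(eta, allowed)[:, coef_idx]
        g, A = _score_info(X, P, Yind, w)
        if np.max(np.abs(g[free_idx])) < tol:
            converged = True
            n_iter -= 1
            break
        step_free, _ = _solve_with_ridge(
            A[np.ix_(free_idx, free_idx)], g[free_idx], ridge
        )
        step = np.zeros(K * p)
        step[free_idx] = step_free
        scale = 1.0
        for _ in range(40):
            beta_new = beta + scale * step.reshape(K, p)
            eta_new = _linear_predictors(X, beta_new, levels, coef_levels)
            ll_new = _loglik(eta_new, allowed, y, w)
            if ll_new >= ll - 1e-10:
                break
            scale /= 2.0
        beta, eta, ll = beta_new, eta_new, ll_new
        finite_eta = np.abs(eta[allowed])
        if not separation_warned and finite_eta.size and finite_eta.max() > _SEPARATION_ETA:
            worst = np.unravel_index(np.argmax(np.abs(beta)), beta.shape)
            warnings.warn(
                "possible complete separation: linear predictor diverging, "
                f"driven by predictor {data.colnames[worst[1]]!r} "
                f"(outcome {coef_levels[worst[0]]!r})",
                stacklevel=2,
            )
            separation_warned = True
    if not converged:
        P = _softmax_masked(eta, allowed)[:, coef_idx]
        g, A = _score_info(X, P, Yind, w)
        converged = bool(np.max(np.abs(g[free_idx])) < tol)
        if not converged:
            warnings.warn(
                f"nominal-logit fit did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(g[free_idx])):.3g})",
                stacklevel=2,
            )

    # covariance over the free parameters, embedded with zero rows/columns
    # at the constrained positions
    A_free = A[np.ix_(free_idx, free_idx)]
    try:
        vcov_free = np.linalg.inv(A_free)
    except np.linalg.LinAlgError:
        warnings.warn(
            "information matrix singular at the optimum; using pseudo-inverse "
            "(consider the ridge option)",
            stacklevel=2,
        )
        vcov_free = np.linalg.pinv(A_free)
    vcov_model = np.zeros((K * p, K * p))
    vcov_model[np.ix_(free_idx, free_idx)] = 0.5 * (vcov_free + vcov_free.T)

    n_clusters = len(pd.unique(data.cluster))
    result = NominalFit(
        beta=beta,
        reference=reference,
        levels=levels,
        coef_levels=coef_levels,
        colnames=data.colnames,
        vcov_model=vcov_model,
        vcov_robust=np.empty((0, 0)),
        loglik=ll,
        loglik_null=np.nan,
        n_obs=data.n_obs,
        n_clusters=n_clusters,
        converged=converged,
        n_iter=n_iter,
        free_mask=free,
        metadata=dict(metadata or {}),
    )
    try:
        result.vcov_robust = robust_vcov(result, data)
    except np.linalg.LinAlgError:
        # separation or degenerate data can flatten the information; keep the
        # pinv-based sandwich rather than failing the whole fit
        warnings.warn(
            "information singular when forming the robust covariance; "
            "using a pseudo-inverse sandwich",
            stacklevel=2,
        )
        result.vcov_robust = robust_vcov(result, data, strict=False)

    if compute_null:
        null_data = DesignResponse(
            X=np.ones((data.n_obs, 1)),
            y=data.y,
            levels=levels,
            cluster=data.cluster,
            allowed=data.allowed,
            weights=data.weights,
            colnames=("const",),
        )
        null_fit = fit(
            null_data, reference, max_iter=max_iter, tol=tol, ridge=ridge,
            compute_null=False,
        )
        result.loglik_null = null_fit.loglik
    return result


def robust_vcov(
    fit_result: NominalFit, data: DesignResponse, strict: bool = True
) -> np.ndarray:
    """Cluster-robust sandwich covariance ``A^{-1} B A^{-1}``.

    ``A`` is the observed information; ``B`` sums, over clusters, the outer
    products of each cluster's summed per-row score contribution.  With one
    row per cluster this is HC0.  With ``strict=False`` a singular ``A`` is
    pseudo-inverted instead of raising.
    """
    levels = fit_result.levels
    coef_idx = [levels.index(l) for l in fit_result.coef_levels]
    eta = _linear_predictors(data.X, fit_result.beta, levels, fit_result.coef_levels)
    P = _softmax_masked(eta, data.allowed)[:, coef_idx]
    Yind = np.column_stack([(data.y == j).astype(float) for j in coef_idx])
    _, A = _score_info(data.X, P, Yind, data.weights)
    free_idx = np.flatnonzero(fit_result.free_mask.ravel())
    A_free = A[np.ix_(free_idx, free_idx)]
    try:
        Ainv = np.linalg.inv(A_free)
    except np.linalg.LinAlgError:
        if strict:
            raise np.linalg.LinAlgError(
                "observed information is singular; refit with the ridge option "
                "before requesting a robust covariance"
            )
        Ainv = np.linalg.pinv(A_free)
    E = (data.weights[:, None] * (Yind - P))  # n × K
    # per-row stacked score contribution, level-major: U[i] = E[i] ⊗ X[i]
    U = (E[:, :, None] * data.X[:, None, :]).reshape(data.n_obs, -1)
    codes, _ = pd.factorize(data.cluster)
    S = np.zeros((codes.max() + 1, U.shape[1]))
    np.add.at(S, codes, U)
    B = S[:, free_idx].T @ S[:, free_idx]
    V_free = Ainv @ B @ Ainv
    V = np.zeros_like(A)
    V[np.ix_(free_idx, free_idx)] = 0.5 * (V_free + V_free.T)
    return V


def rrr_table(
    fit_result: NominalFit,
    level_of_ci: float = 0.95,
    vcov: str = "robust",
) -> pd.DataFrame:
    """Relative risk ratios exp(beta) with Wald confidence intervals.

    One row per (outcome level, predictor); columns ``rrr``, ``ci_low``,
    ``ci_high``, ``se_log``, ``z``, ``p``.
    """
    z = stats.norm.ppf(0.5 + level_of_ci / 2.0)
    se = fit_result.se(vcov)
    rows = []
    for j, lvl in enumerate(fit_result.coef_levels):
        for k, name in enumerate(fit_result.colnames):
            b, s = fit_result.beta[j, k], se[j, k]
            zstat = b / s if s > 0 else np.nan
            rows.append(
                {
                    "outcome": lvl,
                    "predictor": name,
                    "rrr": np.exp(b),
                    "ci_low": np.exp(b - z * s),
                    "ci_high": np.exp(b + z * s),
                    "se_log": s,
                    "z": zstat,
                    "p": 2 * stats.norm.sf(abs(zstat)) if s > 0 else np.nan,
                    "constrained": not bool(fit_result.free_mask[j, k]),
                }
            )
    return pd.DataFrame(rows)


def pseudo_r2(loglik: float, loglik_null: float) -> float:
    """McFadden's pseudo R-squared, ``1 - loglik / loglik_null``."""
    if loglik_null == 0:
        return 0.0
    return 1.0 - loglik / loglik_null


def mcfadden_r2(fit_result: NominalFit) -> float:
    """McFadden's pseudo R-squared of a fit against its intercepts-only null."""
    if np.isnan(fit_result.loglik_null):
        raise ValueError("fit was computed without its null model")
    return pseudo_r2(fit_result.loglik, fit_result.loglik_null)


def percent_ll_increase(ll_sequence: Sequence[float]) -> list[float]:
    """Stepwise log-likelihood improvements as percentages of |null LL|.

    The first entry of ``ll_sequence`` is the null model's log-likelihood;
    each returned entry is ``100 * (ll_k - ll_{k-1}) / |ll_0|``, so the first
    returned value is McFadden's pseudo R-squared of step one in percent and
    later values are incremental gains on the same denominator.
    """
    lls = [float(v) for v in ll_sequence]
    if len(lls) < 2:
        raise ValueError("need the null log-likelihood and at least one model")
    denom = abs(lls[0])
    if denom == 0:
        raise ValueError("null log-likelihood of zero gives no meaningful scale")
    return [100.0 * (lls[k] - lls[k - 1]) / denom for k in range(1, len(lls))]


def proportion_correct(fit_result: NominalFit, data: DesignResponse) -> float:
    """Weighted share of rows whose observed level is the modal prediction.

    Ties in the modal probability are broken towards the lowest level code
    (logged at DEBUG level).
    """
    P = fit_result.predict_proba(data.X, data.allowed)
    pred = np.argmax(P, axis=1)  # argmax takes the first (lowest code) on ties
    near_tie = (np.abs(P - P.max(axis=1, keepdims=True)) < 1e-12).sum(axis=1) > 1
    if near_tie.any():
        logger.debug(
            "%d rows had tied modal probabilities; ties broken to the lowest level code",
            int(near_tie.sum()),
        )
    w = data.weights
    return float(np.sum(w * (pred == data.y)) / np.sum(w))


def vif(X: np.ndarray, colnames: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors, ``1 / (1 - R^2)`` per non-constant column.

    Each column is regressed by least squares on all other columns plus an
    intercept; constant (intercept-like) columns are skipped.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if colnames is None:
        colnames = [f"x{k}" for k in range(p)]
    out = {}
    const = np.ptp(X, axis=0) == 0
    for k in range(p):
        if const[k]:
            continue
        others = np.column_stack([np.ones(n), X[:, [j for j in range(p) if j != k]]])
        target = X[:, k]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = float(np.sum((target - target.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
        out[colnames[k]] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
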