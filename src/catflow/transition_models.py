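"""Lagged-status transition models for categorical panels.

The transition model regresses the current category on indicator variables
for category at one or more previous waves,

    log(pi_j / pi_ref) = b1_j + sum_over_lagged_indicators I(...) * b_j,

optionally including *joint* indicators such as "ex-smoker at both previous
waves".  Outcomes that are logically impossible given a subject's history
(re-entering an absorbing source level such as "never smoker") are handled
as structural zeros: the level is masked out of the soft-max normalisation
so its fitted probability is exactly zero.

Transition probabilities for covariate patterns (histories) come with
delta-method standard errors propagated from the cluster-robust coefficient
covariance, and lag depth is chosen with variance inflation factors and
percentage log-likelihood increases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import nominal_logit
from .data_model import _MISSING_CODE, CategoricalPanel, CategoryScheme
from .nominal_logit import DesignResponse, NominalFit, percent_ll_increase, vif

__all__ = [
    "LagSpec",
    "TransitionEstimates",
    "TreeNode",
    "ProbabilityTree",
    "build_lag_design",
    "fit_transition",
    "transition_probabilities",
    "transition_matrix",
    "select_lags",
    "probability_tree",
]


@dataclass(frozen=True)
class LagSpec:
    """Specification of the lagged-indicator design.

    Parameters
    ----------
    n_lags:
        How many previous waves enter the model (must be < number of waves).
    single_lags:
        Which lags receive a full set of per-level indicators; defaults to
        all of ``1..n_lags``.  The smoking-style model uses single indicators
        at lag 1 only, plus a joint indicator spanning lags 1-2.
    joint_indicators:
        Level sequences treated as single indicators, ordered lag-1 first:
        ``("ex", "ex")`` means "ex at the previous wave and ex two waves
        previously".
    coding:
        ``"additive"`` keeps single-lag indicators as plain indicators, so a
        joint effect multiplies on top of them; ``"mutually_exclusive"``
        zeroes the constituent single-lag indicators whenever the joint
        indicator fires, so each coefficient reads as an exclusive contrast.
        Both codings span the same column space and give identical fitted
        probabilities.
    lag_reference:
        Baseline level for the lag indicators (no indicator column); defaults
        to the outcome reference at fit time.
    structural_rules:
        Extra ``(outcome_level, predicate)`` pairs: the outcome level is
        masked (structural zero) for rows whose history, a tuple of labels
        ordered lag-1 first, satisfies the predicate.  The absorbing-source
        rule from the scheme is always applied automatically.
    """

    n_lags: int = 1
    single_lags: tuple[int, ...] | None = None
    joint_indicators: tuple[tuple[str, ...], ...] = ()
    coding: str = "additive"
    lag_reference: str | None = None
    structural_rules: tuple[tuple[str, Callable[[tuple], bool]], ...] = ()

    def __post_init__(self):
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.coding not in ("additive", "mutually_exclusive"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.single_lags is not None:
            object.__setattr__(self, "single_lags", tuple(self.single_lags))
            if any(not 1 <= l <= self.n_lags for l in self.single_lags):
                raise ValueError("single_lags must lie in 1..n_lags")
        joints = tuple(tuple(seq) for seq in self.joint_indicators)
        object.__setattr__(self, "joint_indicators", joints)
        if any(len(seq) > self.n_lags or not seq for seq in joints):
            raise ValueError("joint indicator sequences must have length 1..n_lags")

    @property
    def effective_single_lags(self) -> tuple[int, ...]:
        return self.single_lags if self.single_lags is not None else tuple(
            range(1, self.n_lags + 1)
        )


def _column_names(spec: LagSpec, scheme: CategoryScheme, lag_reference: str):
    names = ["const"]
    for lag in spec.effective_single_lags:
        for lvl in scheme.levels:
            if lvl != lag_reference:
                names.append(f"{lvl}[-{lag}]")
    for seq in spec.joint_indicators:
        names.append("&".join(f"{lvl}[-{i + 1}]" for i, lvl in enumerate(seq)))
    return tuple(names)


def _encode_histories(
    histories: Sequence[tuple[str, ...]],
    spec: LagSpec,
    scheme: CategoryScheme,
    lag_reference: str,
) -> np.ndarray:
    """Design rows for label histories ordered lag-1 first."""
    if lag_reference not in scheme.levels:
        raise ValueError(f"lag reference {lag_reference!r} is not a scheme level")
    n = len(histories)
    single_cols: list[np.ndarray] = []
    single_key: dict[tuple[int, str], int] = {}
    for lag in spec.effective_single_lags:
        for lvl in scheme.levels:
            if lvl == lag_reference:
                continue
            col = np.array(
                [1.0 if h[lag - 1] == lvl else 0.0 for h in histories]
            )
            single_key[(lag, lvl)] = len(single_cols)
            single_cols.append(col)
    joint_cols = []
    for seq in spec.joint_indicators:
        fired = np.array(
            [1.0 if all(h[i] == lvl for i, lvl in enumerate(seq)) else 0.0 for h in histories]
        )
        joint_cols.append(fired)
        if spec.coding == "mutually_exclusive":
            for i, lvl in enumerate(seq):
                idx = single_key.get((i + 1, lvl))
                if idx is not None:
                    single_cols[idx] = single_cols[idx] * (1.0 - fired)
    return np.column_stack([np.ones(n)] + single_cols + joint_cols)


def _allowed_for_history(
    history: tuple, scheme: CategoryScheme, spec: LagSpec
) -> np.ndarray:
    """Permitted-outcome mask for a history (tuple of labels, earliest last).

    Applies the absorbing-source rule from the scheme — the source level is
    impossible once any other level has been observed — plus any custom
    structural rules in the spec.
    """
    allowed = np.ones(scheme.n_levels, dtype=bool)
    src = scheme.monotone_absorbing_source
    if src is not None:
        for lvl in history:
            if isinstance(lvl, str) and lvl != src:
                allowed[scheme.index(src)] = False
                break
    for outcome, predicate in spec.structural_rules:
        if predicate(tuple(history)):
            allowed[scheme.index(outcome)] = False
    return allowed


def _target_wave_indices(panel: CategoricalPanel, spec: LagSpec, target_wave):
    if target_wave in ("last", None):
        return [panel.n_waves - 1]
    if target_wave == "pooled":
        return list(range(spec.n_lags, panel.n_waves))
    t = panel.wave_index(target_wave)
    if t < spec.n_lags:
        raise ValueError(
            f"target wave {target_wave} has fewer than {spec.n_lags} predecessors"
        )
    return [t]


def build_lag_design(
    panel: CategoricalPanel,
    spec: LagSpec,
    target_wave="last",
    lag_reference: str | None = None,
) -> DesignResponse:
    """Expand a panel into the lagged-indicator design.

    One row per subject-wave whose outcome and full lag window are observed.
    ``target_wave`` is a wave label, ``"last"``, or ``"pooled"`` (all eligible
    waves, for a pooled fit with subject-clustered variances).  Rows whose
    outcome level is impossible given the subject's earlier observed history
    get that level masked in the ``allowed`` matrix.
    """
    if spec.n_lags >= panel.n_waves:
        raise ValueError(
            f"n_lags={spec.n_lags} requires more than {panel.n_waves} waves"
        )
    lag_reference = lag_reference or spec.lag_reference or panel.scheme.levels[0]
    t_indices = _target_wave_indices(panel, spec, target_wave)
    scheme = panel.scheme
    histories: list[tuple[str, ...]] = []
    full_histories: list[tuple[str, ...]] = []
    y, cluster, meta = [], [], []
    for t in t_indices:
        for i in range(panel.n_subjects):
            c_out = panel.codes[i, t]
            lag_codes = panel.codes[i, t - spec.n_lags:t][::-1]  # lag-1 first
            if c_out == _MISSING_CODE or (lag_codes == _MISSING_CODE).any():
                continue
            hist = tuple(scheme.levels[c] for c in lag_codes)
            earlier = panel.codes[i, :t][::-1]
            full = tuple(
                scheme.levels[c] for c in earlier if c != _MISSING_CODE
            )
            histories.append(hist)
            full_histories.append(full)
            y.append(int(c_out))
            cluster.append(i)
            meta.append((panel.subject_ids[i], panel.waves[t]))
    if not histories:
        raise ValueError("no rows with complete lag histories")
    for lag in spec.effective_single_lags:
        seen = {h[lag - 1] for h in histories}
        if lag_reference not in seen:
            raise ValueError(
                f"lag reference {lag_reference!r} never observed at lag {lag}; "
                f"choose one of {sorted(seen)} instead"
            )
    X = _encode_histories(histories, spec, scheme, lag_reference)
    allowed = np.array(
        [_allowed_for_history(h, scheme, spec) for h in full_histories]
    )
    return DesignResponse(
        X=X,
        y=np.array(y),
        levels=scheme.levels,
        cluster=np.array(cluster),
        allowed=allowed,
        colnames=_column_names(spec, scheme, lag_reference),
        row_meta=pd.DataFrame(meta, columns=["subject", "wave"]),
    )


def _auto_constraints(data: DesignResponse, reference: str) -> list[tuple[str, str]]:
    """Coefficients made unidentifiable by structural zeros.

    A lag-indicator coefficient for outcome level j carries no information
    when the column does not vary over the rows where level j is permitted —
    e.g. the never-smoker equation only involves rows with an all-"never"
    history, where every ever-smoking indicator is identically zero.  Such
    coefficients are fixed (structurally) at zero, mirroring how the
    impossible transitions carry probability zero.
    """
    out: list[tuple[str, str]] = []
    for j, lvl in enumerate(data.levels):
        if lvl == reference:
            continue
        rows = data.allowed[:, j]
        if rows.all() or not rows.any():
            continue
        for k, name in enumerate(data.colnames):
            col = data.X[:, k]
            if np.ptp(col) > 0 and np.ptp(col[rows]) == 0:
                out.append((lvl, name))
    return out


def fit_transition(
    panel: CategoricalPanel,
    spec: LagSpec | None = None,
    reference: str | None = None,
    target_wave="last",
    **fit_options,
) -> NominalFit:
    """Fit the lagged-status transition model on a panel.

    Delegates to :func:`catflow.nominal_logit.fit` on the design from
    :func:`build_lag_design`; the spec, lag reference and the panel's
    first-wave distribution are recorded in the fit metadata (the latter so
    a fitted first-order chain can be turned back into a simulation spec).
    """
    spec = spec or LagSpec(1)
    if reference is None:
        reference = panel.scheme.levels[0]
    lag_reference = spec.lag_reference or reference
    data = build_lag_design(panel, spec, target_wave, lag_reference)
    constraints = list(fit_options.pop("constraints", ()))
    constraints += _auto_constraints(data, reference)
    result = nominal_logit.fit(data, reference, constraints=constraints, **fit_options)
    first = panel.codes[:, 0]
    obs = first[first != _MISSING_CODE]
    initial = np.bincount(obs, minlength=panel.scheme.n_levels) / max(len(obs), 1)
    result.metadata.update(
        {
            "kind": "transition",
            "spec": spec,
            "scheme": panel.scheme,
            "lag_reference": lag_reference,
            "target_wave": target_wave,
            "waves": panel.waves,
            "initial_dist": initial,
        }
    )
    return result


@dataclass(frozen=True)
class TransitionEstimates:
    """Per-history outcome probabilities with delta-method uncertainty.

    ``table`` has one row per (history, outcome level) with columns
    ``history`` (tuple, lag-1 first), ``outcome``, ``prob``, ``se``,
    ``ci_low``, ``ci_high``.  Within each history the probabilities sum to
    one over permitted levels; structurally excluded levels carry probability
    0 with SE 0.
    """

    table: pd.DataFrame
    level_of_ci: float
    scale: str

    def pivot(self, column: str = "prob") -> pd.DataFrame:
        return self.table.pivot(index="history", columns="outcome", values=column)

    def to_tsv(self, target) -> None:
        out = self.table.copy()
        out["history"] = out["history"].map(lambda h: "|".join(h))
        out.to_csv(target, sep="\t", index=False)


def transition_probabilities(
    fit: NominalFit,
    patterns: Sequence[tuple[str, ...]] | None = None,
    level_of_ci: float = 0.95,
    scale: str = "linear",
    vcov: str = "robust",
) -> TransitionEstimates:
    """Outcome probabilities for covariate patterns, with delta-method CIs.

    Probabilities are the masked soft-max of the fitted linear predictors;
    the SE propagates the coefficient covariance ``V`` through the gradient
    ``g`` of each probability, ``se = sqrt(g' V g)``.  ``scale="linear"``
    gives symmetric intervals truncated to [0, 1]; ``scale="logit"``
    transforms a symmetric interval on the log-odds scale, which keeps
    intervals inside (0, 1) and allows asymmetry near the boundaries.
    """
    md = fit.metadata
    if "spec" not in md:
        raise ValueError("fit does not carry transition-model metadata")
    spec: LagSpec = md["spec"]
    scheme: CategoryScheme = md["scheme"]
    lag_reference: str = md["lag_reference"]
    if scale not in ("linear", "logit"):
        raise ValueError(f"scale must be 'linear' or 'logit', got {scale!r}")
    if patterns is None:
        patterns = list(itertools.product(scheme.levels, repeat=spec.n_lags))
    patterns = [tuple(p) for p in patterns]
    for p in patterns:
        if len(p) != spec.n_lags:
            raise ValueError(
                f"pattern {p} has length {len(p)}; the model uses {spec.n_lags} lags"
            )
    X = _encode_histories(patterns, spec, scheme, lag_reference)
    V = fit.vcov_robust if vcov == "robust" else fit.vcov_model
    z = stats.norm.ppf(0.5 + level_of_ci / 2.0)
    levels = list(fit.levels)
    coef_idx = [levels.index(l) for l in fit.coef_levels]
    K, p = fit.beta.shape
    rows = []
    for r, pattern in enumerate(patterns):
        allowed = _allowed_for_history(pattern, scheme, spec)
        pi = fit.predict_proba(X[r], allowed[None, :])[0]
        for m, lvl in enumerate(levels):
            if not allowed[m]:
                rows.append(
                    {"history": pattern, "outcome": lvl, "prob": 0.0, "se": 0.0,
                     "ci_low": 0.0, "ci_high": 0.0}
                )
                continue
            # d pi_m / d beta_j = pi_m (1{m=j} - pi_j) x
            g = np.empty((K, p))
            for jpos, cj in enumerate(coef_idx):
                g[jpos] = pi[m] * ((1.0 if cj == m else 0.0) - pi[cj]) * X[r]
            gv = g.reshape(-1)
            se = float(np.sqrt(max(gv @ V @ gv, 0.0)))
            if scale == "linear":
                lo, hi = max(pi[m] - z * se, 0.0), min(pi[m] + z * se, 1.0)
            else:
                if se == 0.0 or pi[m] <= 0.0 or pi[m] >= 1.0:
                    lo = hi = pi[m]
                else:
                    se_logit = se / (pi[m] * (1.0 - pi[m]))
                    lo = float(expit(logit(pi[m]) - z * se_logit))
                    hi = float(expit(logit(pi[m]) + z * se_logit))
            rows.append(
                {"history": pattern, "outcome": lvl, "prob": float(pi[m]),
                 "se": se, "ci_low": lo, "ci_high": hi}
            )
    return TransitionEstimates(pd.DataFrame(rows), level_of_ci, scale)


def transition_matrix(fit: NominalFit) -> pd.DataFrame:
    """J × J one-step transition probability matrix from a first-order fit."""
    md = fit.metadata
    spec: LagSpec = md.get("spec") or LagSpec(1)
    if spec.n_lags != 1:
        raise ValueError("transition_matrix needs a first-order (n_lags=1) fit")
    est = transition_probabilities(fit)
    mat = est.pivot("prob")
    mat.index = [h[0] for h in mat.index]
    levels = list(fit.levels)
    return mat.loc[levels, levels]


def select_lags(
    panel: CategoricalPanel,
    max_lags: int = 3,
    vif_threshold: float = 5.0,
    ll_threshold_pct: float = 1.0,
    reference: str | None = None,
    target_wave="last",
    **fit_options,
) -> tuple[LagSpec, pd.DataFrame]:
    """Choose the lag depth via VIFs and percentage log-likelihood gains.

    Fits models of depth ``1..max_lags`` on a common row set (subjects with
    the full ``max_lags`` window observed at the target wave, so that the
    log-likelihoods are comparable) and tabulates, per depth, the maximum
    VIF across indicator columns and the incremental log-likelihood gain as
    a percentage of |null log-likelihood|.  The recommended depth is the
    deepest consecutive depth whose max VIF stays below ``vif_threshold``
    and whose incremental gain is at least ``ll_threshold_pct`` (depth 1 is
    always admissible).
    """
    if max_lags >= panel.n_waves:
        raise ValueError("max_lags must be smaller than the number of waves")
    if reference is None:
        reference = panel.scheme.levels[0]
    # common row set: restrict to subjects observed over the deepest window
    deep = LagSpec(max_lags, lag_reference=reference)
    deep_design = build_lag_design(panel, deep, target_wave, reference)
    keep_keys = set(map(tuple, deep_design.row_meta.to_numpy()))

    lls, max_vifs, fits = [], [], []
    for d in range(1, max_lags + 1):
        spec_d = LagSpec(d, lag_reference=reference)
        design = build_lag_design(panel, spec_d, target_wave, reference)
        keep = np.array(
            [tuple(r) in keep_keys for r in design.row_meta.to_numpy()]
        )
        design = DesignResponse(
            X=design.X[keep], y=design.y[keep], levels=design.levels,
            cluster=design.cluster[keep], allowed=design.allowed[keep],
            colnames=design.colnames, row_meta=design.row_meta[keep],
        )
        f = nominal_logit.fit(design, reference, compute_null=(d == 1), **fit_options)
        if d == 1:
            ll_null = f.loglik_null
        lls.append(f.loglik)
        v = vif(design.X[:, 1:], design.colnames[1:])
        max_vifs.append(float(v.max()) if len(v) else 1.0)
        fits.append(f)
    pct = percent_ll_increase([ll_null] + lls)
    diag = pd.DataFrame(
        {
            "n_lags": np.arange(1, max_lags + 1),
            "loglik": lls,
            "pct_ll_step": pct,
            "max_vif": max_vifs,
            "converged": [f.converged for f in fits],
        }
    )
    recommended = 1
    for d in range(2, max_lags + 1):
        if max_vifs[d - 1] < vif_threshold and pct[d - 1] >= ll_threshold_pct:
            recommended = d
        else:
            break
    return LagSpec(recommended, lag_reference=reference), diag


@dataclass
class TreeNode:
    """Node of a probability tree: subjects following one exact path."""

    wave: int
    level: str
    count: int
    prob: float  # conditional probability given the parent node
    children: list["TreeNode"] = field(default_factory=list)


@dataclass(frozen=True)
class ProbabilityTree:
    """Conditional-proportion tree from a root category at a root wave.

    Each node holds the number of subjects whose trajectory follows the path
    from the root, and the conditional probability of the node's level given
    the parent's path.  Children's probabilities sum to one and their counts
    sum to the parent's count.
    """

    root: TreeNode
    waves: tuple[int, ...]
    scheme: CategoryScheme

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, depth: int):
            lines.append(
                f"{'  ' * depth}wave {node.wave}: {node.level} "
                f"(n={node.count}, p={node.prob:.3f})"
            )
            for child in node.children:
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def probability_tree(
    panel: CategoricalPanel, root_level: str, root_wave: int
) -> ProbabilityTree:
    """Build the probability tree of trajectories from a root category.

    Subjects with the root level at the root wave and complete observations
    from the root wave onward are partitioned recursively by their level at
    each subsequent wave; conditional probabilities are child count divided
    by parent count.
    """
    t0 = panel.wave_index(root_wave)
    root_code = panel.scheme.index(root_level)
    window = panel.codes[:, t0:]
    eligible = (window[:, 0] == root_code) & ~(window == _MISSING_CODE).any(axis=1)
    if not eligible.any():
        raise ValueError(
            f"no subject has level {root_level!r} at wave {root_wave} "
            "with complete follow-up"
        )
    sub = window[eligible]
    waves = panel.waves[t0:]

    def grow(rows: np.ndarray, depth: int, parent_count: int) -> list[TreeNode]:
        if depth >= sub.shape[1]:
            return []
        nodes = []
        for j, lvl in enumerate(panel.scheme.levels):
            mask = rows[:, depth] == j
            n = int(mask.sum())
            if n == 0:
                continue
            node = TreeNode(waves[depth], lvl, n, n / parent_count)
            node.children = grow(rows[mask], depth + 1, n)
            nodes.append(node)
        return nodes

    root = TreeNode(waves[0], root_level, int(eligible.sum()), 1.0)
    root.children = grow(sub, 1, root.count)
    return ProbabilityTree(root, waves, panel.scheme)
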