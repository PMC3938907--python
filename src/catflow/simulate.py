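"""Seeded simulation of categorical panels from Markov chains.

Generates subjects × waves panels whose trajectories follow a first- or
second-order Markov chain, optionally with an absorbing source level (a
"never" state that cannot be re-entered once left) and missingness applied
after the complete trajectory is drawn (so complete-case and
missing-as-category analyses are both exercisable on the same draw).

The generator exists so the models in this package can be validated by
parameter recovery: simulate from a known chain, fit, and check the fitted
transition probabilities and trends against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import CategoricalPanel, CategoryScheme
from .nominal_logit import NominalFit
from .transition_models import transition_matrix

__all__ = ["MarkovPanelSpec", "simulate_panel", "spec_from_fit"]


@dataclass(frozen=True)
class MarkovPanelSpec:
    """Parameters of a synthetic Markov panel.

    Parameters
    ----------
    scheme:
        Category scheme (levels; optional absorbing source level).
    n_subjects, waves:
        Panel dimensions; waves are the literal survey indices.
    initial_dist:
        Probability vector over levels at the first wave.
    order:
        1 for a first-order chain (``transition`` is J × J, row = previous
        level) or 2 (``transition`` is J × J × J indexed by
        [two-ago, previous, current]; the second wave uses the order-1
        marginalisation of the array under ``initial_dist``).
    transition:
        Row-stochastic transition probabilities.
    monotone:
        If true, validates that no transition re-enters the scheme's
        absorbing source level, so generated panels satisfy the monotone
        invariant by construction.
    missing_mechanism:
        Optional per-wave missingness probability: a scalar, or a mapping
        level → probability (missing-at-random given the current level).
    """

    scheme: CategoryScheme
    n_subjects: int
    waves: tuple[int, ...]
    initial_dist: np.ndarray
    transition: np.ndarray
    order: int = 1
    monotone: bool = False
    missing_mechanism: float | Mapping[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "waves", tuple(int(w) for w in self.waves))
        J = self.scheme.n_levels
        init = np.asarray(self.initial_dist, dtype=float)
        object.__setattr__(self, "initial_dist", init)
        T = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "transition", T)
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if init.shape != (J,) or not np.isclose(init.sum(), 1.0):
            raise ValueError("initial_dist must be a length-J probability vector")
        want = (J, J) if self.order == 1 else (J, J, J)
        if T.shape != want:
            raise ValueError(f"transition must have shape {want}, got {T.shape}")
        if (T < 0).any() or not np.allclose(T.sum(axis=-1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if self.monotone:
            src = self.scheme.monotone_absorbing_source
            if src is None:
                raise ValueError("monotone requires a scheme with an absorbing source")
            s = self.scheme.index(src)
            if self.order == 1:
                bad = np.delete(T[:, s], s).max() if J > 1 else 0.0
            else:
                into = T[..., s].copy()
                into[s, s] = 0.0
                bad = into.max()
            if bad > 0:
                raise ValueError(
                    f"monotone spec forbids transitions into {src!r} from other levels"
                )

    @property
    def n_waves(self) -> int:
        return len(self.waves)


def _missing_probs(spec: MarkovPanelSpec) -> np.ndarray | None:
    mech = spec.missing_mechanism
    if mech is None:
        return None
    J = spec.scheme.n_levels
    if isinstance(mech, Mapping):
        probs = np.zeros(J)
        for lvl, p in mech.items():
            probs[spec.scheme.index(lvl)] = float(p)
    else:
        probs = np.full(J, float(mech))
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("missingness probabilities must lie in [0, 1]")
    return probs


def simulate_panel(spec: MarkovPanelSpec, seed: int) -> CategoricalPanel:
    """Draw a panel from the specified chain; bit-reproducible given seed."""
    rng = np.random.default_rng(seed)
    n, W, J = spec.n_subjects, spec.n_waves, spec.scheme.n_levels
    codes = np.empty((n, W), dtype=np.int32)
    codes[:, 0] = rng.choice(J, size=n, p=spec.initial_dist)
    if spec.order == 1:
        cum = np.cumsum(spec.transition, axis=1)
        for t in range(1, W):
            u = rng.random(n)
            codes[:, t] = (u[:, None] > cum[codes[:, t - 1]]).sum(axis=1)
    else:
        # second wave: order-1 marginalisation of the array under initial_dist
        T1 = np.einsum("a,abc->bc", spec.initial_dist, spec.transition)
        T1 = T1 / T1.sum(axis=1, keepdims=True)
        cum1 = np.cumsum(T1, axis=1)
        u = rng.random(n)
        codes[:, 1] = (u[:, None] > cum1[codes[:, 0]]).sum(axis=1)
        cum2 = np.cumsum(spec.transition, axis=2)
        for t in range(2, W):
            u = rng.random(n)
            rows = cum2[codes[:, t - 2], codes[:, t - 1]]
            codes[:, t] = (u[:, None] > rows).sum(axis=1)
    probs = _missing_probs(spec)
    if probs is not None:
        drop = rng.random((n, W)) < probs[codes]
        codes[drop] = -1
    subject_ids = tuple(f"s{i:06d}" for i in range(n))
    return CategoricalPanel(subject_ids, spec.waves, codes, spec.scheme)


def spec_from_fit(fit: NominalFit, n_subjects: int | None = None) -> MarkovPanelSpec:
    """Turn a fitted first-order transition model back into a simulation spec.

    The fitted one-step transition matrix (structural zeros preserved as
    exact zeros) becomes the chain, and the source panel's first-wave
    distribution becomes the initial distribution, closing the
    simulate → fit → simulate loop.
    """
    md = fit.metadata
    if "scheme" not in md:
        raise ValueError("fit does not carry transition-model metadata")
    scheme: CategoryScheme = md["scheme"]
    T = transition_matrix(fit).to_numpy()
    monotone = scheme.monotone_absorbing_source is not None
    return MarkovPanelSpec(
        scheme=scheme,
        n_subjects=n_subjects or 1000,
        waves=md.get("waves", tuple(range(1, 5))),
        initial_dist=np.asarray(md["initial_dist"], dtype=float),
        transition=T,
        order=1,
        monotone=monotone,
    )
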