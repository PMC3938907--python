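"""Population-level (marginal) category distributions over survey waves.

The marginal distribution ignores individual trajectories and tracks the
share of each category at each wave.  A nominal-logit model with wave as the
explanatory variable, ``log(pi_j / pi_ref) = b1_j + wave * b2_j``, estimates
a linear trend on the log relative-risk-ratio scale; cluster-robust variances
(clustered on subject) account for the repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nominal_logit
from .data_model import _MISSING_CODE, CategoricalPanel
from .nominal_logit import DesignResponse, NominalFit

__all__ = [
    "MarginalTable",
    "marginal_table",
    "fit_marginal_trend",
    "predict_marginals",
    "marginal_gof",
    "MarginalGof",
]


@dataclass(frozen=True)
class MarginalTable:
    """Per-wave category counts and proportions.

    ``counts`` and ``proportions`` are DataFrames indexed by wave with one
    column per level; proportions sum to one within each wave over the cells
    that contributed (missing cells are excluded unless an explicit missing
    category was added upstream).
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def to_tsv(self, target, percent_decimals: int = 1) -> None:
        out = (100 * self.proportions).round(percent_decimals)
        out.to_csv(target, sep="\t")


def marginal_table(panel: CategoricalPanel) -> MarginalTable:
    """Observed per-wave counts and proportions of each level."""
    J = panel.scheme.n_levels
    counts = np.zeros((panel.n_waves, J), dtype=int)
    for j in range(J):
        counts[:, j] = (panel.codes == j).sum(axis=0)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(panel.waves, name="wave"), columns=list(panel.scheme.levels)
    )
    totals = counts_df.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a wave has no observed values; cannot form proportions")
    return MarginalTable(counts_df, counts_df.div(totals, axis=0))


def _stack_rows(panel: CategoricalPanel):
    """One row per observed subject-wave: (subject index, wave, level code)."""
    subj, wave_idx = np.nonzero(panel.codes != _MISSING_CODE)
    waves = np.asarray(panel.waves)[wave_idx]
    y = panel.codes[subj, wave_idx]
    return subj, waves, y


def fit_marginal_trend(
    panel: CategoricalPanel,
    wave_coding: str = "numeric",
    reference: str | None = None,
    **fit_options,
) -> NominalFit:
    """Fit the marginal trend model over waves.

    ``wave_coding="numeric"`` enters the literal survey number as a single
    slope per outcome level (the linear-trend model); ``"categorical"`` fits
    one indicator per wave after the first (the saturated marginal model,
    whose fitted marginals equal the observed ones).  Rows are stacked one
    per observed subject-wave and variances are clustered on subject.
    """
    if panel.n_waves < 2:
        raise ValueError("marginal trend needs at least 2 waves")
    if wave_coding not in ("numeric", "categorical"):
        raise ValueError(f"wave_coding must be 'numeric' or 'categorical', got {wave_coding!r}")
    subj, waves, y = _stack_rows(panel)
    if wave_coding == "numeric":
        X = np.column_stack([np.ones(len(y)), waves.astype(float)])
        colnames = ("const", "wave")
    else:
        dummies = [(waves == w).astype(float) for w in panel.waves[1:]]
        X = np.column_stack([np.ones(len(y))] + dummies)
        colnames = ("const",) + tuple(f"wave_{w}" for w in panel.waves[1:])
    data = DesignResponse(
        X=X, y=y, levels=panel.scheme.levels, cluster=subj, colnames=colnames,
    )
    result = nominal_logit.fit(data, reference, **fit_options)
    result.metadata.update(
        {"kind": "marginal", "wave_coding": wave_coding, "waves": panel.waves}
    )
    return result


def predict_marginals(fit: NominalFit) -> pd.DataFrame:
    """Model-predicted marginal probabilities per wave (rows sum to 1)."""
    waves = fit.metadata.get("waves")
    coding = fit.metadata.get("wave_coding")
    if waves is None or coding is None:
        raise ValueError("fit does not carry marginal-model metadata")
    rows = []
    for w in waves:
        if coding == "numeric":
            rows.append([1.0, float(w)])
        else:
            rows.append([1.0] + [1.0 if w == v else 0.0 for v in waves[1:]])
    P = fit.predict_proba(np.asarray(rows))
    return pd.DataFrame(P, index=pd.Index(waves, name="wave"), columns=list(fit.levels))


@dataclass(frozen=True)
class MarginalGof:
    """Absolute differences between predicted and observed marginals."""

    diffs: pd.DataFrame
    max_abs: float


def marginal_gof(fit: NominalFit, table: MarginalTable) -> MarginalGof:
    """Goodness of fit: |predicted − observed| marginal probability per
    wave and level, plus the maximum over all cells."""
    pred = predict_marginals(fit)
    obs = table.proportions.loc[pred.index, pred.columns]
    diffs = (pred - obs).abs()
    return MarginalGof(diffs, float(diffs.to_numpy().max()))
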