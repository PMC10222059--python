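"""Collinearity filtering of predictor stacks.

Reduces a climate stack to a low-collinearity subset by the standard
two-stage filter: first prune highly correlated pairs (|Pearson r| above a
cutoff, default 0.7), then prune predictors with a variance inflation
factor at or above a cutoff (default 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .rasters import ClimateStack

#: VIF sentinel for exactly collinear predictors.
VIF_INF = np.inf

_R2_COLLINEAR = 1.0 - 1e-12


@dataclass
class SelectionReport:
    """Outcome of a correlation + VIF filtering pass."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (name, reason in {correlation, vif}, value)
    r_max: float
    vif_max: float

    def to_dict(self) -> dict:
        return asdict(self)


def _stack_matrix(stack: ClimateStack, sample_cells: int | None, seed: int = 0) -> pd.DataFrame:
    X = stack.as_matrix()
    df = pd.DataFrame(X, columns=stack.layer_names)
    if sample_cells is not None and sample_cells < len(df):
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.choice(len(df), size=sample_cells, replace=False)]
    return df


def correlation_matrix(
    stack: ClimateStack, sample_cells: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Pairwise Pearson correlations among layers over (sampled) cells.

    Missing cells are excluded pairwise-complete.  A layer that is constant
    over the cells in common is an error (its correlation is undefined).
    """
    if stack.n_layers < 2:
        raise ValueError("need at least two layers for a correlation matrix")
    df = _stack_matrix(stack, sample_cells, seed)
    if len(df.dropna()) < 3:
        raise ValueError("need at least 3 non-missing shared cells")
    for name in df.columns:
        col = df[name].dropna()
        if col.std(ddof=0) == 0:
            raise ValueError(f"layer {name!r} is constant; correlation undefined")
    r = df.corr(method="pearson")  # pandas corr is pairwise-complete
    np.fill_diagonal(r.values, 1.0)
    return r


def vif(values: np.ndarray | pd.DataFrame, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factor of each column of a cells x predictors matrix.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from the OLS regression of column j
    on all other columns plus an intercept.  Exact collinearity yields an
    ``inf`` sentinel rather than an exception.  Rows with any missing value
    are dropped (listwise).
    """
    if isinstance(values, pd.DataFrame):
        names = list(values.columns)
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    X = X[np.isfinite(X).all(axis=1)]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete rows for {p} predictors")
    out = {}
    for j in range(p):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"predictor {names[j]!r} is constant; VIF undefined")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[names[j]] = VIF_INF if r2 >= _R2_COLLINEAR else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def select_predictors(
    stack: ClimateStack,
    r_max: float = 0.7,
    vif_max: float = 10.0,
    sample_cells: int | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Iteratively drop predictors until all |r| <= r_max and all VIF < vif_max.

    Correlation stage: while some pair exceeds ``r_max``, take the
    highest-|r| offending pair and drop the member with the larger mean |r|
    against all other remaining predictors (tie: drop the layer later in
    input order).  VIF stage: while some VIF >= ``vif_max``, drop the
    predictor with the largest VIF.  Deterministic throughout.
    """
    df = _stack_matrix(stack, sample_cells, seed)
    names = list(df.columns)
    if len(names) < 2:
        raise ValueError("need at least two layers to select from")
    order = {n: i for i, n in enumerate(names)}
    dropped: list[tuple[str, str, float]] = []
    kept = list(names)

    # --- correlation stage ---
    while len(kept) > 1:
        r = df[kept].corr(method="pearson").abs()
        np.fill_diagonal(r.values, 0.0)
        i, j = np.unravel_index(np.argmax(r.values), r.shape)
        worst = r.values[i, j]
        if worst <= r_max:
            break
        a, b = kept[i], kept[j]
        mean_r = {n: r.loc[n, [m for m in kept if m != n]].mean() for n in (a, b)}
        if np.isclose(mean_r[a], mean_r[b]):
            victim = a if order[a] > order[b] else b
        else:
            victim = a if mean_r[a] > mean_r[b] else b
        kept.remove(victim)
        dropped.append((victim, "correlation", float(worst)))
    if len(kept) == 1:
        warnings.warn("all layers mutually collinear; keeping a single predictor")

    # --- VIF stage ---
    while len(kept) > 1:
        v = vif(df[kept])
        worst_name = v.idxmax()
        if v[worst_name] < vif_max:
            break
        kept.remove(worst_name)
        dropped.append((worst_name, "vif", float(v[worst_name])))

    report = SelectionReport(kept=kept, dropped=dropped, r_max=r_max, vif_max=vif_max)
    _assert_constraints(df, report)
    return report


def _assert_constraints(df: pd.DataFrame, report: SelectionReport) -> None:
    """Post-condition enforced on every run: the kept set satisfies both filters."""
    kept = report.kept
    if len(kept) < 2:
        return
    r = df[kept].corr(method="pearson").abs()
    np.fill_diagonal(r.values, 0.0)
    assert r.values.max() <= report.r_max + 1e-12, "correlation constraint violated"
    assert vif(df[kept]).max() < report.vif_max, "VIF constraint violated"
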