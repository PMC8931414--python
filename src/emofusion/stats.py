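"""Inferential layer: paired t-tests, Pearson correlations, and
covariate-adjusted within-subject ANCOVAs via contrast scores.

The within-subject ANCOVA for 2-level factors is implemented in its
contrast-score form: for each subject a single contrast score is formed from
the condition cells (difference of level means for a main effect, difference
of differences for the interaction) and regressed on the z-scored
between-subject covariates with an intercept.  The intercept's F on
``(1, n - 1 - k)`` degrees of freedom tests the within-subject effect; each
covariate slope's F tests the effect-by-covariate interaction.  With zero
covariates this reduces exactly to the paired t-test (``F = t**2``).  Effect
sizes are partial eta squared, ``F * df1 / (F * df1 + df2)``.

No multiple-comparison correction is applied anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    InsufficientDataError,
    InsufficientVarianceError,
)

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("aq", "tas", "depression", "anxiety", "stress")
_CONDITION_THRESHOLD = 1e8


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    n: int
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass
class CovariateTest:
    covariate: str
    slope: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class AncovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    contrast: Mapping
    n: int
    covariate_tests: list[CovariateTest] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed paired t-test: ``t = mean(d) / (sd(d) / sqrt(n))``, d = x - y.

    A zero-variance difference with zero mean yields ``t = 0, p = 1``; with a
    nonzero mean the infinite-t case is reported as ``p = 0`` with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("paired_t needs two equal-length 1-d arrays")
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"paired_t needs n >= 2, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("paired_t does not accept missing pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, sd_diff=0.0, n=n)
        return TTestResult(
            t=float(np.inf) * np.sign(mean), df=df, p=0.0,
            mean_diff=mean, sd_diff=0.0, n=n, degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, mean_diff=mean, sd_diff=sd, n=n)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("pearson needs two equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"pearson needs n >= 3, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise InsufficientVarianceError("pearson requires both variables to vary")
    r = float(np.clip(np.cov(x, y, ddof=1)[0, 1] / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def zscore_covariates(
    covariates: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Z-score covariate columns over the included subjects (sample SD, ddof=1)."""
    columns = list(columns) if columns is not None else [
        c for c in COVARIATE_COLUMNS if c in covariates.columns
    ]
    out = covariates[columns].astype(float).copy()
    for c in columns:
        sd = out[c].std(ddof=1)
        if not sd > 0:
            raise InsufficientVarianceError(f"covariate {c!r} is constant; cannot z-score")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def main_effect_contrast(cells: Sequence, factor: int, positive_level) -> dict:
    """Weights for a 2-level main effect: difference of level means over the other factor."""
    weights = {}
    for cell in cells:
        level = cell[factor] if isinstance(cell, tuple) else cell
        sign = 1.0 if level == positive_level else -1.0
        n_side = sum(
            1 for c in cells
            if (c[factor] if isinstance(c, tuple) else c) == level
        )
        weights[cell] = sign / n_side
    return weights


def interaction_contrast(cells: Sequence[tuple], positive_levels: tuple) -> dict:
    """Weights for the 2x2 interaction: difference of differences (+/-1)."""
    weights = {}
    for cell in cells:
        sign = 1.0
        for value, pos in zip(cell, positive_levels):
            sign *= 1.0 if value == pos else -1.0
        weights[cell] = sign
    return weights


def within_ancova(
    cell_table: pd.DataFrame,
    contrast: Mapping,
    covariates: Optional[pd.DataFrame] = None,
    effect: str = "effect",
) -> AncovaResult:
    """Contrast-score within-subject ANCOVA for 2-level factors.

    Parameters
    ----------
    cell_table : DataFrame
        One row per subject (index = subject id), one column per within-subject
        condition cell.  Subjects with a missing cell are excluded listwise.
    contrast : mapping of column -> weight
        The per-subject contrast score is the weighted sum over cells.
    covariates : DataFrame, optional
        Between-subject covariates aligned on the same index; z-scored over
        the included subjects before entering the regression.
    """
    missing_cols = [c for c in contrast if c not in cell_table.columns]
    if missing_cols:
        raise InsufficientDataError(f"cell_table lacks contrast cells: {missing_cols}")
    cells = cell_table[list(contrast)].astype(float)
    if covariates is not None:
        covariates = covariates.reindex(cells.index)
        complete = cells.notna().all(axis=1) & covariates.notna().all(axis=1)
    else:
        complete = cells.notna().all(axis=1)
    excluded = [str(s) for s in cells.index[~complete]]
    if excluded:
        logger.info("ANCOVA %s: excluding %d incomplete subjects", effect, len(excluded))
    cells = cells[complete]
    n = len(cells)
    k = 0 if covariates is None else covariates.shape[1]
    if n < k + 2:
        raise InsufficientDataError(f"ANCOVA needs n >= k + 2 subjects, got n={n}, k={k}")

    scores = cells.to_numpy() @ np.array([contrast[c] for c in cells.columns], dtype=float)

    if k:
        z = zscore_covariates(covariates[complete], covariates.columns).to_numpy()
        design = np.column_stack([np.ones(n), z])
    else:
        design = np.ones((n, 1))
    cond = np.linalg.cond(design)
    if cond > _CONDITION_THRESHOLD:
        raise CollinearityError(
            f"covariate design condition number {cond:.2e} exceeds {_CONDITION_THRESHOLD:.0e}"
        )

    beta, _, _, _ = np.linalg.lstsq(design, scores, rcond=None)
    resid = scores - design @ beta
    df2 = n - 1 - k
    sigma2 = float((resid**2).sum() / df2)
    xtx_inv = np.linalg.inv(design.T @ design)

    def f_test(j: int) -> tuple[float, float, float]:
        if sigma2 == 0.0:
            f = np.inf if beta[j] != 0 else 0.0
            return float(f), 0.0 if beta[j] != 0 else 1.0, 1.0 if beta[j] != 0 else 0.0
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        f = float((beta[j] / se) ** 2)
        return f, float(sps.f.sf(f, 1, df2)), partial_eta_squared(f, 1, df2)

    f0, p0, eta0 = f_test(0)
    cov_tests = []
    if k:
        for j, name in enumerate(covariates.columns, start=1):
            fj, pj, etaj = f_test(j)
            cov_tests.append(
                CovariateTest(
                    covariate=str(name), slope=float(beta[j]),
                    F=fj, df1=1, df2=df2, p=pj, partial_eta_sq=etaj,
                )
            )
    return AncovaResult(
        effect=effect,
        F=f0,
        df1=1,
        df2=df2,
        p=p0,
        partial_eta_sq=eta0,
        contrast=dict(contrast),
        n=n,
        covariate_tests=cov_tests,
        excluded=excluded,
    )


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """``F * df1 / (F * df1 + df2)`` — the share of effect-plus-error variance."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise InsufficientDataError("partial_eta_squared needs F >= 0 and dfs >= 1")
    if np.isinf(F):
        return 1.0
    return float((F * df1) / (F * df1 + df2))
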