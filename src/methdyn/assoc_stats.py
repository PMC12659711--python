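"""Contingency-table association statistics.

Pearson chi-square (no continuity correction), Cramér's V with the
uncorrected formula

    V = sqrt(X² / (n · min(r − 1, c − 1)))

a percentile-bootstrap confidence interval for V (multinomial resampling of
the table at fixed grand total), and a conventional verbal effect label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import MethdynError, logger


@dataclass
class AssociationResult:
    table: np.ndarray
    n: int
    chi2: float
    df: int
    p: float
    v: float
    ci: tuple[float, float] | None = None
    label: str = ""


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise MethdynError("contingency table must be r x c with r, c >= 2")
    if (arr < 0).any():
        raise MethdynError("contingency table has negative counts")
    return arr


def contingency_chi2(table) -> tuple[float, float]:
    """Pearson X² and p for an r×c table, without continuity correction."""
    arr = _as_table(table)
    rowsum, colsum = arr.sum(axis=1), arr.sum(axis=0)
    if (rowsum == 0).any():
        raise MethdynError(f"zero row margin at row {int(np.argmax(rowsum == 0))}")
    if (colsum == 0).any():
        raise MethdynError(f"zero column margin at column {int(np.argmax(colsum == 0))}")
    expected = np.outer(rowsum, colsum) / arr.sum()
    if (expected < 1).any():
        logger.warning("contingency_chi2: expected counts below 1; chi2 approximation is poor")
    chi2, p, _df, _exp = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramér's V from a chi-square statistic (uncorrected formula)."""
    if chi2 < 0 or n < 1 or min(r, c) < 2:
        raise MethdynError("cramers_v needs chi2 >= 0, n >= 1 and an r x c table, r,c >= 2")
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def cramers_v_from_table(table) -> float:
    arr = _as_table(table)
    chi2, _ = contingency_chi2(arr)
    return cramers_v(chi2, int(arr.sum()), *arr.shape)


def cramers_v_ci(
    table, level: float = 0.95, B: int = 2000, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI for Cramér's V.

    Resamples the table as a multinomial over its cells at fixed grand
    total; resamples with a zero margin are redrawn (they carry no
    information about V).  Deterministic given ``seed``.
    """
    if B < 100:
        raise MethdynError("bootstrap needs B >= 100")
    arr = _as_table(table)
    n = int(arr.sum())
    probs = (arr / n).ravel()
    rng = np.random.default_rng(seed)
    mindim = min(arr.shape) - 1
    vs = np.empty(B)
    i = 0
    while i < B:
        draw = rng.multinomial(n, probs).reshape(arr.shape).astype(float)
        if (draw.sum(axis=1) == 0).any() or (draw.sum(axis=0) == 0).any():
            continue
        rowsum, colsum = draw.sum(axis=1), draw.sum(axis=0)
        expected = np.outer(rowsum, colsum) / n
        chi2 = ((draw - expected) ** 2 / expected).sum()
        vs[i] = np.sqrt(chi2 / (n * mindim))
        i += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


_EFFECT_THRESHOLDS = ((0.5, "strong"), (0.3, "moderate"), (0.1, "weak"))


def label_effect(v: float) -> str:
    """Verbal effect-size label for V: <0.1 negligible, <0.3 weak,
    <0.5 moderate, else strong (intervals closed on the left)."""
    if not 0 <= v <= 1 + 1e-12:
        raise MethdynError("Cramér's V must lie in [0, 1]")
    for thr, name in _EFFECT_THRESHOLDS:
        if v >= thr:
            return name
    return "negligible"


def associate(table, level: float = 0.95, B: int = 2000, seed: int | None = None
              ) -> AssociationResult:
    """Full association summary for one table: X², p, V, bootstrap CI, label."""
    arr = _as_table(table)
    chi2, p = contingency_chi2(arr)
    n = int(arr.sum())
    v = cramers_v(chi2, n, *arr.shape)
    ci = cramers_v_ci(arr, level=level, B=B, seed=seed)
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return AssociationResult(arr, n, chi2, df, p, v, ci, label_effect(v))
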