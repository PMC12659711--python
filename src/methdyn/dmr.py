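"""Windowed differential-methylation calling.

Each contig is tiled into 100-bp non-overlapping windows anchored at the
contig origin; each cytosine context is tested independently.  For a pair
of samples the per-context read counts of a window are pooled (replicates
summed, then cytosines summed) and compared with a two-sided Fisher exact
test on the 2x2 table [[meth_A, unmeth_A], [meth_B, unmeth_B]].  A window is
a DMR when, jointly,

* Fisher p < 0.01,
* Benjamini-Hochberg q < 0.05 (FDR family per context per comparison),
* at least 5 cytosines of the window's context are covered at depth >= 5
  in BOTH samples, and
* the ratio of the pooled methylation levels exceeds 1.5
  (FC = max(a, b) / max(min(a, b), eps), eps = 0.01).

Direction is hyper when the focal sample's level is the higher one.  The
same engine drives arbitrary regions of interest (miRNA features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import CONTEXTS, MethdynError, logger

DEFAULT_WIDTH = 100
DEFAULT_FISHER_P = 0.01
DEFAULT_FDR_Q = 0.05
DEFAULT_MIN_CYTOSINES = 5
DEFAULT_MIN_FOLD = 1.5
DEFAULT_EPSILON = 0.01
DEFAULT_MIN_DEPTH = 5


@dataclass(frozen=True)
class DmrThresholds:
    fisher_p: float = DEFAULT_FISHER_P
    fdr_q: float = DEFAULT_FDR_Q
    min_cytosines: int = DEFAULT_MIN_CYTOSINES
    min_fold: float = DEFAULT_MIN_FOLD
    epsilon: float = DEFAULT_EPSILON
    min_depth: int = DEFAULT_MIN_DEPTH


def tile_windows(contig_lengths: dict[str, int], width: int = DEFAULT_WIDTH) -> pd.DataFrame:
    """Non-overlapping tiles partitioning each contig; the last may be short.

    Returns chrom, start, end (0-based half-open) and a per-contig window
    index ``win``.
    """
    if width < 10:
        raise MethdynError("window width below 10 bp is not supported")
    frames = []
    for chrom, length in contig_lengths.items():
        if length <= 0:
            raise MethdynError(f"contig {chrom!r} has non-positive length")
        starts = np.arange(0, length, width)
        ends = np.minimum(starts + width, length)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "win": np.arange(starts.size), "start": starts, "end": ends}
            )
        )
    return pd.concat(frames, ignore_index=True)


def aggregate_window_counts(
    counts: pd.DataFrame, width: int = DEFAULT_WIDTH, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """Pool one sample's counts into per-(window, context) sums.

    Only cytosines with pooled depth >= ``min_depth`` contribute.  Returns
    chrom, win, context, meth, unmeth, covered.
    """
    df = counts.copy()
    depth = df["meth"] + df["unmeth"]
    df = df[depth >= min_depth]
    df["win"] = df["pos"] // width
    g = (
        df.groupby(["chrom", "win", "context"], observed=True)
        .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"), covered=("pos", "size"))
        .reset_index()
    )
    return g


def pool_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Sum two replicates' per-site counts into a single sample table."""
    key = ["chrom", "pos", "strand", "context"]
    merged = rep1[key + ["meth", "unmeth"]].merge(
        rep2[key + ["meth", "unmeth"]], on=key, how="outer", suffixes=("_1", "_2")
    )
    for col in ("meth_1", "meth_2", "unmeth_1", "unmeth_2"):
        merged[col] = merged[col].fillna(0)
    merged["meth"] = (merged["meth_1"] + merged["meth_2"]).astype(np.int64)
    merged["unmeth"] = (merged["unmeth_1"] + merged["unmeth_2"]).astype(np.int64)
    return merged[key + ["meth", "unmeth"]]


def aggregate_pair_counts(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    width: int = DEFAULT_WIDTH,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Window-level pooled counts for a sample pair.

    A cytosine qualifies only when its depth is >= ``min_depth`` in BOTH
    samples; ``covered`` counts qualifying cytosines per (window, context).
    """
    key = ["chrom", "pos", "strand", "context"]
    merged = counts_a[key + ["meth", "unmeth"]].merge(
        counts_b[key + ["meth", "unmeth"]], on=key, suffixes=("_a", "_b")
    )
    depth_a = merged["meth_a"] + merged["unmeth_a"]
    depth_b = merged["meth_b"] + merged["unmeth_b"]
    merged = merged[(depth_a >= min_depth) & (depth_b >= min_depth)]
    merged = merged.copy()
    merged["win"] = merged["pos"] // width
    g = (
        merged.groupby(["chrom", "win", "context"], observed=True)
        .agg(
            meth_a=("meth_a", "sum"),
            unmeth_a=("unmeth_a", "sum"),
            meth_b=("meth_b", "sum"),
            unmeth_b=("unmeth_b", "sum"),
            covered=("pos", "size"),
        )
        .reset_index()
    )
    return g


def fisher_region_test(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one pooled region. All-zero table -> 1."""
    if min(meth_a, unmeth_a, meth_b, unmeth_b) < 0:
        raise MethdynError("negative counts in Fisher table")
    if meth_a + unmeth_a + meth_b + unmeth_b == 0:
        logger.warning("fisher_region_test: all-zero table, p = 1")
        return 1.0
    _, p = stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]], alternative="two-sided")
    return float(p)


_TIE_REL = 1e-7  # relative tolerance for probability ties in the two-sided sum


def fisher_exact_vector(ma, ua, mb, ub, chunk_cells: int = 4_000_000) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables at once.

    Direct hypergeometric enumeration: for each table the p-value is the sum
    of pmf(k) over the support where pmf(k) <= pmf(observed) * (1 + 1e-7),
    the standard tie convention.  Log-pmfs come from a cached log-factorial
    table, so the cost is linear in the summed support sizes.  All-zero
    tables yield p = 1.
    """
    ma = np.asarray(ma, dtype=np.int64)
    ua = np.asarray(ua, dtype=np.int64)
    mb = np.asarray(mb, dtype=np.int64)
    ub = np.asarray(ub, dtype=np.int64)
    if min(ma.min(initial=0), ua.min(initial=0), mb.min(initial=0), ub.min(initial=0)) < 0:
        raise MethdynError("negative counts in Fisher tables")
    M = ma + ua + mb + ub
    n1 = ma + ua          # row margin of sample A
    n2 = ma + mb          # column margin of methylated reads
    out = np.ones(ma.size)
    live = M > 0
    if not live.any():
        return out

    from scipy.special import gammaln

    lgf = gammaln(np.arange(int(M.max()) + 2))  # log k!

    def logC(n, k):
        return lgf[n + 1] - lgf[k + 1] - lgf[n - k + 1]

    idx_all = np.flatnonzero(live)
    lo_all = np.maximum(0, n2 - (M - n1))
    hi_all = np.minimum(n1, n2)
    supp_all = hi_all - lo_all + 1

    start = 0
    log_tie = np.log1p(_TIE_REL)
    while start < idx_all.size:
        # take a slice of tables whose summed support fits the chunk budget
        stop = start
        cells = 0
        while stop < idx_all.size and cells < chunk_cells:
            cells += int(supp_all[idx_all[stop]])
            stop += 1
        idx = idx_all[start:stop]
        lo, supp = lo_all[idx], supp_all[idx]
        reps = np.repeat(np.arange(idx.size), supp)
        offsets = np.concatenate(([0], np.cumsum(supp)))[:-1]
        k = lo[reps] + (np.arange(reps.size) - offsets[reps])
        Mi, n1i, n2i = M[idx][reps], n1[idx][reps], n2[idx][reps]
        logpmf = logC(n1i, k) + logC(Mi - n1i, n2i - k) - logC(Mi, n2i)
        aobs = ma[idx][reps]
        logpobs = (
            logC(n1i, aobs) + logC(Mi - n1i, n2i - aobs) - logC(Mi, n2i)
        )
        take = logpmf <= logpobs + log_tie
        p = np.zeros(idx.size)
        np.add.at(p, reps[take], np.exp(logpmf[take]))
        out[idx] = np.minimum(p, 1.0)
        start = stop
    return out


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise MethdynError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(level_a: float, level_b: float, epsilon: float = DEFAULT_EPSILON
                ) -> tuple[float, str]:
    """Ratio of pooled window levels with a pseudocount floor.

    FC = max(a, b) / max(min(a, b), epsilon); direction is 'hyper' when the
    focal (A) level exceeds the reference, else 'hypo'.
    """
    if not (0 <= level_a <= 1 and 0 <= level_b <= 1):
        raise MethdynError("levels must lie in [0, 1]")
    hi, lo = max(level_a, level_b), min(level_a, level_b)
    fc = hi / max(lo, epsilon)
    return float(fc), ("hyper" if level_a > level_b else "hypo")


def call_dmrs(
    counts_focal: pd.DataFrame,
    counts_reference: pd.DataFrame,
    contig_lengths: dict[str, int],
    comparison_type: str,
    width: int = DEFAULT_WIDTH,
    thresholds: DmrThresholds = DmrThresholds(),
    contexts=CONTEXTS,
) -> pd.DataFrame:
    """Windowed DMRs between a focal and a reference sample.

    Input counts are per-site pooled sample tables (replicates already
    summed, e.g. via :func:`pool_replicates`).  Direction conventions live
    with the caller: the focal sample is the one named first (panicle for
    tissue-DMRs, N22 for cultivar-DMRs, drought for drought-DMRs), so
    ``hyper`` always means higher in the focal sample.

    Returns the full tested table with a boolean ``is_dmr``; the DMR set is
    the subset where it is True.
    """
    if comparison_type not in {"tissue", "cultivar", "drought", "mirna_feature", "custom"}:
        raise MethdynError(f"unknown comparison type {comparison_type!r}")
    agg = aggregate_pair_counts(counts_focal, counts_reference, width, thresholds.min_depth)
    agg = agg[agg["context"].isin(contexts)].reset_index(drop=True)
    if agg.empty:
        return _empty_dmr_table()

    level_a = agg["meth_a"] / (agg["meth_a"] + agg["unmeth_a"])
    level_b = agg["meth_b"] / (agg["meth_b"] + agg["unmeth_b"])
    agg["level_focal"] = level_a
    agg["level_ref"] = level_b
    hi = np.maximum(level_a, level_b)
    lo = np.minimum(level_a, level_b)
    agg["fc"] = hi / np.maximum(lo, thresholds.epsilon)
    agg["direction"] = np.where(level_a > level_b, "hyper", "hypo")

    # Fisher on candidate windows only: windows failing the coverage filter
    # can never be DMRs but still belong to the FDR family, so p is computed
    # for all windows of the context family.
    agg["p"] = fisher_exact_vector(
        agg["meth_a"].to_numpy(),
        agg["unmeth_a"].to_numpy(),
        agg["meth_b"].to_numpy(),
        agg["unmeth_b"].to_numpy(),
    )
    agg["q"] = np.nan
    for ctx in contexts:
        mask = agg["context"] == ctx
        if mask.any():
            agg.loc[mask, "q"] = adjust_fdr(agg.loc[mask, "p"].to_numpy())

    agg["is_dmr"] = (
        (agg["p"] < thresholds.fisher_p)
        & (agg["q"] < thresholds.fdr_q)
        & (agg["covered"] >= thresholds.min_cytosines)
        & (agg["fc"] > thresholds.min_fold)
    )
    agg["comparison"] = comparison_type
    agg["start"] = agg["win"] * width
    ends = {c: length for c, length in contig_lengths.items()}
    agg["end"] = np.minimum(agg["start"] + width, agg["chrom"].map(ends))
    cols = [
        "chrom", "start", "end", "win", "context", "comparison", "direction",
        "level_focal", "level_ref", "fc", "p", "q", "covered", "is_dmr",
        "meth_a", "unmeth_a", "meth_b", "unmeth_b",
    ]
    return agg[cols]


def _empty_dmr_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "start", "end", "win", "context", "comparison", "direction",
            "level_focal", "level_ref", "fc", "p", "q", "covered", "is_dmr",
            "meth_a", "unmeth_a", "meth_b", "unmeth_b",
        ]
    )


def compare_dmr_sets(
    set_1: pd.DataFrame,
    set_2: pd.DataFrame,
    mode: str = "region_overlap",
    gene_col: str = "gene_id",
) -> dict:
    """Shared/unique composition of two DMR sets.

    ``region_overlap``: any base-pair intersection of windows (same contig).
    ``gene_overlap``: intersection of associated gene-identifier sets.
    """
    if mode == "gene_overlap":
        g1 = set(set_1[gene_col].dropna())
        g2 = set(set_2[gene_col].dropna())
        shared = g1 & g2
        return {
            "shared": len(shared),
            "unique_1": len(g1 - g2),
            "unique_2": len(g2 - g1),
            "pct_of_1": 100.0 * len(shared) / len(g1) if g1 else 0.0,
            "pct_of_2": 100.0 * len(shared) / len(g2) if g2 else 0.0,
        }
    if mode != "region_overlap":
        raise MethdynError(f"unknown comparison mode {mode!r}")

    def _overlaps(df_a: pd.DataFrame, df_b: pd.DataFrame) -> np.ndarray:
        hits = np.zeros(len(df_a), dtype=bool)
        by_chrom = {c: g for c, g in df_b.groupby("chrom")}
        for i, row in enumerate(df_a.itertuples()):
            g = by_chrom.get(row.chrom)
            if g is None:
                continue
            hits[i] = bool(((g["start"] < row.end) & (g["end"] > row.start)).any())
        return hits

    h1 = _overlaps(set_1, set_2)
    h2 = _overlaps(set_2, set_1)
    return {
        "shared_1": int(h1.sum()),
        "shared_2": int(h2.sum()),
        "unique_1": int((~h1).sum()),
        "unique_2": int((~h2).sum()),
        "pct_of_1": 100.0 * h1.mean() if len(set_1) else 0.0,
        "pct_of_2": 100.0 * h2.mean() if len(set_2) else 0.0,
    }
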