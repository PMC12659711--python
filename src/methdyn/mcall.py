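"""Methylcytosine calling against a chloroplast-calibrated error null.

Bisulfite conversion occasionally fails, so a truly unmethylated cytosine
is read as methylated at some small rate *e*.  The chloroplast genome is
unmethylated in rice, so the pooled chloroplast methylated-read fraction of
each library estimates its *e*.  A nuclear cytosine with coverage n and k
methylated reads is then called methylated when the one-sided binomial
upper tail P(X >= k | X ~ Bin(n, e)) falls at or below alpha, with a
minimum read depth, and a sample's consensus keeps only the sites called in
both biological replicates.

Drought dynamics are classified per site: DI (demethylated; in the control
consensus only), DII (de novo; in the stress consensus only) and maintained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import CONTEXTS, MethdynError, logger

SITE_KEY = ["chrom", "pos", "strand"]

DEFAULT_ALPHA = 0.005
DEFAULT_MIN_DEPTH = 5
ERROR_FLOOR = 1e-4


@dataclass
class ConversionErrorRate:
    sample_id: str
    e: float
    total_chloroplast_coverage: int
    floored: bool = False


@dataclass
class ConsensusSet:
    """Methylated sites of one sample: called in both replicates.

    ``sites`` carries the site key plus context and the coverage-weighted
    mean methylation level of the two replicates.
    """

    sample_id: str
    sites: pd.DataFrame
    context_tally: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.context_tally:
            self.context_tally = self.sites["context"].value_counts().to_dict()
            for ctx in CONTEXTS:
                self.context_tally.setdefault(ctx, 0)

    def __len__(self) -> int:
        return len(self.sites)

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[SITE_KEY])


def estimate_conversion_error(
    counts: pd.DataFrame,
    chloroplast_contigs: set[str],
    sample_id: str = "",
    floor: float = ERROR_FLOOR,
) -> ConversionErrorRate:
    """Pooled conversion-failure rate from chloroplast cytosines.

    e = sum(meth) / sum(meth + unmeth) over every chloroplast cytosine of
    the library, all contexts and both strands pooled; floored at ``floor``
    when the raw ratio is zero so the binomial null stays defined.
    """
    if not chloroplast_contigs:
        raise MethdynError("no contig is flagged chloroplast")
    sub = counts[counts["chrom"].isin(chloroplast_contigs)]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        raise MethdynError(
            f"sample {sample_id!r}: zero total chloroplast coverage, cannot calibrate"
        )
    e = float(sub["meth"].sum()) / total
    floored = e == 0.0
    if floored:
        logger.warning("sample %r: zero chloroplast error, floored at %g", sample_id, floor)
        e = floor
    return ConversionErrorRate(sample_id, e, total, floored)


def binomial_pvalue(k, n, e: float):
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, e).

    Accepts scalars or arrays; numerically stable via the regularised
    incomplete beta behind ``scipy.stats.binom.sf``.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(k_arr > n_arr) or np.any(k_arr < 0):
        raise MethdynError("binomial_pvalue needs 0 <= k <= n")
    if not 0 < e < 1:
        raise MethdynError("binomial_pvalue needs 0 < e < 1")
    p = stats.binom.sf(k_arr - 1, n_arr, e)
    if np.isscalar(k) and np.isscalar(n):
        return float(p)
    return p


def call_methylated_sites(
    counts: pd.DataFrame,
    error: ConversionErrorRate | float,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-replicate methylation calls.

    Sites with coverage below ``min_depth`` carry no call and are dropped.
    Returns chrom, pos, strand, context, k, n, level, p, methylated.
    """
    e = error.e if isinstance(error, ConversionErrorRate) else float(error)
    df = counts.copy()
    df["n"] = df["meth"] + df["unmeth"]
    df = df[df["n"] >= min_depth].reset_index(drop=True)
    df["k"] = df["meth"]
    df["level"] = df["k"] / df["n"]
    df["p"] = binomial_pvalue(df["k"].to_numpy(), df["n"].to_numpy(), e)
    df["methylated"] = df["p"] <= alpha
    return df[SITE_KEY + ["context", "k", "n", "level", "p", "methylated"]]


def intersect_replicates(
    calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame, sample_id: str = ""
) -> ConsensusSet:
    """Consensus methylated sites: called in BOTH replicates.

    The consensus level is the coverage-weighted mean of the replicates'
    k/n, i.e. (k1 + k2) / (n1 + n2).
    """
    m1 = calls_rep1[calls_rep1["methylated"]]
    m2 = calls_rep2[calls_rep2["methylated"]]
    merged = m1.merge(m2, on=SITE_KEY + ["context"], suffixes=("_1", "_2"))
    if merged.empty:
        logger.warning("sample %r: replicate consensus is empty", sample_id)
    sites = merged[SITE_KEY + ["context"]].copy()
    denom = merged["n_1"] + merged["n_2"]
    sites["level"] = np.where(
        denom > 0, (merged["k_1"] + merged["k_2"]) / denom.replace(0, np.nan), np.nan
    )
    return ConsensusSet(sample_id, sites.reset_index(drop=True))


def overlap_mC(set_a: ConsensusSet, set_b: ConsensusSet) -> dict:
    """Shared methylated sites between two consensus sets.

    Returns shared count, the share as a percentage of each set, and the
    context composition of the shared sites (percentages summing to 100).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise MethdynError("overlap_mC needs two non-empty consensus sets")
    ia, ib = set_a.key_index(), set_b.key_index()
    shared_mask = ia.isin(ib)
    shared = int(shared_mask.sum())
    ctx = set_a.sites.loc[shared_mask, "context"].value_counts()
    comp = {c: (100.0 * ctx.get(c, 0) / shared if shared else 0.0) for c in CONTEXTS}
    return {
        "shared": shared,
        "pct_of_a": 100.0 * shared / len(set_a),
        "pct_of_b": 100.0 * shared / len(set_b),
        "context_composition": comp,
    }


def classify_dynamics(control: ConsensusSet, stress: ConsensusSet) -> pd.DataFrame:
    """Partition control ∪ stress consensus sites into DI / DII / maintained.

    DI: methylated in control only (drought demethylation).
    DII: methylated in stress only (de novo methylation).
    """
    c = control.sites[SITE_KEY + ["context"]].copy()
    s = stress.sites[SITE_KEY + ["context"]].copy()
    merged = c.merge(s, on=SITE_KEY + ["context"], how="outer", indicator=True)
    merged["class"] = merged["_merge"].map(
        {"left_only": "DI", "right_only": "DII", "both": "maintained"}
    ).astype(str)
    return merged.drop(columns="_merge").reset_index(drop=True)


def dynamics_summary(dynamics: pd.DataFrame) -> dict:
    total = len(dynamics)
    counts = dynamics["class"].value_counts()
    return {
        "total": total,
        "pct_DI": 100.0 * counts.get("DI", 0) / total if total else 0.0,
        "pct_DII": 100.0 * counts.get("DII", 0) / total if total else 0.0,
        "pct_maintained": 100.0 * counts.get("maintained", 0) / total if total else 0.0,
    }


KDE_GRID = np.linspace(-1.0, 1.0, 512)
_DEGENERATE_BW = 0.01


def methylation_difference_density(
    levels_a: np.ndarray, levels_b: np.ndarray, min_sites: int = 50
) -> pd.DataFrame:
    """Gaussian KDE of per-site methylation differences (a − b).

    Silverman bandwidth on a fixed 512-point grid over [−1, 1]; when the
    differences are degenerate (zero variance) a fixed fallback bandwidth of
    0.01 keeps the density defined.  Returns columns ``diff`` and
    ``density``.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size != b.size:
        raise MethdynError("paired level vectors must be the same length")
    if a.size < min_sites:
        raise MethdynError(f"need at least {min_sites} shared sites for a density")
    d = a - b
    if np.ptp(d) == 0 or np.std(d) == 0:
        dens = stats.norm.pdf(KDE_GRID, loc=d[0], scale=_DEGENERATE_BW)
    else:
        kde = stats.gaussian_kde(d, bw_method="silverman")
        dens = kde(KDE_GRID)
    return pd.DataFrame({"diff": KDE_GRID, "density": dens})
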