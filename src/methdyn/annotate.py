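"""Gene-feature annotation, metagene profiles and DI/DII positional curves.

Every genomic position maps to exactly one feature label through a
strand-aware precedence rule, mirroring promoter-first peak-annotation
conventions:

    promoter (<=1 kb) > 5'UTR > 3'UTR > exon > intron
    > promoter (1-2 kb) > promoter (2-3 kb)
    > downstream (<=1 kb) > downstream (1-2 kb) > downstream (2-3 kb)
    > distal intergenic

Among overlapping intervals of equal precedence the gene with the nearest
TSS wins.  Region labels (100-bp DMR windows) use the region midpoint.

Metagene profiles average methylation over a fixed bin scheme: 30 x 100-bp
upstream bins, the gene body rescaled to 40 bins TSS->TES, and 30 x 100-bp
downstream bins, strand-flipped for minus-strand genes.  Bins without
covered cytosines are missing, not zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import MethdynError, logger

FLANK_BINS = 30
BODY_BINS = 40
TOTAL_BINS = FLANK_BINS + BODY_BINS + FLANK_BINS
FLANK_BP = 3000

# label -> precedence (lower wins)
PRECEDENCE = {
    "promoter_0_1kb": 0,
    "five_prime_utr": 1,
    "three_prime_utr": 2,
    "exon": 3,
    "intron": 4,
    "promoter_1_2kb": 5,
    "promoter_2_3kb": 6,
    "downstream_0_1kb": 7,
    "downstream_1_2kb": 8,
    "downstream_2_3kb": 9,
}
DISTAL = "distal_intergenic"


class GeneFeatureIndex:
    """Interval index answering "what feature is this position in?".

    Built from gene models; promoter and downstream extents default to 3 kb
    split into 1-kb bins.  Intervals are 0-based half-open and strand-aware;
    flank bins are truncated at contig bounds (and the truncation logged).
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        exons: pd.DataFrame,
        contig_lengths: dict[str, int],
        utrs: pd.DataFrame | None = None,
        promoter_extent: int = FLANK_BP,
        downstream_extent: int = FLANK_BP,
    ) -> None:
        if ((genes["end"] - genes["start"]) <= 0).any():
            raise MethdynError("zero-length gene in gene models")
        self.genes = genes.reset_index(drop=True)
        self.contig_lengths = dict(contig_lengths)
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in contig_lengths}
        truncated = 0

        def add(chrom: str, start: int, end: int, label: str, gene_id: str, tss: int):
            nonlocal truncated
            length = self.contig_lengths[chrom]
            s, e = max(0, start), min(end, length)
            if (s, e) != (start, end):
                truncated += 1
            if e > s:
                self._trees[chrom].addi(s, e, (PRECEDENCE[label], label, gene_id, tss))

        n_bins = promoter_extent // 1000
        exon_by_gene = {g: df for g, df in exons.groupby("gene_id")}
        utr_by_gene = (
            {g: df for g, df in utrs.groupby("gene_id")} if utrs is not None else {}
        )
        for g in genes.itertuples():
            if g.strand == "+":
                for i in range(n_bins):
                    add(g.chrom, g.start - 1000 * (i + 1), g.start - 1000 * i,
                        f"promoter_{i}_{i + 1}kb", g.gene_id, g.tss)
                    add(g.chrom, g.end + 1000 * i, g.end + 1000 * (i + 1),
                        f"downstream_{i}_{i + 1}kb", g.gene_id, g.tss)
            else:
                for i in range(n_bins):
                    add(g.chrom, g.end + 1000 * i, g.end + 1000 * (i + 1),
                        f"promoter_{i}_{i + 1}kb", g.gene_id, g.tss)
                    add(g.chrom, g.start - 1000 * (i + 1), g.start - 1000 * i,
                        f"downstream_{i}_{i + 1}kb", g.gene_id, g.tss)
            ex = exon_by_gene.get(g.gene_id)
            if ex is None or ex.empty:
                add(g.chrom, g.start, g.end, "exon", g.gene_id, g.tss)
            else:
                prev_end = None
                for e in ex.sort_values("start").itertuples():
                    add(g.chrom, e.start, e.end, "exon", g.gene_id, g.tss)
                    if prev_end is not None and e.start > prev_end:
                        add(g.chrom, prev_end, e.start, "intron", g.gene_id, g.tss)
                    prev_end = max(prev_end or e.end, e.end)
            for u in utr_by_gene.get(g.gene_id, pd.DataFrame()).itertuples():
                label = "five_prime_utr" if u.kind == "5" else "three_prime_utr"
                add(g.chrom, u.start, u.end, label, g.gene_id, g.tss)
        if truncated:
            logger.info("GeneFeatureIndex: %d flank bins truncated at contig bounds", truncated)

    def query(self, chrom: str, pos: int) -> tuple[str, str | None, int | None]:
        """Feature label at one position: (label, gene_id, distance_to_tss)."""
        tree = self._trees.get(chrom)
        if tree is None:
            raise MethdynError(f"unknown contig {chrom!r}")
        hits = tree[pos]
        if not hits:
            return DISTAL, None, None
        best = min(hits, key=lambda iv: (iv.data[0], abs(pos - iv.data[3])))
        _, label, gene_id, tss = best.data
        return label, gene_id, pos - tss

    def query_many(self, chroms, positions) -> pd.DataFrame:
        rows = [self.query(c, int(p)) for c, p in zip(chroms, positions)]
        return pd.DataFrame(rows, columns=["feature", "gene_id", "dist_to_tss"])


def annotate_regions(regions: pd.DataFrame, index: GeneFeatureIndex
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Label sites or regions with their gene feature.

    Point tables use ``pos``; interval tables use the midpoint of
    ``start``/``end``.  Returns the labeled table and the feature
    distribution as percentages (summing to 100).
    """
    if "pos" in regions.columns:
        positions = regions["pos"]
    else:
        positions = (regions["start"] + regions["end"] - 1) // 2
    ann = index.query_many(regions["chrom"].to_numpy(), positions.to_numpy())
    out = pd.concat([regions.reset_index(drop=True), ann], axis=1)
    if len(out):
        dist = out["feature"].value_counts(normalize=True) * 100.0
    else:
        dist = pd.Series(dtype=float)
    return out, dist


# ---------------------------------------------------------------------------
# Metagene machinery
# ---------------------------------------------------------------------------

def _site_bins_for_gene(gene, positions: np.ndarray) -> np.ndarray:
    """Map absolute positions to metagene bin indices for one gene.

    Bins 0..29: upstream flank (3 kb, 100-bp bins, promoter-distal first);
    bins 30..69: gene body scaled TSS->TES; bins 70..99: downstream flank.
    Positions outside the window return -1.
    """
    start, end = gene.start, gene.end
    length = end - start
    bins = np.full(positions.size, -1, dtype=np.int64)
    if gene.strand == "+":
        up = (positions >= start - FLANK_BP) & (positions < start)
        bins[up] = (positions[up] - (start - FLANK_BP)) // 100
        body = (positions >= start) & (positions < end)
        bins[body] = FLANK_BINS + (
            (positions[body] - start) * BODY_BINS // length
        )
        down = (positions >= end) & (positions < end + FLANK_BP)
        bins[down] = FLANK_BINS + BODY_BINS + (positions[down] - end) // 100
    else:
        up = (positions >= end) & (positions < end + FLANK_BP)
        bins[up] = (end + FLANK_BP - 1 - positions[up]) // 100
        body = (positions >= start) & (positions < end)
        bins[body] = FLANK_BINS + (
            (end - 1 - positions[body]) * BODY_BINS // length
        )
        down = (positions >= start - FLANK_BP) & (positions < start)
        bins[down] = FLANK_BINS + BODY_BINS + (start - 1 - positions[down]) // 100
    return bins


def bin_labels() -> list[str]:
    labels = [f"up_{FLANK_BP - 100 * i}bp" for i in range(FLANK_BINS)]
    labels += [f"body_{i}" for i in range(BODY_BINS)]
    labels += [f"down_{100 * (i + 1)}bp" for i in range(FLANK_BINS)]
    return labels


def _gene_windows(genes: pd.DataFrame) -> dict[str, list]:
    by_chrom: dict[str, list] = {}
    for g in genes.itertuples():
        by_chrom.setdefault(g.chrom, []).append(g)
    return by_chrom


def metagene_profile(
    levels: pd.DataFrame, genes: pd.DataFrame, context: str | None = None,
    min_genes: int = 50,
) -> pd.DataFrame:
    """Mean methylation across the metagene bin scheme.

    ``levels`` carries chrom, pos, context, level for covered cytosines.
    Per-gene bin means are averaged across genes ignoring missing bins.
    """
    if len(genes) < min_genes:
        raise MethdynError(f"metagene profile needs >= {min_genes} genes")
    df = levels if context is None else levels[levels["context"] == context]
    if df.empty:
        raise MethdynError("no covered cytosines for metagene profile")
    sums = np.zeros(TOTAL_BINS)
    counts = np.zeros(TOTAL_BINS)  # number of genes contributing to the bin
    by_chrom = {c: g for c, g in df.groupby("chrom")}
    for g in genes.itertuples():
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        lo, hi = g.start - FLANK_BP, g.end + FLANK_BP
        window = sub[(sub["pos"] >= lo) & (sub["pos"] < hi)]
        if window.empty:
            continue
        bins = _site_bins_for_gene(g, window["pos"].to_numpy())
        ok = bins >= 0
        if not ok.any():
            continue
        per_bin = pd.Series(window["level"].to_numpy()[ok]).groupby(bins[ok]).mean()
        sums[per_bin.index] += per_bin.to_numpy()
        counts[per_bin.index] += 1
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"bin": np.arange(TOTAL_BINS), "label": bin_labels(), "mean_level": mean}
    )


def dynamics_abundance_profile(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    expression_classes: pd.Series,
    context: str | None = None,
) -> pd.DataFrame:
    """Positional abundance of DI or DII sites per expression class.

    Counts sites per metagene bin, normalised per kb per gene within each
    class (flank bins are 0.1 kb; body bins are gene-length/40 bp, averaged
    over the class's genes).  Classes with zero genes are omitted with a
    warning.  Returns long-form: class, bin, label, abundance.
    """
    df = sites if context is None else sites[sites["context"] == context]
    gene_class = expression_classes.reindex(genes["gene_id"])
    frames = []
    by_chrom = {c: g for c, g in df.groupby("chrom")} if len(df) else {}
    for cls in pd.unique(gene_class.dropna()):
        cls_genes = genes[gene_class.to_numpy() == cls]
        if cls_genes.empty:
            logger.warning("dynamics_abundance_profile: class %r has no genes", cls)
            continue
        counts = np.zeros(TOTAL_BINS)
        kb = np.zeros(TOTAL_BINS)
        for g in cls_genes.itertuples():
            body_kb = (g.end - g.start) / BODY_BINS / 1000.0
            kb[:FLANK_BINS] += 0.1
            kb[FLANK_BINS : FLANK_BINS + BODY_BINS] += body_kb
            kb[FLANK_BINS + BODY_BINS :] += 0.1
            sub = by_chrom.get(g.chrom)
            if sub is None:
                continue
            window = sub[(sub["pos"] >= g.start - FLANK_BP) & (sub["pos"] < g.end + FLANK_BP)]
            if window.empty:
                continue
            bins = _site_bins_for_gene(g, window["pos"].to_numpy())
            np.add.at(counts, bins[bins >= 0], 1)
        frames.append(
            pd.DataFrame(
                {
                    "class": cls,
                    "bin": np.arange(TOTAL_BINS),
                    "label": bin_labels(),
                    "abundance": counts / np.maximum(kb, 1e-12),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["class", "bin", "label", "abundance"])
    return pd.concat(frames, ignore_index=True)
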