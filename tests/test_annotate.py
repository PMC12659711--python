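"""Feature annotation, metagene profiles and positional abundance."""

import numpy as np
import pandas as pd
import pytest

from methdyn.annotate import (
    TOTAL_BINS,
    GeneFeatureIndex,
    annotate_regions,
    dynamics_abundance_profile,
    metagene_profile,
)

LENGTHS = {"chr1": 40_000}


@pytest.fixture
def simple_index():
    # + strand gene with two exons, and a - strand single-exon gene far away
    genes = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 10_000, "end": 12_000,
             "strand": "+", "tss": 10_000, "tes": 11_999},
            {"gene_id": "gB", "chrom": "chr1", "start": 30_000, "end": 31_000,
             "strand": "-", "tss": 30_999, "tes": 30_000},
        ]
    )
    exons = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 10_000, "end": 10_500},
            {"gene_id": "gA", "chrom": "chr1", "start": 11_200, "end": 12_000},
            {"gene_id": "gB", "chrom": "chr1", "start": 30_000, "end": 31_000},
        ]
    )
    return GeneFeatureIndex(genes, exons, LENGTHS)


class TestFeatureIndex:
    @pytest.mark.parametrize(
        "pos, label",
        [
            (9_500, "promoter_0_1kb"),      # 500 bp upstream of + TSS
            (8_500, "promoter_1_2kb"),
            (7_500, "promoter_2_3kb"),
            (11_500, "exon"),               # inside exon 2
            (10_800, "intron"),
            (12_500, "downstream_0_1kb"),
            (20_000, "distal_intergenic"),  # >5 kb from every gene
            (31_500, "promoter_0_1kb"),     # upstream of the - strand gene
            (29_500, "downstream_0_1kb"),
        ],
    )
    def test_labels_respect_strand_and_precedence(self, simple_index, pos, label):
        got, _, _ = simple_index.query("chr1", pos)
        assert got == label

    def test_every_position_gets_exactly_one_label(self, simple_index, rng):
        for pos in rng.integers(0, LENGTHS["chr1"], 300):
            label, _, _ = simple_index.query("chr1", int(pos))
            assert isinstance(label, str) and label

    def test_promoter_beats_downstream_between_adjacent_genes(self):
        # two + strand genes 1500 bp apart: the gap is downstream of g1 and
        # promoter of g2; the <=1 kb promoter must win inside 1 kb of g2
        genes = pd.DataFrame(
            [
                {"gene_id": "g1", "chrom": "chr1", "start": 1000, "end": 2000,
                 "strand": "+", "tss": 1000, "tes": 1999},
                {"gene_id": "g2", "chrom": "chr1", "start": 3500, "end": 4500,
                 "strand": "+", "tss": 3500, "tes": 4499},
            ]
        )
        exons = genes.rename(columns={})[["gene_id", "chrom", "start", "end"]]
        idx = GeneFeatureIndex(genes, exons, {"chr1": 10_000})
        label, gene, _ = idx.query("chr1", 3000)
        assert label == "promoter_0_1kb" and gene == "g2"


class TestAnnotateRegions:
    def test_gene_free_contig_is_all_distal(self, simple_index, rng):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(15_000, 25_000, 50)}
        )
        _, dist = annotate_regions(sites, simple_index)
        assert dist["distal_intergenic"] == pytest.approx(100.0)

    def test_region_label_uses_midpoint(self, simple_index):
        # region straddling the promoter/gene boundary: midpoint decides
        regions = pd.DataFrame(
            {"chrom": ["chr1"], "start": [9_990], "end": [10_090]}
        )
        ann, _ = annotate_regions(regions, simple_index)
        assert ann.iloc[0]["feature"] == "exon"  # midpoint 10_039 inside exon 1

    def test_distribution_sums_to_100_and_is_order_invariant(self, simple_index, rng):
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 40_000, 400)}
        )
        _, d1 = annotate_regions(sites, simple_index)
        _, d2 = annotate_regions(sites.sample(frac=1, random_state=0), simple_index)
        assert d1.sum() == pytest.approx(100.0, abs=0.01)
        pd.testing.assert_series_equal(d1.sort_index(), d2.sort_index())

    def test_planted_gene_body_share_recovered(self):
        # construct sites with exactly 35% placed in gene bodies
        rng = np.random.default_rng(5)
        genes = pd.DataFrame(
            [{"gene_id": f"g{i}", "chrom": "chr1", "start": s, "end": s + 1000,
              "strand": "+", "tss": s, "tes": s + 999}
             for i, s in enumerate(range(5000, 35_000, 10_000))]
        )
        exons = genes[["gene_id", "chrom", "start", "end"]]
        idx = GeneFeatureIndex(genes, exons, LENGTHS)
        body = [
            {"chrom": "chr1", "pos": int(rng.integers(s, s + 1000))}
            for s in rng.choice(genes["start"], 35)
        ]
        # distal positions: midway between the 10-kb-spaced genes, >3 kb away
        distal = [
            {"chrom": "chr1", "pos": int(rng.choice([500, 9500, 19_500, 29_500]))}
            for _ in range(65)
        ]
        sites = pd.DataFrame(body + distal)
        _, dist = annotate_regions(sites, idx)
        assert dist.get("exon", 0) == pytest.approx(35.0, abs=2.0)


def uniform_levels(rng, n=4000, level=0.5):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.sort(rng.choice(40_000, n, replace=False)),
            "context": "CpG",
            "level": level,
        }
    )


def gene_grid(n=60, start=3_500, spacing=600, length=400, strand="+"):
    rows = []
    for i in range(n):
        s = start + i * spacing
        rows.append(
            {"gene_id": f"g{i}", "chrom": "chr1", "start": s, "end": s + length,
             "strand": strand,
             "tss": s if strand == "+" else s + length - 1,
             "tes": s + length - 1 if strand == "+" else s}
        )
    return pd.DataFrame(rows)


class TestMetagene:
    def test_uniform_methylome_gives_flat_profile(self, rng):
        genes = gene_grid()
        prof = metagene_profile(uniform_levels(rng), genes)
        observed = prof["mean_level"].dropna()
        assert len(observed) > 90
        assert np.allclose(observed, 0.5)

    def test_strand_flip_symmetry(self, rng):
        levels = uniform_levels(rng)
        # impose a gradient so the profile is not trivially symmetric
        levels["level"] = levels["pos"] / 40_000
        plus = gene_grid(strand="+")
        minus = plus.copy()
        minus["strand"] = "-"
        minus["tss"], minus["tes"] = plus["tes"], plus["tss"]
        p1 = metagene_profile(levels, plus)["mean_level"].to_numpy()
        p2 = metagene_profile(levels, minus)["mean_level"].to_numpy()
        # a minus-strand gene set reads the same gradient mirrored
        assert np.nanmean(np.abs(p1 - p2[::-1])) < 0.02

    def test_requires_minimum_genes(self, rng):
        with pytest.raises(Exception):
            metagene_profile(uniform_levels(rng), gene_grid(n=5))


class TestDynamicsAbundance:
    def test_sites_in_silent_promoters_peak_there_only(self):
        genes = gene_grid(n=60, spacing=8000)  # isolate flanks from neighbours
        classes = pd.Series(
            ["silent" if i < 30 else "high" for i in range(60)],
            index=genes["gene_id"],
        )
        rng = np.random.default_rng(13)
        silent_genes = genes.iloc[:30]
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [int(rng.integers(g.start - 500, g.start))
                        for g in silent_genes.itertuples() for _ in range(3)],
                "context": "CHH",
            }
        )
        prof = dynamics_abundance_profile(sites, genes, classes)
        silent = prof[prof["class"] == "silent"]
        promoter_bins = silent[silent["label"].str.startswith("up_")]
        assert promoter_bins["abundance"].sum() > 0
        body = silent[silent["label"].str.startswith("body_")]
        assert body["abundance"].sum() == 0

    def test_empty_site_set_gives_zero_curves(self):
        genes = gene_grid(n=60)
        classes = pd.Series("high", index=genes["gene_id"])
        sites = pd.DataFrame(columns=["chrom", "pos", "context"])
        prof = dynamics_abundance_profile(sites, genes, classes)
        assert (prof["abundance"] == 0).all()
        assert len(prof) == TOTAL_BINS
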