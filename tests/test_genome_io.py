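"""Genome I/O and strand-aware cytosine context extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdyn._util import ValidationError, revcomp
from methdyn.genome_io import (
    Genome,
    extract_cytosine_sites,
    read_cx_report,
    read_gene_models,
    read_mirna_loci,
    write_bed,
    write_cx_report,
)
from conftest import make_counts, random_dna


def oracle_sites(seq: str) -> set[tuple[int, str, str]]:
    """Brute-force context oracle: apply the plus-strand rule to the
    sequence and to its reverse complement, mapping coordinates back."""

    def plus_strand(s):
        out = []
        for i, ch in enumerate(s):
            if ch != "C" or i + 2 >= len(s):
                continue
            d1, d2 = s[i + 1], s[i + 2]
            if "N" in (d1, d2):
                continue
            ctx = "CpG" if d1 == "G" else ("CHG" if d2 == "G" else "CHH")
            out.append((i, ctx))
        return out

    sites = {(i, "+", ctx) for i, ctx in plus_strand(seq)}
    rc = revcomp(seq)
    L = len(seq)
    sites |= {(L - 1 - j, "-", ctx) for j, ctx in plus_strand(rc)}
    return sites


class TestContextExtraction:
    @pytest.mark.parametrize(
        "seq, pos, strand, context, tri",
        [
            ("ACGTA", 1, "+", "CpG", "CGT"),
            ("ACTGA", 1, "+", "CHG", "CTG"),
            ("ACGTA", 2, "-", "CpG", "CGT"),  # G on + strand reads leftward
        ],
    )
    def test_definition_examples(self, seq, pos, strand, context, tri):
        sites = extract_cytosine_sites(Genome({"c": seq}))
        row = sites[(sites["pos"] == pos) & (sites["strand"] == strand)]
        assert len(row) == 1
        assert row.iloc[0]["context"] == context
        assert row.iloc[0]["tri"] == tri

    def test_matches_bruteforce_oracle_on_random_sequence(self, rng):
        seq = random_dna(rng, 10_000, p_n=0.01)
        got = extract_cytosine_sites(Genome({"c": seq}))
        got_set = set(zip(got["pos"], got["strand"], got["context"]))
        assert got_set == oracle_sites(seq)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    def test_matches_oracle_property(self, seq):
        got = extract_cytosine_sites(Genome({"c": seq}))
        got_set = set(zip(got["pos"], got["strand"], got["context"]))
        assert got_set == oracle_sites(seq)

    def test_trinucleotide_is_own_strand_3mer(self, rng):
        seq = random_dna(rng, 2000)
        sites = extract_cytosine_sites(Genome({"c": seq}))
        minus = sites[sites["strand"] == "-"].head(20)
        for r in minus.itertuples():
            assert r.tri == revcomp(seq[r.pos - 2 : r.pos + 1])
            assert r.tri[0] == "C"

    def test_context_frequencies_on_uniform_sequence(self, rng):
        # given a random C, P(CpG)=1/4, P(CHG)=3/16, P(CHH)=9/16
        seq = random_dna(rng, 250_000)
        sites = extract_cytosine_sites(Genome({"c": seq}))
        n = len(sites)
        assert n > 1e5
        freq = sites["context"].value_counts(normalize=True)
        for ctx, expected in [("CpG", 1 / 4), ("CHG", 3 / 16), ("CHH", 9 / 16)]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq[ctx] - expected) < 4 * se

    def test_edge_and_n_sites_excluded(self):
        # pos 1 has an N among its two downstream bases; pos 4 is at the edge
        sites = extract_cytosine_sites(Genome({"c": "CCGNC"}))
        plus = sites[sites["strand"] == "+"]
        assert plus["pos"].tolist() == [0]
        assert plus["context"].tolist() == ["CHG"]

    def test_empty_contig_rejected(self):
        with pytest.raises(ValidationError):
            Genome({"c": ""})

    def test_non_dna_character_names_contig_and_offset(self):
        with pytest.raises(ValidationError, match="c2.*offset 3"):
            Genome({"c1": "ACGT", "c2": "ACGXT"})


class TestCxReport:
    def test_roundtrip_identity(self, rng, small_genome, tmp_path):
        sites = extract_cytosine_sites(small_genome).head(10)
        table = make_counts(sites, rng.integers(0, 5, 10), rng.integers(0, 20, 10))
        path = tmp_path / "t.cx.tsv"
        write_cx_report(table, path)
        back = read_cx_report(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), table.reset_index(drop=True),
            check_dtype=False, check_like=True,
        )

    def test_extract_write_read_reextract_idempotent(self, small_genome, tmp_path):
        sites = extract_cytosine_sites(small_genome)
        table = make_counts(sites, 0, 0)
        path = tmp_path / "all.cx.tsv"
        write_cx_report(table, path)
        back = read_cx_report(path, sites=sites)  # validates contexts too
        again = extract_cytosine_sites(small_genome)
        assert back[["chrom", "pos", "strand", "context", "tri"]].equals(
            again[["chrom", "pos", "strand", "context", "tri"]]
        )

    def test_context_mismatch_raises(self, small_genome, tmp_path):
        sites = extract_cytosine_sites(small_genome)
        table = make_counts(sites.head(5), 1, 1)
        table.loc[0, "context"] = (
            "CHH" if table.loc[0, "context"] != "CHH" else "CpG"
        )
        path = tmp_path / "bad.cx.tsv"
        write_cx_report(table, path)
        with pytest.raises(ValidationError, match="disagrees"):
            read_cx_report(path, sites=sites)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "empty.cx.tsv"
        path.touch()
        out = read_cx_report(path)
        assert out.empty

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.cx.tsv"
        path.write_text("chr1\t10\t+\t3\t4\tCpG\tCGA\nchr1\txx\t+\t3\t4\tCpG\tCGA\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_cx_report(path)

    def test_unknown_contig_rejected(self, small_genome, tmp_path):
        sites = extract_cytosine_sites(small_genome)
        path = tmp_path / "uc.cx.tsv"
        path.write_text("chr9\t10\t+\t3\t4\tCpG\tCGA\n")
        with pytest.raises(ValidationError, match="chr9"):
            read_cx_report(path, sites=sites)


class TestAnnotationIo:
    def test_gene_tss_tes_by_strand(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1001\t3000\t.\t+\t.\tID=gplus\n"
            "chr1\tx\tgene\t1001\t3000\t.\t-\t.\tID=gminus\n"
        )
        genes, exons = read_gene_models(gff)
        gp = genes[genes.gene_id == "gplus"].iloc[0]
        gm = genes[genes.gene_id == "gminus"].iloc[0]
        assert (gp.tss, gp.tes) == (1000, 2999)  # 0-based
        assert (gm.tss, gm.tes) == (2999, 1000)
        # exonless genes become single-exon
        assert set(exons.gene_id) == {"gplus", "gminus"}

    def test_mature_outside_precursor_rejected(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "chr1\tx\tmiRNA_primary_transcript\t100\t220\t.\t+\t.\tID=miR1\n"
            "chr1\tx\tmiRNA\t10\t31\t.\t+\t.\tID=miR1.m;Derives_from=miR1\n"
        )
        with pytest.raises(ValidationError, match="outside"):
            read_mirna_loci(gff)

    def test_bed_is_zero_based_half_open(self, tmp_path):
        # a region covering 1-based 101..200 is internally start=100, end=200
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        path = tmp_path / "r.bed"
        write_bed(regions, path)
        fields = path.read_text().strip().split("\t")
        assert fields[:3] == ["chr1", "100", "200"]
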