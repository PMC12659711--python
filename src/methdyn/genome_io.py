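"""Genome and annotation I/O plus strand-aware cytosine context extraction.

Cytosine contexts follow the plant convention: CpG, CHG and CHH, where H is
A, T or C, read on the cytosine's own strand.  A cytosine on the minus
strand is a G in the reference; its downstream bases are the complemented
reference bases immediately to its left.

File dialects handled here:

* FASTA genomes (via :mod:`pyfaidx`); contigs flagged as chloroplast by name
  are the conversion-error calibration null.
* CX reports: tab-separated per-cytosine count files with columns
  ``contig, 1-based position, strand, meth_reads, unmeth_reads, context,
  trinucleotide`` — one file per sample replicate.
* GFF3 gene models (gene/mRNA/exon, optional UTR features) and miRBase-style
  GFF3 for miRNA loci (miRNA_primary_transcript + miRNA).
* BED6 exports, 0-based half-open.

All in-memory tables use 0-based positions.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._util import CONTEXTS, ValidationError, logger, revcomp

_VALID_BASES = frozenset(b"ACGTN")

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]

# Default substrings used to recognise the chloroplast contig when no
# explicit flag list is supplied.
CHLOROPLAST_HINTS = ("chrc", "chloroplast", "chrpt", "pltd", "pt")


@dataclass
class Genome:
    """A genome as an ordered mapping of contig name -> uppercase sequence.

    ``chloroplast`` names exactly the contigs used as the unmethylated
    calibration null for the bisulfite conversion-error estimate.
    """

    sequences: dict[str, str]
    chloroplast: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"contig {name!r} is empty")
            bad = set(seq.upper().encode()) - _VALID_BASES
            if bad:
                offset = next(
                    i for i, ch in enumerate(seq.upper().encode()) if ch not in _VALID_BASES
                )
                raise ValidationError(
                    f"contig {name!r} has non-DNA character "
                    f"{chr(sorted(bad)[0])!r} at offset {offset}"
                )
            self.sequences[name] = seq.upper()
        unknown = self.chloroplast - set(self.sequences)
        if unknown:
            raise ValidationError(f"chloroplast flags name unknown contigs: {sorted(unknown)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __iter__(self):
        return iter(self.sequences)


def read_genome(path: str | os.PathLike, chloroplast: set[str] | None = None) -> Genome:
    """Load a FASTA genome; guess the chloroplast contig by name if not given."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if chloroplast is None:
        chloroplast = {n for n in seqs if n.lower() in CHLOROPLAST_HINTS
                       or "chloroplast" in n.lower()}
    return Genome(seqs, set(chloroplast))


def write_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cytosine context extraction
# ---------------------------------------------------------------------------

def _extract_contig_sites(name: str, seq: str) -> tuple[pd.DataFrame, int]:
    """Vectorised site extraction for one contig. Returns (sites, n_excluded)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = arr.size
    C, G, N = ord("C"), ord("G"), ord("N")

    frames = []
    excluded = 0

    # plus strand: cytosines with two determinable downstream bases
    plus = np.flatnonzero(arr == C)
    if plus.size:
        ok = plus < L - 2
        excluded += int((~ok).sum())
        cand = plus[ok]
        d1, d2 = arr[cand + 1], arr[cand + 2]
        good = (d1 != N) & (d2 != N)
        excluded += int((~good).sum())
        cand, d1, d2 = cand[good], d1[good], d2[good]
        ctx = np.where(d1 == G, 0, np.where(d2 == G, 1, 2))
        tri = [seq[i : i + 3] for i in cand]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": cand,
                    "strand": "+",
                    "context": np.array(CONTEXTS)[ctx],
                    "tri": tri,
                }
            )
        )

    # minus strand: reference G; downstream bases are complemented bases to
    # the left, so context depends on seq[i-1], seq[i-2]
    minus = np.flatnonzero(arr == G)
    if minus.size:
        ok = minus >= 2
        excluded += int((~ok).sum())
        cand = minus[ok]
        u1, u2 = arr[cand - 1], arr[cand - 2]
        good = (u1 != N) & (u2 != N)
        excluded += int((~good).sum())
        cand, u1, u2 = cand[good], u1[good], u2[good]
        # next base on − strand is complement(u1): G iff u1 == C
        ctx = np.where(u1 == C, 0, np.where(u2 == C, 1, 2))
        tri = [revcomp(seq[i - 2 : i + 1]) for i in cand]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": cand,
                    "strand": "-",
                    "context": np.array(CONTEXTS)[ctx],
                    "tri": tri,
                }
            )
        )

    if not frames:
        return (
            pd.DataFrame(columns=["chrom", "pos", "strand", "context", "tri"]),
            excluded,
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)
    return out, excluded


def extract_cytosine_sites(genome: Genome) -> pd.DataFrame:
    """All cytosines of a genome with strand, context and trinucleotide.

    A site whose two downstream bases (on its own strand) are not both
    determinable — contig edge or an N — is excluded rather than guessed;
    exclusions are counted in the log.  Positions are 0-based.
    """
    frames, excluded = [], 0
    for name, seq in genome.sequences.items():
        df, nex = _extract_contig_sites(name, seq)
        frames.append(df)
        excluded += nex
    if excluded:
        logger.info("extract_cytosine_sites: excluded %d edge/ambiguous sites", excluded)
    out = pd.concat(frames, ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# CX reports
# ---------------------------------------------------------------------------

def write_cx_report(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-cytosine count table as a 7-column CX report (1-based)."""
    out = table[CX_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_cx_report(
    path: str | os.PathLike, sites: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a CX report; optionally validate contexts against genome sites.

    Returns a table with 0-based positions.  An empty file yields an empty
    table with a warning.  Malformed lines raise :class:`ValidationError`
    naming the line number; a context disagreeing with the genome-derived
    context for the same (contig, position, strand) raises too.
    """
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        logger.warning("read_cx_report: %s is empty", path)
        return pd.DataFrame(columns=CX_COLUMNS)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "tri": str,
            },
        )
    except Exception as exc:  # surface pandas' line info, wrapped
        raise ValidationError(f"malformed CX report {path}: {exc}") from exc
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValidationError(
                f"malformed CX report {path}: bad {col!r} value at line {line}"
            )
        df[col] = vals.astype(np.int64)
    badctx = ~df["context"].isin(CONTEXTS)
    if badctx.any():
        line = int(badctx.idxmax()) + 1
        raise ValidationError(f"malformed CX report {path}: unknown context at line {line}")
    badstr = ~df["strand"].isin(["+", "-"])
    if badstr.any():
        line = int(badstr.idxmax()) + 1
        raise ValidationError(f"malformed CX report {path}: bad strand at line {line}")
    df["pos"] = df["pos"] - 1

    if sites is not None:
        unknown = set(df["chrom"]) - set(sites["chrom"])
        if unknown:
            raise ValidationError(f"CX report {path} names unknown contigs: {sorted(unknown)}")
        merged = df.merge(
            sites[["chrom", "pos", "strand", "context"]],
            on=["chrom", "pos", "strand"],
            how="left",
            suffixes=("", "_genome"),
        )
        missing = merged["context_genome"].isna()
        if missing.any():
            row = merged[missing].iloc[0]
            raise ValidationError(
                f"CX report {path}: record at {row.chrom}:{row.pos + 1}({row.strand}) "
                "is not a genome cytosine site"
            )
        mismatch = merged["context"] != merged["context_genome"]
        if mismatch.any():
            row = merged[mismatch].iloc[0]
            raise ValidationError(
                f"CX report {path}: context {row.context!r} at "
                f"{row.chrom}:{row.pos + 1}({row.strand}) disagrees with "
                f"genome context {row.context_genome!r}"
            )
    return df


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff3(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(f"GFF3 {path}: line {lineno} has {len(parts)} columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attrd = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrd[k.strip()] = v.strip()
            rows.append(
                {
                    "chrom": chrom,
                    "type": ftype,
                    "start": int(start) - 1,  # to 0-based half-open
                    "end": int(end),
                    "strand": strand,
                    "attrs": attrd,
                }
            )
    return pd.DataFrame(rows)


def _feature_id(attrs: dict) -> str | None:
    return attrs.get("ID") or attrs.get("Name")


def read_gene_models(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene models from GFF3.

    Returns ``(genes, exons)``.  ``genes`` has one row per gene with
    0-based half-open ``start``/``end`` and strand-resolved ``tss``/``tes``
    (0-based positions: for a + gene tss == start, tes == end − 1; for a −
    gene tss == end − 1, tes == start).  ``exons`` maps gene_id to exon
    intervals.  A gene without exon children is treated as single-exon with
    a warning.
    """
    df = _parse_gff3(path)
    if df.empty:
        raise ValidationError(f"GFF3 {path} contains no features")
    genes = df[df["type"] == "gene"].copy()
    if genes.empty:
        raise ValidationError(f"GFF3 {path} contains no gene features")
    genes["gene_id"] = genes["attrs"].map(_feature_id)
    zero = genes["end"] <= genes["start"]
    if zero.any():
        raise ValidationError(f"GFF3 {path}: zero-length gene {genes[zero].iloc[0]['gene_id']}")

    # map mRNA id -> gene id so exons attach through their transcript
    mrna = df[df["type"] == "mRNA"]
    mrna_to_gene = {
        _feature_id(a): a.get("Parent") for a in mrna["attrs"] if _feature_id(a)
    }

    exon_rows = []
    for _, row in df[df["type"] == "exon"].iterrows():
        parent = row["attrs"].get("Parent")
        gene_id = mrna_to_gene.get(parent, parent)
        exon_rows.append(
            {"gene_id": gene_id, "chrom": row["chrom"], "start": row["start"], "end": row["end"]}
        )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    have_exons = set(exons["gene_id"])
    missing = [g for g in genes["gene_id"] if g not in have_exons]
    if missing:
        logger.warning(
            "read_gene_models: %d genes without exons treated as single-exon", len(missing)
        )
        single = genes[genes["gene_id"].isin(missing)]
        exons = pd.concat(
            [exons, single[["gene_id", "chrom", "start", "end"]]], ignore_index=True
        )

    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    genes["tes"] = np.where(genes["strand"] == "+", genes["end"] - 1, genes["start"])
    out = genes[["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]].reset_index(
        drop=True
    )
    return out, exons.reset_index(drop=True)


def read_mirna_loci(path: str | os.PathLike) -> pd.DataFrame:
    """Read miRBase-style GFF3 with precursor + mature features.

    Returns one row per miRNA locus: ``mirna_id, chrom, strand, pre_start,
    pre_end, mat_start, mat_end`` (0-based half-open).  A mature feature not
    contained in its precursor is an error.
    """
    df = _parse_gff3(path)
    pre = df[df["type"] == "miRNA_primary_transcript"].copy()
    mat = df[df["type"] == "miRNA"].copy()
    if pre.empty:
        raise ValidationError(f"GFF3 {path}: no miRNA_primary_transcript features")
    pre["mirna_id"] = pre["attrs"].map(_feature_id)
    by_id = {r.mirna_id: r for r in pre.itertuples()}
    rows = []
    for r in mat.itertuples():
        parent = r.attrs.get("Derives_from") or r.attrs.get("Parent")
        p = by_id.get(parent)
        if p is None:
            raise ValidationError(f"GFF3 {path}: mature {_feature_id(r.attrs)} has no precursor")
        if r.start < p.start or r.end > p.end:
            raise ValidationError(
                f"GFF3 {path}: mature feature of {parent} lies outside its precursor"
            )
        rows.append(
            {
                "mirna_id": parent,
                "chrom": p.chrom,
                "strand": p.strand,
                "pre_start": p.start,
                "pre_end": p.end,
                "mat_start": r.start,
                "mat_end": r.end,
            }
        )
    return pd.DataFrame(rows)


def write_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write BED6 (0-based half-open). Expects chrom/start/end and optional
    name/score/strand columns."""
    out = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int),
            "end": regions["end"].astype(int),
            "name": regions.get("name", pd.Series(["."] * len(regions))).values,
            "score": regions.get("score", pd.Series([0] * len(regions))).values,
            "strand": regions.get("strand", pd.Series(["."] * len(regions))).values,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")
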