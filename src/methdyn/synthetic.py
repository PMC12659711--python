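"""Seeded miniature-study generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a small nuclear
genome plus an unmethylated chloroplast contig, gene and miRNA annotation,
per-context baseline methylation levels, two biological replicates per
sample with negative-binomial depth, bisulfite conversion failure at a
known rate, planted differentially methylated windows on three comparison
axes (tissue, cultivar, drought), and expression tables in which a
configured fraction of drought-DMR host genes move in the opposite
direction.  Everything derives from one integer seed; identical seeds give
byte-identical output files, recorded with hashes in a ground-truth
manifest.

The generator draws depth independently per cytosine and models no
positional autocorrelation, read-level errors or transposon architecture —
it exercises the pipeline's filters, not the full texture of real WGBS.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._util import CONTEXTS, MethdynError
from . import genome_io
from .genome_io import Genome

CULTIVARS = ("IR64", "N22")
TISSUES = ("panicle", "flagleaf")
CONDITIONS = ("control", "drought")

BETA_PARAMS = {"CpG": (5.0, 2.0), "CHG": (2.0, 3.0), "CHH": (1.0, 12.0)}


@dataclass
class PlantedDmrSpec:
    n_tissue: int = 20
    n_cultivar: int = 20
    n_drought: int = 20          # per cultivar
    delta: float = 0.4
    low_level: float = 0.15
    width: int = 100
    min_sites: int = 6           # target-context sites a planted window must hold


@dataclass
class PlantedExpressionSpec:
    anticorr_fraction: float = 1.0
    log2fc: float = 2.0
    n_background_degs: int = 10


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    chloroplast_name: str = "chrC"
    chloroplast_length: int = 20_000
    n_genes: int = 120
    n_mirna: int = 20
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    e_true: float = 0.014
    n_replicates: int = 2
    beta_params: dict = field(default_factory=lambda: dict(BETA_PARAMS))
    dmr_spec: PlantedDmrSpec = field(default_factory=PlantedDmrSpec)
    expr_spec: PlantedExpressionSpec = field(default_factory=PlantedExpressionSpec)
    n_mirna_dmfs: int = 6


def sample_id(cultivar: str, tissue: str, condition: str) -> str:
    return f"{cultivar}_{tissue}_{condition}"


def all_samples() -> list[tuple[str, str, str]]:
    return [(c, t, d) for c in CULTIVARS for t in TISSUES for d in CONDITIONS]


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def _random_genome(cfg: SimulationConfig, rng: np.random.Generator) -> Genome:
    seqs = {}
    for chrom, length in cfg.chrom_lengths.items():
        seqs[chrom] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    seqs[cfg.chloroplast_name] = "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, cfg.chloroplast_length)]
    )
    return Genome(seqs, {cfg.chloroplast_name})


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes laid out in regular slots so bodies never overlap."""
    chroms = list(cfg.chrom_lengths)
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    rows, exon_rows = [], []
    gid = 0
    for chrom in chroms:
        length = cfg.chrom_lengths[chrom]
        slot = length // per_chrom
        if slot < 1500:
            raise MethdynError("too many genes for the contig length")
        for s in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            glen = int(rng.integers(1200, min(2600, slot - 300)))
            start = s * slot + int(rng.integers(100, slot - glen - 100))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid:04d}"
            rows.append(
                {
                    "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end - 1,
                    "tes": end - 1 if strand == "+" else start,
                }
            )
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), 2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], dtype=int)
            bounds = np.concatenate(([start], cuts, [end]))
            for i in range(n_exons):
                exon_rows.append(
                    {"gene_id": gene_id, "chrom": chrom,
                     "start": int(bounds[2 * i]), "end": int(bounds[2 * i + 1])}
                )
            gid += 1
    return pd.DataFrame(rows), pd.DataFrame(exon_rows)


def _place_mirnas(cfg: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
                  ) -> pd.DataFrame:
    """miRNA precursors dropped into gaps between gene bodies on the last
    nuclear contig."""
    chrom = list(cfg.chrom_lengths)[-1]
    length = cfg.chrom_lengths[chrom]
    gb = genes[genes["chrom"] == chrom].sort_values("start")
    gaps = []
    prev = 0
    for g in gb.itertuples():
        if g.start - prev > 400:
            gaps.append((prev, g.start))
        prev = g.end
    if length - prev > 400:
        gaps.append((prev, length))
    rows = []
    for i in range(cfg.n_mirna):
        lo, hi = gaps[i % len(gaps)]
        plen = int(rng.integers(100, 150))
        start = int(rng.integers(lo + 50, max(lo + 51, hi - plen - 50)))
        strand = "+" if rng.random() < 0.5 else "-"
        mstart = start + int(rng.integers(10, plen - 31))
        rows.append(
            {
                "mirna_id": f"miR{i:03d}", "chrom": chrom, "strand": strand,
                "pre_start": start, "pre_end": start + plen,
                "mat_start": mstart, "mat_end": mstart + 21,
            }
        )
    return pd.DataFrame(rows)


def _write_gene_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        ex_by_gene = {g: df for g, df in exons.groupby("gene_id")}
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for j, e in enumerate(ex_by_gene[g.gene_id].sort_values("start").itertuples()):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{j};Parent={mrna}\n"
                )


def _write_mirna_gff3(loci: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in loci.itertuples():
            fh.write(
                f"{m.chrom}\tsim\tmiRNA_primary_transcript\t{m.pre_start + 1}\t{m.pre_end}"
                f"\t.\t{m.strand}\t.\tID={m.mirna_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsim\tmiRNA\t{m.mat_start + 1}\t{m.mat_end}\t.\t{m.strand}\t.\t"
                f"ID={m.mirna_id}.mature;Derives_from={m.mirna_id}\n"
            )


# ---------------------------------------------------------------------------
# methylome construction and DMR planting
# ---------------------------------------------------------------------------

def _baseline_levels(sites: pd.DataFrame, cfg: SimulationConfig,
                     rng: np.random.Generator, block: int = 100) -> np.ndarray:
    """Per-site baseline true levels.

    Methylation is locally correlated, so levels are drawn per 100-bp block
    and context from the context's Beta distribution and shared by the
    block's sites; the chloroplast is identically unmethylated.
    """
    levels = np.zeros(len(sites))
    chloro = (sites["chrom"] == cfg.chloroplast_name).to_numpy()
    ctx = sites["context"].to_numpy()
    chrom_codes, _ = pd.factorize(sites["chrom"])
    blk = sites["pos"].to_numpy() // block
    for name in CONTEXTS:
        a, b = cfg.beta_params[name]
        mask = (ctx == name) & ~chloro
        key = chrom_codes[mask].astype(np.int64) * 2**32 + blk[mask]
        uniq, inv = np.unique(key, return_inverse=True)
        levels[mask] = rng.beta(a, b, uniq.size)[inv]
    return levels


def plant_dmrs(
    sites: pd.DataFrame,
    levels: dict[str, np.ndarray],
    genes: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Force planted window levels per comparison axis; returns manifest rows.

    Planted windows are 100-bp tiles whose midpoint lies inside a gene body
    (so drought-axis plants map cleanly to a host gene), hold at least
    ``min_sites`` cytosines of the target context, and never touch the
    chloroplast.  For a planted window the target-context sites take
    ``low_level`` on the reference side and ``low_level + delta`` on the
    focal side, so the level ratio clears the 1.5-fold filter by
    construction.
    """
    spec = cfg.dmr_spec
    if spec.low_level + spec.delta > 1:
        raise MethdynError("planted delta pushes levels above 1")
    width = spec.width
    site_chrom = sites["chrom"].to_numpy()
    site_win = sites["pos"].to_numpy() // width
    site_ctx = sites["context"].to_numpy()

    # candidate (window, gene, context) triples: midpoint inside a gene body
    # and clear of every other gene's <=1-kb promoter, whose precedence would
    # otherwise annotate the window to the neighbour
    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")
    }
    candidates = []
    for g in genes.itertuples():
        w_lo = (g.start + width) // width      # windows fully inside-ish
        w_hi = g.end // width
        for w in range(w_lo, w_hi):
            mid = w * width + width // 2
            if not (g.start <= mid < g.end):
                continue
            tss = tss_by_chrom[g.chrom]
            near = tss[np.abs(tss - mid) <= 1000 + width]
            if any(t != g.tss for t in near):
                continue
            mask = (site_chrom == g.chrom) & (site_win == w)
            for ctx in CONTEXTS:
                if (mask & (site_ctx == ctx)).sum() >= spec.min_sites:
                    candidates.append((g.chrom, w, ctx, g.gene_id))
    if not candidates:
        raise MethdynError(
            "no plantable windows: context density too low, widen windows or genome"
        )
    rng.shuffle(candidates)
    need = spec.n_tissue + spec.n_cultivar + 2 * spec.n_drought
    # at most one planted window per gene keeps DMR-gene links unambiguous
    chosen, used_genes, used_windows = [], set(), set()
    for chrom, w, ctx, gid in candidates:
        if gid in used_genes or (chrom, w) in used_windows:
            continue
        chosen.append((chrom, w, ctx, gid))
        used_genes.add(gid)
        used_windows.add((chrom, w))
        if len(chosen) == need:
            break
    if len(chosen) < need:
        raise MethdynError(
            f"only {len(chosen)} plantable windows for {need} requested; "
            "widen windows or enlarge the genome"
        )

    manifest = []
    idx = 0

    def plant(axis: str, n: int, focal_samples, reference_samples, extra=None):
        nonlocal idx
        for _ in range(n):
            chrom, w, ctx, gid = chosen[idx]
            idx += 1
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            hi = spec.low_level + spec.delta
            focal_level = hi if direction == "hyper" else spec.low_level
            ref_level = spec.low_level if direction == "hyper" else hi
            mask = (
                (site_chrom == chrom) & (site_win == w) & (site_ctx == ctx)
            )
            for s in focal_samples:
                levels[s][mask] = focal_level
            for s in reference_samples:
                levels[s][mask] = ref_level
            manifest.append(
                {
                    "axis": axis, "chrom": chrom, "start": int(w * width),
                    "end": int((w + 1) * width), "context": ctx,
                    "direction": direction, "gene_id": gid,
                    **(extra or {}),
                }
            )

    # tissue axis: focal = panicle, across cultivars and conditions
    plant(
        "tissue", spec.n_tissue,
        [sample_id(c, "panicle", d) for c in CULTIVARS for d in CONDITIONS],
        [sample_id(c, "flagleaf", d) for c in CULTIVARS for d in CONDITIONS],
    )
    # cultivar axis: focal = N22
    plant(
        "cultivar", spec.n_cultivar,
        [sample_id("N22", t, d) for t in TISSUES for d in CONDITIONS],
        [sample_id("IR64", t, d) for t in TISSUES for d in CONDITIONS],
    )
    # drought axis, per cultivar: focal = drought
    for cultivar in CULTIVARS:
        plant(
            "drought", spec.n_drought,
            [sample_id(cultivar, t, "drought") for t in TISSUES],
            [sample_id(cultivar, t, "control") for t in TISSUES],
            extra={"cultivar": cultivar},
        )
    return manifest


def _plant_mirna_dmfs(
    sites: pd.DataFrame,
    levels: dict[str, np.ndarray],
    mirnas: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Drought-axis methylation shifts on miRNA promoter/downstream features
    of the tolerant cultivar's samples (the miRNA analysis cell)."""
    from .mirna_dmf import derive_all_features

    lengths = {**cfg.chrom_lengths, cfg.chloroplast_name: cfg.chloroplast_length}
    feats = derive_all_features(mirnas, lengths)
    feats = feats[
        feats["feature"].str.startswith(("promoter_", "downstream_")) & ~feats["empty"]
    ]
    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    site_ctx = sites["context"].to_numpy()
    chosen_ids = rng.choice(mirnas["mirna_id"], size=min(cfg.n_mirna_dmfs, len(mirnas)),
                            replace=False)
    spec = cfg.dmr_spec
    manifest = []
    for mid in chosen_ids:
        f = feats[feats["mirna_id"] == mid].sample(1, random_state=int(rng.integers(2**31)))
        f = f.iloc[0]
        ctx = "CHH"
        mask = (
            (site_chrom == f.chrom)
            & (site_pos >= f.start)
            & (site_pos < f.end)
            & (site_ctx == ctx)
        )
        if mask.sum() < spec.min_sites:
            continue
        direction = "hyper"
        hi = spec.low_level + spec.delta
        for t in TISSUES:
            levels[sample_id("N22", t, "drought")][mask] = hi
            levels[sample_id("N22", t, "control")][mask] = spec.low_level
        manifest.append(
            {
                "mirna_id": mid, "feature": f.feature, "context": ctx,
                "direction": direction, "chrom": f.chrom,
                "start": int(f.start), "end": int(f.end),
            }
        )
    return manifest


# ---------------------------------------------------------------------------
# counts and expression
# ---------------------------------------------------------------------------

def _draw_counts(
    sites: pd.DataFrame, true_levels: np.ndarray, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One replicate's CX count table: NB depth, binomial methylated reads.

    The observed per-site methylated-read probability is
    m + (1 − m)·e_true: methylated molecules always read C, unmethylated
    ones read C only on conversion failure.
    """
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.depth_mean)
    depth = rng.negative_binomial(r, p_nb, len(sites))
    prob = true_levels + (1.0 - true_levels) * cfg.e_true
    meth = rng.binomial(depth, prob)
    out = sites[["chrom", "pos", "strand", "context", "tri"]].copy()
    out["meth"] = meth
    out["unmeth"] = depth - meth
    return out[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]]


def plant_expression(
    genes: pd.DataFrame,
    dmr_manifest: list[dict],
    cultivar: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict]]:
    """Expression table for one cultivar's drought comparison.

    A configured fraction of genes hosting that cultivar's planted drought
    DMRs move in the opposite direction (hyper DMR -> down DEG, hypo -> up)
    with FDR and fold-change set to pass DEG selection; the construction is
    exact, with no noise on status.
    """
    spec = cfg.expr_spec
    n = len(genes)
    fpkm_control = np.exp(rng.normal(1.0, 1.2, n))
    # a sprinkle of silent genes
    silent_idx = rng.choice(n, max(2, n // 10), replace=False)
    fpkm_control[silent_idx] = rng.uniform(0.0, 0.4, silent_idx.size)
    fpkm_stress = fpkm_control * np.exp(rng.normal(0.0, 0.05, n))
    fdr = rng.uniform(0.2, 1.0, n)

    planted = [
        m for m in dmr_manifest if m["axis"] == "drought" and m.get("cultivar") == cultivar
    ]
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    fc_mult = 2.0 ** cfg.expr_spec.log2fc
    manifest = []
    n_anti = int(round(spec.anticorr_fraction * len(planted)))
    for j, m in enumerate(planted):
        i = gene_pos[m["gene_id"]]
        fpkm_control[i] = max(fpkm_control[i], 2.0)
        if j < n_anti:
            if m["direction"] == "hyper":
                fpkm_stress[i] = fpkm_control[i] / fc_mult
                status = "down"
            else:
                fpkm_stress[i] = fpkm_control[i] * fc_mult
                status = "up"
            fdr[i] = 1e-4
            manifest.append(
                {"gene_id": m["gene_id"], "cultivar": cultivar,
                 "dmr_direction": m["direction"], "expr_status": status}
            )
        else:
            fpkm_stress[i] = fpkm_control[i]
            fdr[i] = 0.9
    # background DEGs unlinked to planted DMRs
    planted_ids = {m["gene_id"] for m in planted}
    free = [i for g, i in gene_pos.items() if g not in planted_ids]
    bg = rng.choice(free, min(spec.n_background_degs, len(free)), replace=False)
    for i in bg:
        fpkm_control[i] = max(fpkm_control[i], 1.0)
        fpkm_stress[i] = fpkm_control[i] * (fc_mult if rng.random() < 0.5 else 1 / fc_mult)
        fdr[i] = 1e-3

    expr = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "fpkm_control": fpkm_control,
            "fpkm_stress": fpkm_stress,
            "fc": fpkm_stress / np.maximum(fpkm_control, 1e-9),
            "log2fc": np.log2(fpkm_stress / np.maximum(fpkm_control, 1e-9)),
            "fdr": fdr,
        }
    )
    return expr, manifest


def _mirna_expression(
    mirnas: pd.DataFrame, dmf_manifest: list[dict], genes: pd.DataFrame,
    dmr_manifest: list[dict], rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    planted = {m["mirna_id"]: m for m in dmf_manifest}
    tpm_c = np.exp(rng.normal(2.0, 1.0, len(mirnas)))
    log2fc = rng.normal(0.0, 0.3, len(mirnas))
    for i, mid in enumerate(mirnas["mirna_id"]):
        if mid in planted:
            # hyper-methylated feature -> repressed miRNA
            log2fc[i] = -2.0 + rng.normal(0, 0.1)
    expr = pd.DataFrame(
        {
            "mirna_id": mirnas["mirna_id"],
            "tpm_control": tpm_c,
            "tpm_stress": tpm_c * 2.0 ** log2fc,
            "log2fc": log2fc,
        }
    )
    # targets: two genes per miRNA, avoiding planted-DMR hosts
    hosts = {m["gene_id"] for m in dmr_manifest}
    free = [g for g in genes["gene_id"] if g not in hosts]
    rows = []
    for mid in mirnas["mirna_id"]:
        for g in rng.choice(free, 2, replace=False):
            rows.append({"mirna_id": mid, "gene_id": g})
    return expr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level study simulation
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_study(cfg: SimulationConfig, outdir: str | os.PathLike) -> dict:
    """Generate the full synthetic study under ``outdir``.

    Writes genome FASTA, gene and miRNA GFF3, 16 CX reports (2 cultivars x
    2 tissues x 2 conditions x 2 replicates), one expression table per
    cultivar x tissue, miRNA expression and target tables, and
    ``manifest.json`` with the planted truth and file hashes.  Returns the
    manifest as a dict.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    keys = ["genome", "genes", "mirna", "baseline", "plant", "mirna_plant",
            "counts", "expr", "mirna_expr"]
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    genome = _random_genome(cfg, rngs["genome"])
    genes, exons = _place_genes(cfg, rngs["genes"])
    mirnas = _place_mirnas(cfg, genes, rngs["mirna"])

    sites = genome_io.extract_cytosine_sites(genome)
    baseline = _baseline_levels(sites, cfg, rngs["baseline"])
    levels = {sample_id(*s): baseline.copy() for s in all_samples()}

    dmr_manifest = plant_dmrs(sites, levels, genes, cfg, rngs["plant"])
    for m in dmr_manifest:
        if m["chrom"] == cfg.chloroplast_name:
            raise MethdynError("planted DMR overlaps the chloroplast contig")
    dmf_manifest = _plant_mirna_dmfs(sites, levels, mirnas, cfg, rngs["mirna_plant"])

    paths: dict[str, str] = {}
    genome_path = os.path.join(outdir, "genome.fa")
    genome_io.write_genome(genome, genome_path)
    paths["genome"] = genome_path
    gff_path = os.path.join(outdir, "genes.gff3")
    _write_gene_gff3(genes, exons, gff_path)
    paths["genes"] = gff_path
    mir_path = os.path.join(outdir, "mirna.gff3")
    _write_mirna_gff3(mirnas, mir_path)
    paths["mirna"] = mir_path

    cx_dir = os.path.join(outdir, "cx")
    os.makedirs(cx_dir, exist_ok=True)
    counts_ss = rngs["counts"].bit_generator.seed_seq.spawn(
        len(all_samples()) * cfg.n_replicates
    )
    i = 0
    for c, t, d in all_samples():
        sid = sample_id(c, t, d)
        for rep in range(1, cfg.n_replicates + 1):
            rng = np.random.default_rng(counts_ss[i]); i += 1
            tab = _draw_counts(sites, levels[sid], cfg, rng)
            p = os.path.join(cx_dir, f"{sid}_rep{rep}.cx.tsv")
            genome_io.write_cx_report(tab, p)
            paths[f"cx/{sid}_rep{rep}"] = p

    expr_manifest = []
    for c in CULTIVARS:
        expr, man = plant_expression(genes, dmr_manifest, c, cfg, rngs["expr"])
        expr_manifest.extend(man)
        for t in TISSUES:
            p = os.path.join(outdir, f"expression_{c}_{t}.tsv")
            expr.to_csv(p, sep="\t", index=False, lineterminator="\n")
            paths[f"expression_{c}_{t}"] = p

    mir_expr, targets = _mirna_expression(
        mirnas, dmf_manifest, genes, dmr_manifest, rngs["mirna_expr"]
    )
    p = os.path.join(outdir, "mirna_expression.tsv")
    mir_expr.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["mirna_expression"] = p
    p = os.path.join(outdir, "mirna_targets.tsv")
    targets.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["mirna_targets"] = p

    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "e_true": cfg.e_true,
        "planted_dmrs": dmr_manifest,
        "planted_mirna_dmfs": dmf_manifest,
        "planted_degs": expr_manifest,
        "paths": {k: os.path.relpath(v, outdir) for k, v in paths.items()},
        "sha256": {k: _sha256(v) for k, v in paths.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# focused simulators for calibration checks
# ---------------------------------------------------------------------------

def simulate_chloroplast_counts(
    n_cytosines: int = 5000, depth_mean: float = 20.0, e_true: float = 0.0142,
    seed: int = 0, chrom: str = "chrC",
) -> pd.DataFrame:
    """Unmethylated chloroplast-like counts for conversion-error recovery."""
    rng = np.random.default_rng(seed)
    depth = rng.poisson(depth_mean, n_cytosines)
    meth = rng.binomial(depth, e_true)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_cytosines),
            "strand": "+",
            "meth": meth,
            "unmeth": depth - meth,
            "context": "CHH",
            "tri": "CTT",
        }
    )


def simulate_window_experiment(
    n_windows: int = 10_000,
    cyt_per_window: int = 8,
    depth: int = 20,
    n_replicates: int = 2,
    base_level_beta: tuple[float, float] = (1.0, 6.0),
    n_planted: int = 0,
    delta: float = 0.4,
    planted_low: float = 0.15,
    e_true: float = 0.014,
    seed: int = 0,
    width: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired-sample window experiment with optional planted differences.

    Abstract single-contig design: each 100-bp window holds
    ``cyt_per_window`` evenly spaced cytosines of one context.  Both
    samples share per-site true levels except in the first ``n_planted``
    windows, where sample B (the focal side) takes ``planted_low + delta``
    against ``planted_low``.  Returns (counts_a, counts_b, truth).
    """
    rng = np.random.default_rng(seed)
    n_sites = n_windows * cyt_per_window
    win = np.repeat(np.arange(n_windows), cyt_per_window)
    offs = np.tile(
        np.linspace(2, width - 2, cyt_per_window).astype(int), n_windows
    )
    pos = win * width + offs
    # one shared level per window: methylation is locally correlated
    base = np.repeat(rng.beta(*base_level_beta, n_windows), cyt_per_window)
    level_a = base.copy()
    level_b = base.copy()
    planted_mask = win < n_planted
    level_a[planted_mask] = planted_low
    level_b[planted_mask] = planted_low + delta

    def draw(levels: np.ndarray) -> pd.DataFrame:
        meth = np.zeros(n_sites, dtype=np.int64)
        total = np.zeros(n_sites, dtype=np.int64)
        prob = levels + (1 - levels) * e_true
        for _ in range(n_replicates):
            meth += rng.binomial(depth, prob)
            total += depth
        return pd.DataFrame(
            {
                "chrom": "sim", "pos": pos, "strand": "+",
                "meth": meth, "unmeth": total - meth,
                "context": "CHH", "tri": "CTT",
            }
        )

    truth = pd.DataFrame(
        {"win": np.arange(n_windows), "planted": np.arange(n_windows) < n_planted}
    )
    return draw(level_a), draw(level_b), truth
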