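"""miRNA-locus methylation features and differentially methylated features.

Each miRNA locus is partitioned, strand-aware, into eight features: the
mature miRNA, its precursor, three 1-kb promoter bins tiling 3 kb upstream
of the precursor start, and three 1-kb downstream bins past the precursor
end.  On the minus strand upstream/downstream swap genomic sides.  Each
feature is a region of interest for the same Fisher/FDR/coverage/fold
filter stack as windowed DMRs; the results are differentially methylated
features (DMFs).

Anti-correlation chains: a hyper-methylated feature with a down-regulated
miRNA (or hypo with up) is methylation-expression anti-correlated; a
down-regulated miRNA whose target goes up (or vice versa) extends the chain
to the target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import CONTEXTS, MethdynError, logger
from .dmr import DmrThresholds, adjust_fdr, fisher_exact_vector

FEATURE_NAMES = [
    "mature",
    "precursor",
    "promoter_0_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "downstream_0_1kb",
    "downstream_1_2kb",
    "downstream_2_3kb",
]


def derive_mirna_features(locus, contig_length: int) -> pd.DataFrame:
    """Feature intervals for one miRNA locus (0-based half-open).

    ``locus`` needs mirna_id, chrom, strand, pre_start, pre_end, mat_start,
    mat_end.  Flank bins are truncated at contig bounds; empty truncated
    bins are kept with ``empty=True`` so their absence is explicit.
    """
    s, e = int(locus.pre_start), int(locus.pre_end)
    ms, me = int(locus.mat_start), int(locus.mat_end)
    if ms < s or me > e:
        raise MethdynError(f"{locus.mirna_id}: mature feature outside precursor")
    rows = [("mature", ms, me), ("precursor", s, e)]
    for i in range(3):
        if locus.strand == "+":
            prom = (s - 1000 * (i + 1), s - 1000 * i)
            down = (e + 1000 * i, e + 1000 * (i + 1))
        else:
            prom = (e + 1000 * i, e + 1000 * (i + 1))
            down = (s - 1000 * (i + 1), s - 1000 * i)
        rows.append((f"promoter_{i}_{i + 1}kb", *prom))
        rows.append((f"downstream_{i}_{i + 1}kb", *down))
    out = []
    for name, a, b in rows:
        ta, tb = max(0, a), min(b, contig_length)
        truncated = (ta, tb) != (a, b)
        empty = tb <= ta
        if empty:
            ta = tb = max(0, min(a, contig_length))
            logger.info("%s: feature %s truncated to empty", locus.mirna_id, name)
        out.append(
            {
                "mirna_id": locus.mirna_id,
                "chrom": locus.chrom,
                "strand": locus.strand,
                "feature": name,
                "start": ta,
                "end": tb,
                "truncated": truncated,
                "empty": empty,
            }
        )
    return pd.DataFrame(out)


def derive_all_features(loci: pd.DataFrame, contig_lengths: dict[str, int]) -> pd.DataFrame:
    frames = [
        derive_mirna_features(locus, contig_lengths[locus.chrom])
        for locus in loci.itertuples()
    ]
    return pd.concat(frames, ignore_index=True)


def call_dmfs(
    features: pd.DataFrame,
    counts_focal: pd.DataFrame,
    counts_reference: pd.DataFrame,
    thresholds: DmrThresholds = DmrThresholds(),
    contexts=CONTEXTS,
) -> pd.DataFrame:
    """Differential methylation per miRNA feature (regions of interest).

    Pools counts over each feature interval per context (cytosines covered
    at depth >= min_depth in both samples), applies the Fisher test and the
    full DMR filter stack, with the BH family per context across all
    features.  Short features (mature) rarely reach five covered cytosines;
    they are excluded by the coverage filter, visible in the output.
    """
    key = ["chrom", "pos", "strand", "context"]
    merged = counts_focal[key + ["meth", "unmeth"]].merge(
        counts_reference[key + ["meth", "unmeth"]], on=key, suffixes=("_a", "_b")
    )
    depth_a = merged["meth_a"] + merged["unmeth_a"]
    depth_b = merged["meth_b"] + merged["unmeth_b"]
    merged = merged[(depth_a >= thresholds.min_depth) & (depth_b >= thresholds.min_depth)]

    rows = []
    by_chrom = {c: g.sort_values("pos") for c, g in merged.groupby("chrom")}
    feats = features[~features["empty"]]
    for f in feats.itertuples():
        sub = by_chrom.get(f.chrom)
        if sub is None:
            continue
        win = sub[(sub["pos"] >= f.start) & (sub["pos"] < f.end)]
        for ctx in contexts:
            w = win[win["context"] == ctx]
            if w.empty:
                continue
            rows.append(
                {
                    "mirna_id": f.mirna_id,
                    "feature": f.feature,
                    "chrom": f.chrom,
                    "start": f.start,
                    "end": f.end,
                    "context": ctx,
                    "meth_a": int(w["meth_a"].sum()),
                    "unmeth_a": int(w["unmeth_a"].sum()),
                    "meth_b": int(w["meth_b"].sum()),
                    "unmeth_b": int(w["unmeth_b"].sum()),
                    "covered": int(len(w)),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "mirna_id", "feature", "chrom", "start", "end", "context",
                "level_focal", "level_ref", "fc", "direction", "p", "q",
                "covered", "is_dmf",
            ]
        )
    tab = pd.DataFrame(rows)
    la = tab["meth_a"] / (tab["meth_a"] + tab["unmeth_a"])
    lb = tab["meth_b"] / (tab["meth_b"] + tab["unmeth_b"])
    tab["level_focal"], tab["level_ref"] = la, lb
    tab["fc"] = np.maximum(la, lb) / np.maximum(np.minimum(la, lb), thresholds.epsilon)
    tab["direction"] = np.where(la > lb, "hyper", "hypo")
    tab["p"] = fisher_exact_vector(
        tab["meth_a"].to_numpy(), tab["unmeth_a"].to_numpy(),
        tab["meth_b"].to_numpy(), tab["unmeth_b"].to_numpy(),
    )
    tab["q"] = np.nan
    for ctx in contexts:
        mask = tab["context"] == ctx
        if mask.any():
            tab.loc[mask, "q"] = adjust_fdr(tab.loc[mask, "p"].to_numpy())
    tab["is_dmf"] = (
        (tab["p"] < thresholds.fisher_p)
        & (tab["q"] < thresholds.fdr_q)
        & (tab["covered"] >= thresholds.min_cytosines)
        & (tab["fc"] > thresholds.min_fold)
    )
    return tab


def anticorrelate_mirna(
    dmfs: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    targets: pd.DataFrame | None = None,
    target_expr: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Methylation / miRNA / target direction triples.

    ``mirna_expr`` needs mirna_id and log2fc (stress over control);
    ``targets`` maps mirna_id -> gene_id; ``target_expr`` is a
    :func:`methdyn.integrate_expression.select_degs` output keyed by
    gene_id.  DMFs without expression for their miRNA get status
    ``not detected``.
    """
    sig = dmfs[dmfs["is_dmf"]].copy() if "is_dmf" in dmfs.columns else dmfs.copy()
    expr = mirna_expr.set_index("mirna_id")["log2fc"]
    rows = []
    tgt_by_mirna = (
        {m: g["gene_id"].tolist() for m, g in targets.groupby("mirna_id")}
        if targets is not None
        else {}
    )
    tstatus = (
        target_expr.set_index("gene_id")["status"] if target_expr is not None else None
    )
    for d in sig.itertuples():
        lfc = expr.get(d.mirna_id)
        if lfc is None or pd.isna(lfc):
            rows.append(
                {
                    "mirna_id": d.mirna_id, "feature": d.feature, "context": d.context,
                    "meth_direction": d.direction, "mirna_direction": None,
                    "anticorr_mirna": None, "gene_id": None,
                    "target_direction": None, "anticorr_target": None,
                    "status": "not detected",
                }
            )
            continue
        mdir = "up" if lfc > 0 else "down"
        anticorr = (d.direction == "hyper" and mdir == "down") or (
            d.direction == "hypo" and mdir == "up"
        )
        gene_list = tgt_by_mirna.get(d.mirna_id, [None])
        for gene in gene_list:
            tdir = None
            tanti = None
            if gene is not None and tstatus is not None:
                st = tstatus.get(gene)
                tdir = st if st in ("up", "down") else None
                if tdir is not None:
                    tanti = (mdir == "down" and tdir == "up") or (
                        mdir == "up" and tdir == "down"
                    )
            rows.append(
                {
                    "mirna_id": d.mirna_id, "feature": d.feature, "context": d.context,
                    "meth_direction": d.direction, "mirna_direction": mdir,
                    "anticorr_mirna": anticorr, "gene_id": gene,
                    "target_direction": tdir, "anticorr_target": tanti,
                    "status": "ok",
                }
            )
    triples = pd.DataFrame(rows)
    anti = triples[triples["anticorr_mirna"] == True]  # noqa: E712 (None-safe)
    summary = {
        "n_dmfs": int(len(sig)),
        "n_anticorr_mirna": int(anti["mirna_id"].nunique()) if len(anti) else 0,
        "anticorr_feature_composition": (
            anti.drop_duplicates(["mirna_id", "feature", "context"])["feature"]
            .value_counts()
            .to_dict()
            if len(anti)
            else {}
        ),
        "n_anticorr_target_chains": int((triples["anticorr_target"] == True).sum()),  # noqa: E712
    }
    return triples, summary
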