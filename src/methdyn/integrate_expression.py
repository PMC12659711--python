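"""Expression classes, DEG selection and DMR-DEG negative-correlation links.

Genes are classed by their mean FPKM under stress: silent (< 0.5), then
low / medium / high by quartiles of the remaining genes' stress FPKM
(boundaries inclusive on the upper end: <= Q2 low, <= Q3 medium, else
high).  Differential expression arrives as an upstream table (mean FPKM per
condition, fold-change, FDR); a DEG needs FPKM >= 0.5 in the larger
condition, FDR <= 0.05 and a two-fold change in either direction.

A DMR-gene link is negatively correlated when methylation and expression
move in opposite directions: hyper DMR with a down DEG, or hypo DMR with an
up DEG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import MethdynError, logger

FPKM_FLOOR = 0.5
DEG_FDR = 0.05
DEG_FC = 2.0


def classify_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Add a ``class`` column: silent / low / medium / high.

    Silent genes (stress FPKM < 0.5) are set aside first; quartiles are
    computed on the remaining genes' stress FPKM with linear-interpolation
    quantiles.  Degenerate quartiles (all equal) put every non-silent gene
    in ``low`` with a warning.
    """
    if (expr["fpkm_stress"] < 0).any() or (expr["fpkm_control"] < 0).any():
        raise MethdynError("negative FPKM values")
    out = expr.copy()
    silent = out["fpkm_stress"] < FPKM_FLOOR
    out["class"] = "silent"
    rest = out.loc[~silent, "fpkm_stress"]
    if len(rest):
        q2, q3 = np.quantile(rest, [0.5, 0.75])
        if q2 == q3 == rest.min():
            logger.warning("classify_expression: degenerate quartiles, all non-silent -> low")
            out.loc[~silent, "class"] = "low"
        else:
            out.loc[~silent, "class"] = np.where(
                rest <= q2, "low", np.where(rest <= q3, "medium", "high")
            )
    return out


def select_degs(expr: pd.DataFrame) -> pd.DataFrame:
    """Differentially expressed genes with direction.

    Needs ``fpkm_control``, ``fpkm_stress``, ``fdr`` and either ``fc`` or
    ``log2fc`` (stress over control).  Returns the DEG subset with a
    ``status`` column in {up, down}; non-DEGs carry status ``ns`` in the
    returned full table's companion — callers usually want just the subset.
    """
    if "fdr" not in expr.columns:
        raise MethdynError("expression table lacks an FDR column")
    out = expr.copy()
    if "fc" in out.columns:
        fc = out["fc"].astype(float)
    elif "log2fc" in out.columns:
        fc = np.power(2.0, out["log2fc"].astype(float))
    else:
        raise MethdynError("expression table lacks fc/log2fc")
    bigger = np.maximum(out["fpkm_control"], out["fpkm_stress"])
    magnitude = np.maximum(fc, 1.0 / np.maximum(fc, 1e-300))
    is_deg = (bigger >= FPKM_FLOOR) & (out["fdr"] <= DEG_FDR) & (magnitude >= DEG_FC)
    out["status"] = np.where(
        ~is_deg, "ns", np.where(out["fpkm_stress"] > out["fpkm_control"], "up", "down")
    )
    return out


def link_dmrs_to_degs(
    annotated_dmrs: pd.DataFrame, expr_with_status: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join annotated DMRs to DEGs and flag negative correlation.

    ``annotated_dmrs`` must carry gene_id, feature, context and direction
    (from :func:`methdyn.annotate.annotate_regions` on a DMR set);
    ``expr_with_status`` is :func:`select_degs` output.  One link per
    (DMR, gene); genes linked to both hyper and hypo DMRs are flagged
    ``mixed``.  Returns the link table and summary tallies.
    """
    degs = expr_with_status[expr_with_status["status"].isin(["up", "down"])]
    links = annotated_dmrs.dropna(subset=["gene_id"]).merge(
        degs[["gene_id", "status"]], on="gene_id", how="inner"
    )
    links = links.copy()
    links["negative_correlation"] = (
        ((links["direction"] == "hyper") & (links["status"] == "down"))
        | ((links["direction"] == "hypo") & (links["status"] == "up"))
    )
    gene_dirs = links.groupby("gene_id")["direction"].nunique()
    links["mixed"] = links["gene_id"].map(gene_dirs > 1)

    neg = links[links["negative_correlation"]]
    summary = {
        "n_links": int(len(links)),
        "n_negative": int(len(neg)),
        "n_negative_genes": int(neg["gene_id"].nunique()),
        "by_context": neg.groupby("context", observed=True)["gene_id"]
        .nunique()
        .to_dict(),
        "by_feature": neg["feature"].value_counts().to_dict()
        if "feature" in neg.columns
        else {},
        "by_pairing": {
            f"{d}/{s}": int(v)
            for (d, s), v in neg.groupby(["direction", "status"], observed=True)["gene_id"]
            .nunique()
            .items()
        },
    }
    return links, summary
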