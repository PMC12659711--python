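"""End-to-end orchestration: contexts -> calls -> consensus -> dynamics ->
DMR/DMF -> annotation -> expression integration -> association statistics.

A run consumes a study directory (as produced by
:func:`methdyn.synthetic.simulate_study`, or real data laid out the same
way), executes the stages in dependency order under one
:class:`RunConfig`, writes every stage's tables under the run directory and
records their SHA-256 hashes in ``MANIFEST.json`` so a rerun with the same
config and inputs is checkably identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._util import CONTEXTS, MethdynError, logger
from . import annotate as annotate_mod
from . import assoc_stats, dmr, genome_io, integrate_expression, mcall, mirna_dmf
from .synthetic import CONDITIONS, CULTIVARS, TISSUES, all_samples, sample_id


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run; defaults are the study's."""

    study_dir: str = "."
    out_dir: str = "run"
    alpha: float = mcall.DEFAULT_ALPHA
    min_depth: int = mcall.DEFAULT_MIN_DEPTH
    error_floor: float = mcall.ERROR_FLOOR
    window_width: int = dmr.DEFAULT_WIDTH
    fisher_p: float = dmr.DEFAULT_FISHER_P
    fdr_q: float = dmr.DEFAULT_FDR_Q
    min_cytosines: int = dmr.DEFAULT_MIN_CYTOSINES
    min_fold: float = dmr.DEFAULT_MIN_FOLD
    epsilon: float = dmr.DEFAULT_EPSILON
    promoter_extent: int = 3000
    downstream_extent: int = 3000
    bootstrap_B: int = 500
    seed: int = 0
    n_replicates: int = 2
    comparison_plan: list = field(default_factory=list)

    def thresholds(self) -> dmr.DmrThresholds:
        return dmr.DmrThresholds(
            self.fisher_p, self.fdr_q, self.min_cytosines,
            self.min_fold, self.epsilon, self.min_depth,
        )


def default_comparison_plan() -> list[dict]:
    plan = []
    for c in CULTIVARS:
        for d in CONDITIONS:
            plan.append(
                {"type": "tissue", "focal": sample_id(c, "panicle", d),
                 "reference": sample_id(c, "flagleaf", d)}
            )
    for t in TISSUES:
        for d in CONDITIONS:
            plan.append(
                {"type": "cultivar", "focal": sample_id("N22", t, d),
                 "reference": sample_id("IR64", t, d)}
            )
    for c in CULTIVARS:
        for t in TISSUES:
            plan.append(
                {"type": "drought", "focal": sample_id(c, t, "drought"),
                 "reference": sample_id(c, t, "control")}
            )
    return plan


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """YAML config merged over defaults; keyword overrides win."""
    data = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise MethdynError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str, outputs: dict, float_format="%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=float_format)
    outputs[os.path.basename(path)] = _sha256(path)


class PipelineRun:
    """Stateful pipeline over one study directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outputs: dict[str, str] = {}
        self.summary: dict = {}

    # -- stages -------------------------------------------------------------

    def load_inputs(self):
        cfg = self.cfg
        sd = cfg.study_dir
        self.genome = genome_io.read_genome(os.path.join(sd, "genome.fa"))
        if not self.genome.chloroplast:
            raise MethdynError("no chloroplast contig recognised in genome.fa")
        self.sites = genome_io.extract_cytosine_sites(self.genome)
        self.genes, self.exons = genome_io.read_gene_models(os.path.join(sd, "genes.gff3"))
        mirna_path = os.path.join(sd, "mirna.gff3")
        self.mirnas = (
            genome_io.read_mirna_loci(mirna_path) if os.path.exists(mirna_path) else None
        )
        self.counts: dict[str, list[pd.DataFrame]] = {}
        for c, t, d in all_samples():
            sid = sample_id(c, t, d)
            reps = []
            for rep in range(1, cfg.n_replicates + 1):
                p = os.path.join(sd, "cx", f"{sid}_rep{rep}.cx.tsv")
                reps.append(genome_io.read_cx_report(p))
            self.counts[sid] = reps

    def stage_calls(self):
        cfg = self.cfg
        self.errors: dict[str, list[mcall.ConversionErrorRate]] = {}
        self.calls: dict[str, list[pd.DataFrame]] = {}
        self.consensus: dict[str, mcall.ConsensusSet] = {}
        for sid, reps in self.counts.items():
            errs, calls = [], []
            for i, rep in enumerate(reps):
                err = mcall.estimate_conversion_error(
                    rep, self.genome.chloroplast, f"{sid}_rep{i + 1}", cfg.error_floor
                )
                errs.append(err)
                calls.append(
                    mcall.call_methylated_sites(rep, err, cfg.alpha, cfg.min_depth)
                )
            self.errors[sid] = errs
            self.calls[sid] = calls
            self.consensus[sid] = mcall.intersect_replicates(calls[0], calls[1], sid)
        self.summary["conversion_error"] = {
            f"{sid}_rep{i + 1}": e.e
            for sid, errs in self.errors.items()
            for i, e in enumerate(errs)
        }
        self.summary["consensus_mC"] = {sid: len(s) for sid, s in self.consensus.items()}

    def stage_dynamics(self):
        self.dynamics: dict[str, pd.DataFrame] = {}
        dyn_summary = {}
        for c in CULTIVARS:
            for t in TISSUES:
                key = f"{c}_{t}"
                dy = mcall.classify_dynamics(
                    self.consensus[sample_id(c, t, "control")],
                    self.consensus[sample_id(c, t, "drought")],
                )
                self.dynamics[key] = dy
                dyn_summary[key] = mcall.dynamics_summary(dy)
        self.summary["dynamics"] = dyn_summary

    def stage_dmrs(self):
        cfg = self.cfg
        plan = cfg.comparison_plan or default_comparison_plan()
        lengths = self.genome.lengths
        self.pooled: dict[str, pd.DataFrame] = {
            sid: dmr.pool_replicates(*reps) for sid, reps in self.counts.items()
        }
        self.dmr_tables: dict[str, pd.DataFrame] = {}
        counts = {}
        for comp in plan:
            name = f"{comp['type']}__{comp['focal']}__vs__{comp['reference']}"
            table = dmr.call_dmrs(
                self.pooled[comp["focal"]],
                self.pooled[comp["reference"]],
                lengths,
                comp["type"],
                cfg.window_width,
                cfg.thresholds(),
            )
            self.dmr_tables[name] = table
            counts[name] = int(table["is_dmr"].sum())
        self.summary["dmr_counts"] = counts

    def stage_annotation(self):
        cfg = self.cfg
        self.index = annotate_mod.GeneFeatureIndex(
            self.genes, self.exons, self.genome.lengths,
            promoter_extent=cfg.promoter_extent,
            downstream_extent=cfg.downstream_extent,
        )
        self.annotated_dmrs: dict[str, pd.DataFrame] = {}
        for name, table in self.dmr_tables.items():
            hits = table[table["is_dmr"]].reset_index(drop=True)
            ann, _dist = annotate_mod.annotate_regions(hits, self.index)
            self.annotated_dmrs[name] = ann

    def stage_integration(self):
        self.links: dict[str, pd.DataFrame] = {}
        link_summary = {}
        for c in CULTIVARS:
            for t in TISSUES:
                name = f"drought__{sample_id(c, t, 'drought')}__vs__{sample_id(c, t, 'control')}"
                if name not in self.annotated_dmrs:
                    continue
                expr_path = os.path.join(self.cfg.study_dir, f"expression_{c}_{t}.tsv")
                if not os.path.exists(expr_path):
                    raise MethdynError(f"integration requested but {expr_path} is missing")
                expr = pd.read_csv(expr_path, sep="\t")
                expr = integrate_expression.classify_expression(expr)
                expr = integrate_expression.select_degs(expr)
                links, summ = integrate_expression.link_dmrs_to_degs(
                    self.annotated_dmrs[name], expr
                )
                self.links[f"{c}_{t}"] = links
                link_summary[f"{c}_{t}"] = summ
        self.summary["dmr_deg_links"] = link_summary

    def stage_dmfs(self):
        if self.mirnas is None or self.mirnas.empty:
            self.dmfs = {}
            return
        feats = mirna_dmf.derive_all_features(self.mirnas, self.genome.lengths)
        self.dmfs: dict[str, pd.DataFrame] = {}
        dmf_counts = {}
        for t in TISSUES:
            focal = self.pooled[sample_id("N22", t, "drought")]
            ref = self.pooled[sample_id("N22", t, "control")]
            tab = mirna_dmf.call_dmfs(feats, focal, ref, self.cfg.thresholds())
            self.dmfs[f"N22_{t}"] = tab
            dmf_counts[f"N22_{t}"] = int(tab["is_dmf"].sum()) if len(tab) else 0
        self.summary["dmf_counts"] = dmf_counts

        sd = self.cfg.study_dir
        me_path = os.path.join(sd, "mirna_expression.tsv")
        tg_path = os.path.join(sd, "mirna_targets.tsv")
        self.mirna_triples = {}
        if os.path.exists(me_path):
            mir_expr = pd.read_csv(me_path, sep="\t")
            targets = pd.read_csv(tg_path, sep="\t") if os.path.exists(tg_path) else None
            expr_path = os.path.join(sd, "expression_N22_panicle.tsv")
            texpr = None
            if os.path.exists(expr_path):
                texpr = integrate_expression.select_degs(
                    integrate_expression.classify_expression(pd.read_csv(expr_path, sep="\t"))
                )
            anti_summary = {}
            for key, tab in self.dmfs.items():
                triples, summ = mirna_dmf.anticorrelate_mirna(tab, mir_expr, targets, texpr)
                self.mirna_triples[key] = triples
                anti_summary[key] = summ
            self.summary["mirna_anticorrelation"] = anti_summary

    def stage_association(self):
        rows = []
        rng_seed = self.cfg.seed
        for name, table in self.dmr_tables.items():
            hits = table[table["is_dmr"]]
            if hits.empty:
                continue
            tab = pd.crosstab(hits["direction"], hits["context"])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                continue
            res = assoc_stats.associate(
                tab.to_numpy(), B=self.cfg.bootstrap_B, seed=rng_seed
            )
            rows.append(
                {
                    "comparison": name, "layout": "direction_x_context",
                    "n": res.n, "chi2": res.chi2, "df": res.df, "p": res.p,
                    "v": res.v, "ci_low": res.ci[0], "ci_high": res.ci[1],
                    "label": res.label,
                }
            )
        self.associations = pd.DataFrame(rows)
        self.summary["associations"] = int(len(self.associations))

    # -- output -------------------------------------------------------------

    def write_outputs(self):
        cfg = self.cfg
        out = cfg.out_dir
        os.makedirs(out, exist_ok=True)
        err_df = pd.DataFrame(
            [
                {"sample": f"{sid}_rep{i + 1}", "e": e.e,
                 "chloroplast_coverage": e.total_chloroplast_coverage,
                 "floored": e.floored}
                for sid, errs in self.errors.items()
                for i, e in enumerate(errs)
            ]
        )
        _write(err_df, os.path.join(out, "conversion_error.tsv"), self.outputs)
        for sid, cons in self.consensus.items():
            df = cons.sites.copy()
            _write(df, os.path.join(out, f"consensus_{sid}.tsv"), self.outputs)
        for key, dy in self.dynamics.items():
            _write(dy, os.path.join(out, f"dynamics_{key}.tsv"), self.outputs)
        for name, table in self.dmr_tables.items():
            hits = table[table["is_dmr"]].copy()
            hits_out = hits.copy()
            hits_out["start"] = hits_out["start"] + 1  # TSV is 1-based inclusive
            _write(hits_out, os.path.join(out, f"dmr_{name}.tsv"), self.outputs)
            if len(hits):
                bed = hits[["chrom", "start", "end"]].copy()
                bed["name"] = (
                    hits["comparison"] + ":" + hits["context"] + ":" + hits["direction"]
                )
                with np.errstate(divide="ignore"):
                    score = -10.0 * np.log10(np.maximum(hits["q"], 1e-100))
                bed["score"] = np.minimum(score, 1000).astype(int)
                bed["strand"] = "."
                genome_io.write_bed(bed, os.path.join(out, f"dmr_{name}.bed"))
                self.outputs[f"dmr_{name}.bed"] = _sha256(
                    os.path.join(out, f"dmr_{name}.bed")
                )
        for key, links in self.links.items():
            _write(links, os.path.join(out, f"links_{key}.tsv"), self.outputs)
        for key, tab in getattr(self, "dmfs", {}).items():
            _write(tab, os.path.join(out, f"dmf_{key}.tsv"), self.outputs)
        for key, tr in getattr(self, "mirna_triples", {}).items():
            _write(tr, os.path.join(out, f"mirna_triples_{key}.tsv"), self.outputs)
        if len(getattr(self, "associations", [])):
            _write(self.associations, os.path.join(out, "associations.tsv"), self.outputs)

        manifest = {
            "config": asdict(self.cfg),
            "outputs": self.outputs,
            "summary": self.summary,
        }
        with open(os.path.join(out, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    def report(self) -> str:
        lines = ["# methdyn run summary", ""]
        for key, val in self.summary.items():
            lines.append(f"## {key}")
            lines.append(json.dumps(val, indent=1, sort_keys=True, default=str))
            lines.append("")
        return "\n".join(lines)


STAGES = [
    ("load_inputs", PipelineRun.load_inputs),
    ("calls", PipelineRun.stage_calls),
    ("dynamics", PipelineRun.stage_dynamics),
    ("dmrs", PipelineRun.stage_dmrs),
    ("annotation", PipelineRun.stage_annotation),
    ("integration", PipelineRun.stage_integration),
    ("dmfs", PipelineRun.stage_dmfs),
    ("association", PipelineRun.stage_association),
]


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute all stages; any failure aborts naming the stage."""
    run = PipelineRun(config)
    for name, fn in STAGES:
        t0 = time.time()
        try:
            fn(run)
        except Exception as exc:
            raise MethdynError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
    run.write_outputs()
    with open(os.path.join(config.out_dir, "report.md"), "w") as fh:
        fh.write(run.report())
    return run
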