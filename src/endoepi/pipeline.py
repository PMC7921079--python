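"""End-to-end orchestration of the two-lineage epigenome comparison.

Reads the flat-file inputs (gene models, per-replicate peak calls,
expression counts, the CpG probe table, promoter/enhancer sequences and
the PWM library), runs consensus peaks → histone-state grading →
differential expression → gain/loss comparison → differential
methylation/DMRs → motif integration, and writes report tables.  Every
table embeds the resolved parameter block and seed in comment lines so a
run is auditable from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import expression as expr
from . import genomic_core as gc
from . import histone_states as hs
from . import integration_motif as im
from . import methylation as meth
from .synthetic_data import FILES, MARKS, peak_filename

log = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(Exception):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, cell-type labels and all stage parameters for one run."""

    data_dir: str
    out_dir: str
    cell_a: str = "BEC"
    cell_b: str = "LEC"
    seed: int = 0
    body_cov_threshold: float = 0.5
    lfc_cut: float = 1.0
    fdr_cut: float = 0.01
    detection_cut: float = 0.01
    probe_sig_q: float = 0.05
    dmr_max_gap: int = 1000
    dmr_min_probes: int = 3
    dmr_fdr: float = 0.05
    dmr_seed_q: float = 0.25
    motif_q: float = 0.05
    score_cut_frac: float = 0.8
    markers: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "data_dir" not in raw or "out_dir" not in raw:
            raise ConfigError("config must set data_dir and out_dir")
        return cls(**raw)

    def validate(self) -> None:
        data = Path(self.data_dir)
        if not data.is_dir():
            raise ConfigError(f"data_dir does not exist: {data}")
        for key in ("genes", "counts", "probes"):
            if not (data / FILES[key]).exists():
                raise ConfigError(f"missing input file: {data / FILES[key]}")
        for name, lo, hi in (
            ("body_cov_threshold", 0, 1),
            ("fdr_cut", 0, 1),
            ("dmr_fdr", 0, 1),
            ("motif_q", 0, 1),
            ("score_cut_frac", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name} must lie in [{lo}, {hi}], got {v}")

    def param_header(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return f"# endoepi run parameters: {payload}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.param_header())
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# stages


def load_inputs(cfg: RunConfig) -> dict:
    data = Path(cfg.data_dir)
    ctx: dict = {"cfg": cfg}
    ctx["genes"] = gc.read_gene_models(data / FILES["genes"], "BED12")
    enh_ivs, enh_names = gc.read_bed(data / FILES["enhancers"])
    ctx["enhancers"] = dict(zip(enh_names, enh_ivs))
    ctx["peaks"] = {}
    for mark in MARKS:
        for cell in (cfg.cell_a, cfg.cell_b):
            for rep in ("rep1", "rep2"):
                path = data / peak_filename(mark, cell, rep)
                if not path.exists():
                    raise ConfigError(f"missing peak file: {path}")
                ctx["peaks"][(mark, cell, rep)] = gc.read_peaks(path, mark, cell, rep)
    ctx["counts"] = pd.read_csv(data / FILES["counts"], sep="\t", index_col="gene_id")
    ctx["probes"] = pd.read_csv(data / FILES["probes"], sep="\t")
    ctx["promoter_seqs"] = _read_fasta(data / FILES["promoter_fasta"])
    ctx["enhancer_seqs"] = _read_fasta(data / FILES["enhancer_fasta"])
    ctx["pwms"] = im.read_jaspar(data / FILES["pwms"])
    m2g = pd.read_csv(data / FILES["motif_to_gene"], sep="\t")
    ctx["motif_to_gene"] = dict(zip(m2g["motif_id"], m2g["gene_id"]))
    log.info(
        "inputs: %d genes, %d enhancers, %d probes, %d PWMs",
        len(ctx["genes"]), len(ctx["enhancers"]), len(ctx["probes"]), len(ctx["pwms"]),
    )
    return ctx


def stage_consensus(ctx: dict) -> None:
    cfg = ctx["cfg"]
    ctx["consensus"] = {}
    for mark in MARKS:
        for cell in (cfg.cell_a, cfg.cell_b):
            cons = hs.consensus_peaks(
                ctx["peaks"][(mark, cell, "rep1")], ctx["peaks"][(mark, cell, "rep2")]
            )
            ctx["consensus"][(mark, cell)] = cons
            log.info("consensus %s/%s: %d peaks", mark, cell, len(cons))


def stage_histone_states(ctx: dict) -> None:
    cfg = ctx["cfg"]
    calls: dict[str, dict[str, hs.HistoneStateCall]] = {}
    rows = []
    for cell in (cfg.cell_a, cfg.cell_b):
        per_cell = {}
        for call in hs.classify_gene_states(
            ctx["genes"],
            ctx["consensus"][("H3K4me3", cell)],
            ctx["consensus"][("H3K27me3", cell)],
            cfg.body_cov_threshold,
        ):
            per_cell[call.gene_id] = call
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "cell_type": cell,
                    "state": call.state.label,
                    "k4_promoter": call.k4_promoter,
                    "k27_promoter": call.k27_promoter,
                    "k27_body_fraction": call.k27_body_fraction,
                    "atypical": call.atypical,
                }
            )
        calls[cell] = per_cell
    ctx["state_calls"] = calls
    ctx["state_table"] = pd.DataFrame(rows)
    log.info("histone states: %d calls", len(rows))


def stage_expression(ctx: dict) -> None:
    cfg = ctx["cfg"]
    lengths = pd.Series({g.gene_id: g.length for g in ctx["genes"]})
    counts = ctx["counts"]
    samples_a = [c for c in counts.columns if c.startswith(f"{cfg.cell_a}_")]
    samples_b = [c for c in counts.columns if c.startswith(f"{cfg.cell_b}_")]
    if not samples_a or not samples_b:
        raise ValueError("count matrix lacks samples for one of the cell types")
    tpm = expr.compute_tpm(counts, lengths)
    de = expr.moderated_de_test(tpm, samples_a, samples_b)
    up_a, up_b = expr.filter_de(de, cfg.lfc_cut, cfg.fdr_cut)
    ctx.update(
        tpm=tpm,
        de_table=de,
        up_a=up_a,
        up_b=up_b,
        samples_a=samples_a,
        samples_b=samples_b,
        replicate_corr=expr.replicate_correlation(tpm),
    )
    log.info("expression: %d up in %s, %d up in %s", len(up_a), cfg.cell_a, len(up_b), cfg.cell_b)


def stage_compare_states(ctx: dict) -> None:
    cfg = ctx["cfg"]
    rows = []
    comparisons = {}
    for gene in ctx["genes"]:
        cmp = hs.compare_states(
            ctx["state_calls"][cfg.cell_a][gene.gene_id],
            ctx["state_calls"][cfg.cell_b][gene.gene_id],
        )
        comparisons[gene.gene_id] = cmp
        rows.append(
            {
                "gene_id": cmp.gene_id,
                "state_a": cmp.state_a.label,
                "state_b": cmp.state_b.label,
                "verdict": cmp.verdict,
                "basis": cmp.basis,
            }
        )
    ctx["comparisons"] = comparisons
    ctx["comparison_table"] = pd.DataFrame(rows)
    ctx["proportions"] = summarize_state_proportions(
        ctx["state_calls"], comparisons, {cfg.cell_a: ctx["up_a"], cfg.cell_b: ctx["up_b"]},
        cfg.cell_a, cfg.cell_b,
    )


def summarize_state_proportions(
    state_calls: Mapping[str, Mapping[str, hs.HistoneStateCall]],
    comparisons: Mapping[str, hs.StateComparison],
    up_sets: Mapping[str, set],
    cell_a: str,
    cell_b: str,
) -> pd.DataFrame:
    """Per-cell-type state and gain/loss fractions over upregulated genes.

    For each cell type, the fraction of its upregulated genes in each
    histone state and under each cross-lineage verdict (from that cell
    type's perspective, so gain/loss are mirrored for cell B).  Fractions
    partition the up-set; an empty up-set yields NA fractions.
    """
    flip = {"gain": "loss", "loss": "gain", "unchanged": "unchanged"}
    rows = []
    for cell, up in up_sets.items():
        n = len(up)
        for state in hs.HistoneState:
            k = sum(1 for g in up if state_calls[cell][g].state == state)
            rows.append(
                {
                    "cell_type": cell,
                    "kind": "state",
                    "label": state.label,
                    "n": k,
                    "fraction": k / n if n else np.nan,
                }
            )
        for verdict in ("gain", "loss", "unchanged"):
            k = sum(
                1
                for g in up
                if (
                    comparisons[g].verdict
                    if cell == cell_a
                    else flip[comparisons[g].verdict]
                )
                == verdict
            )
            rows.append(
                {
                    "cell_type": cell,
                    "kind": "verdict",
                    "label": verdict,
                    "n": k,
                    "fraction": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def stage_methylation(ctx: dict) -> None:
    cfg = ctx["cfg"]
    groups = {s: cfg.cell_a for s in _meth_samples(ctx["probes"], cfg.cell_a)}
    groups.update({s: cfg.cell_b for s in _meth_samples(ctx["probes"], cfg.cell_b)})
    retained = meth.filter_probes(ctx["probes"], cfg.detection_cut)
    diff = meth.differential_probes(retained, groups, cfg.cell_a, cfg.cell_b)
    dmrs = meth.call_dmrs(
        diff, cfg.dmr_max_gap, cfg.dmr_min_probes, cfg.dmr_fdr, cfg.dmr_seed_q
    )
    meth.assign_dmrs(dmrs, ctx["genes"], diff, cfg.probe_sig_q)
    hypo_up_a, hypo_up_b = meth.promoter_hypo_and_up(dmrs, ctx["up_a"], ctx["up_b"])
    ctx.update(
        probes_retained=retained,
        diff_probes=diff,
        dmrs=dmrs,
        hypo_up_a=hypo_up_a,
        hypo_up_b=hypo_up_b,
        genic_summary=meth.genic_region_summary(
            diff, {f"up_{cfg.cell_a}": ctx["up_a"], f"up_{cfg.cell_b}": ctx["up_b"]}
        ),
    )
    log.info(
        "methylation: %d probes retained, %d DMRs, %d/%d hypo+up genes",
        len(retained), len(dmrs), len(hypo_up_a), len(hypo_up_b),
    )


def _meth_samples(probes: pd.DataFrame, cell: str) -> list[str]:
    return [
        c[len("beta_"):]
        for c in probes.columns
        if c.startswith(f"beta_{cell}_")
    ]


def stage_integration(ctx: dict) -> None:
    cfg = ctx["cfg"]
    rng = np.random.default_rng(cfg.seed)
    expressed = set(ctx["tpm"].index[(ctx["tpm"] > 0).any(axis=1)])
    dmr_regions = [d.region for d in ctx["dmrs"]]
    ctx["enrichment"] = {}
    ctx["tf_candidates"] = {}
    for cell, direction, up in (
        (cfg.cell_a, "hypo_a", ctx["up_a"]),
        (cfg.cell_b, "hypo_b", ctx["up_b"]),
    ):
        regions = im.select_enhancer_regions(
            ctx["dmrs"], ctx["consensus"][("H3K27me3", cell)], direction
        )
        fg_enh = {}
        for region in regions:
            for eid, iv in ctx["enhancers"].items():
                if gc.overlap_bp(region, iv) > 0:
                    fg_enh[eid] = ctx["enhancer_seqs"][eid]
                    break
        bg_ids = [
            eid
            for eid, iv in ctx["enhancers"].items()
            if eid not in fg_enh
            and not any(gc.overlap_bp(iv, r) > 0 for r in dmr_regions)
        ]
        n_bg = max(len(fg_enh), 50)  # count-matched background, floor of 50
        if len(bg_ids) > n_bg:
            bg_ids = sorted(rng.choice(bg_ids, size=n_bg, replace=False).tolist())
        bg_enh = {eid: ctx["enhancer_seqs"][eid] for eid in bg_ids}

        fg_prom = {g: ctx["promoter_seqs"][g] for g in sorted(up) if g in ctx["promoter_seqs"]}
        bg_prom = {
            g: ctx["promoter_seqs"][g]
            for g in sorted(expressed - up)
            if g in ctx["promoter_seqs"]
        }
        if not fg_enh or not fg_prom:
            log.warning("integration %s: empty foreground, no candidates", cell)
            ctx["enrichment"][cell] = {"promoters": None, "enhancers": None}
            ctx["tf_candidates"][cell] = []
            continue
        enh_enrich = im.motif_enrichment(fg_enh, bg_enh, ctx["pwms"], cfg.score_cut_frac)
        prom_enrich = im.motif_enrichment(fg_prom, bg_prom, ctx["pwms"], cfg.score_cut_frac)
        ctx["enrichment"][cell] = {"promoters": prom_enrich, "enhancers": enh_enrich}
        ctx["tf_candidates"][cell] = im.select_tf_candidates(
            prom_enrich,
            enh_enrich,
            ctx["state_calls"][cell],
            up,
            ctx["motif_to_gene"],
            cfg.motif_q,
        )
        log.info(
            "integration %s: %d enhancer regions, %d selected TFs",
            cell, len(regions), sum(c.selected for c in ctx["tf_candidates"][cell]),
        )


def marker_summary(ctx: dict, markers: list[str]) -> pd.DataFrame:
    """Epigenetic landscape of a user-supplied marker gene list."""
    cfg = ctx["cfg"]
    known = {g.gene_id for g in ctx["genes"]}
    prom_dmr = {}
    for d in ctx["dmrs"]:
        for g in d.assigned_genes:
            prom_dmr[g] = d.direction
    rows = []
    for gid in markers:
        if gid not in known:
            rows.append({"gene_id": gid, "status": "not_found"})
            continue
        rows.append(
            {
                "gene_id": gid,
                "status": "ok",
                f"state_{cfg.cell_a}": ctx["state_calls"][cfg.cell_a][gid].state.label,
                f"state_{cfg.cell_b}": ctx["state_calls"][cfg.cell_b][gid].state.label,
                "verdict_a_vs_b": ctx["comparisons"][gid].verdict,
                "promoter_dmr": prom_dmr.get(gid, "none"),
                "up_in": (
                    cfg.cell_a
                    if gid in ctx["up_a"]
                    else cfg.cell_b if gid in ctx["up_b"] else "ns"
                ),
            }
        )
    return pd.DataFrame(rows)


def write_report(ctx: dict) -> None:
    cfg = ctx["cfg"]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_table(ctx["state_table"], out / "state_calls.tsv", cfg)
    _write_table(ctx["comparison_table"], out / "state_comparisons.tsv", cfg)
    _write_table(ctx["proportions"], out / "state_proportions.tsv", cfg)
    _write_table(ctx["de_table"], out / "de_table.tsv", cfg)
    _write_table(ctx["replicate_corr"], out / "replicate_correlation.tsv", cfg, index=True)
    _write_table(ctx["diff_probes"], out / "differential_probes.tsv", cfg)
    dmr_rows = [
        {
            "chrom": d.region.chrom,
            "start": d.region.start,
            "end": d.region.end,
            "n_probes": len(d.probe_ids),
            "stouffer_z": d.stouffer_z,
            "stouffer_fdr": d.stouffer_fdr,
            "mean_delta_beta": d.mean_delta_beta,
            "direction": d.direction,
            "enhancer_dmr": d.enhancer_dmr,
            "assigned_genes": ",".join(d.assigned_genes),
        }
        for d in ctx["dmrs"]
    ]
    _write_table(pd.DataFrame(dmr_rows), out / "dmrs.tsv", cfg)
    gc.write_bed([d.region for d in ctx["dmrs"]], out / "dmrs.bed")
    _write_table(ctx["genic_summary"], out / "genic_region_summary.tsv", cfg)
    hypo_rows = [
        {"cell_type": cfg.cell_a, "gene_id": g} for g in sorted(ctx["hypo_up_a"])
    ] + [{"cell_type": cfg.cell_b, "gene_id": g} for g in sorted(ctx["hypo_up_b"])]
    _write_table(pd.DataFrame(hypo_rows), out / "promoter_hypo_up.tsv", cfg)
    for cell, pair in ctx["enrichment"].items():
        for kind, df in pair.items():
            if df is not None:
                _write_table(df, out / f"motif_enrichment_{kind}_{cell}.tsv", cfg)
    tf_rows = []
    for cell, cands in ctx["tf_candidates"].items():
        for c in cands:
            tf_rows.append(
                {
                    "cell_type": cell,
                    "tf_gene": c.tf_name,
                    "enriched_in_promoters": c.enriched_in_promoters,
                    "enriched_in_enhancer_dmrs": c.enriched_in_enhancer_dmrs,
                    "histone_state": c.histone_state.label if c.histone_state else "NA",
                    "upregulated": c.upregulated,
                    "missing_state": c.missing_state,
                    "selected": c.selected,
                }
            )
    _write_table(pd.DataFrame(tf_rows), out / "tf_candidates.tsv", cfg)
    _write_table(marker_summary(ctx, cfg.markers), out / "marker_summary.tsv", cfg)
    for (mark, cell), cons in ctx["consensus"].items():
        gc.write_peaks(cons, out / f"consensus_{mark}_{cell}.bed")


STAGES = (
    ("load_inputs", load_inputs),
    ("consensus_peaks", stage_consensus),
    ("histone_states", stage_histone_states),
    ("expression", stage_expression),
    ("compare_states", stage_compare_states),
    ("methylation", stage_methylation),
    ("integration", stage_integration),
    ("report", write_report),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the in-memory context with every result."""
    cfg.validate()
    ctx: dict = {}
    for name, fn in STAGES:
        try:
            if name == "load_inputs":
                ctx = fn(cfg)
            else:
                fn(ctx)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, exc) from exc
        log.info("stage %s complete", name)
    return ctx
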