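"""Synthetic data generator with a ground-truth manifest.

Emulates the processed forms of a two-lineage endothelial profiling
study: two cell types × two replicates, ChIP-seq peak sets consistent
with planted histone states, negative-binomial RNA-seq counts with
planted differentially expressed genes, Beta-distributed array
methylation with planted >= 3-probe DMRs at promoters and enhancers, and
enhancer/promoter sequences carrying planted motif instances of one
transcription factor per lineage plus decoy motifs.

Every stage draws from its own generator seeded from ``(seed, stage)``,
so stages are individually reproducible and the full dataset is
byte-identical under a fixed :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    merge_intervals,
    promoter_window,
    write_bed,
    write_bed12,
    write_bedgraph,
    write_peaks,
)
from .integration_motif import PWM, write_jaspar

log = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3")
STATE_LABELS = ("repressed", "unmarked", "bivalent", "active")
_RANK = {s: i for i, s in enumerate(STATE_LABELS)}

FILES = {
    "genes": "genes.bed12",
    "enhancers": "enhancers.bed",
    "counts": "counts.tsv",
    "probes": "probes.tsv",
    "promoter_fasta": "promoters.fa",
    "enhancer_fasta": "enhancers.fa",
    "pwms": "motifs.jaspar",
    "motif_to_gene": "motif2tf.tsv",
    "truth": "truth.json",
}


def peak_filename(mark: str, cell: str, rep: str) -> str:
    return f"peaks_{mark}_{cell}_{rep}.narrowPeak"


def signal_filename(mark: str, cell: str) -> str:
    return f"signal_{mark}_{cell}.bedGraph"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the modelled study design where it states one (two
    cell types, two replicate donors per assay, −2 kb/+1 kb promoters,
    1–3 CpG probes per enhancer, planted DE log2FC of 2 and DMR Δβ of
    0.3) and otherwise use scales chosen for stable FDR behaviour at
    seconds-level runtimes: 2,000 genes on one 50-Mb chromosome and
    roughly 20,000 probes.
    """

    seed: int = 0
    cell_a: str = "BEC"
    cell_b: str = "LEC"

    # genome
    n_genes: int = 2000
    chrom: str = "chr1"
    chrom_length: int = 50_000_000
    gene_length: tuple[int, int] = (3000, 15000)
    gene_gap: tuple[int, int] = (6000, 12000)
    frac_minus: float = 0.5
    n_enhancers: int = 300
    enhancer_length: tuple[int, int] = (400, 800)

    # histone states
    state_probs_background: dict = field(
        default_factory=lambda: {
            "repressed": 0.20, "unmarked": 0.30, "bivalent": 0.15, "active": 0.35,
        }
    )
    state_probs_up: dict = field(
        default_factory=lambda: {
            "repressed": 0.05, "unmarked": 0.15, "bivalent": 0.15, "active": 0.65,
        }
    )
    jitter_sd: float = 0.0
    peak_dropout: float = 0.0
    body_cov_range: tuple[float, float] = (0.6, 0.9)
    fe_inside: tuple[float, float] = (5.0, 10.0)
    fe_outside: float = 1.0

    # expression
    n_replicates: int = 2
    de_fraction: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.02
    mean_log_mu: float = math.log(300.0)
    mean_log_sigma: float = 1.0

    # methylation
    promoter_probes: tuple[int, int] = (4, 8)
    body_probes: tuple[int, int] = (1, 3)
    enhancer_probes: tuple[int, int] = (1, 3)
    n_promoter_dmrs: int = 30
    n_discordant_promoter_dmrs: int = 3
    n_enhancer_dmrs: int = 40
    delta_beta: float = 0.3
    beta_noise_sd: float = 0.02
    beta_promoter: float = 0.2
    beta_body: float = 0.7
    beta_enhancer: float = 0.45
    cross_hyb_rate: float = 0.01
    snp_rate: float = 0.01
    detection_fail_rate: float = 0.003

    # motifs
    motif_length: int = 12
    planting_rate: float = 0.7
    motif_mutation_rate: float = 0.1
    n_decoy_pwms: int = 9
    k27_enhancer_fraction: float = 0.15

    def __post_init__(self):
        for name in ("de_fraction", "peak_dropout", "planting_rate", "frac_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])

    @property
    def samples_a(self) -> list[str]:
        return [f"{self.cell_a}_rep{i + 1}" for i in range(self.n_replicates)]

    @property
    def samples_b(self) -> list[str]:
        return [f"{self.cell_b}_rep{i + 1}" for i in range(self.n_replicates)]


@dataclass
class TruthManifest:
    """Planted ground truth: the oracle every recovery test audits."""

    states: dict  # gene -> {cell: state label}
    verdicts: dict  # gene -> gain | loss | unchanged  (cell A vs cell B)
    up_a: list
    up_b: list
    promoter_dmrs: list  # {gene, direction, probe_ids}
    enhancer_dmrs: list  # {enhancer_id, direction, probe_ids, k27_blocked}
    selected_enhancers: dict  # cell label -> [enhancer ids]
    planted_tf: dict  # cell label -> {motif_id, gene_id}
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    manifest: TruthManifest
    genes: list[GeneModel]
    enhancers: dict[str, GenomicInterval]
    peaks: dict[tuple[str, str, str], PeakSet]  # (mark, cell, rep) -> PeakSet
    signals: dict[tuple[str, str], SignalTrack]
    counts: pd.DataFrame
    probes: pd.DataFrame
    promoter_seqs: dict[str, str]
    enhancer_seqs: dict[str, str]
    pwms: list[PWM]
    motif_to_gene: pd.DataFrame

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed12(self.genes, out / FILES["genes"])
        write_bed(
            list(self.enhancers.values()), out / FILES["enhancers"], list(self.enhancers)
        )
        for (mark, cell, rep), ps in self.peaks.items():
            write_peaks(ps, out / peak_filename(mark, cell, rep))
        for (mark, cell), track in self.signals.items():
            write_bedgraph(track, out / signal_filename(mark, cell))
        self.counts.to_csv(out / FILES["counts"], sep="\t", index_label="gene_id")
        self.probes.to_csv(
            out / FILES["probes"], sep="\t", index=False, float_format="%.6g"
        )
        _write_fasta(self.promoter_seqs, out / FILES["promoter_fasta"])
        _write_fasta(self.enhancer_seqs, out / FILES["enhancer_fasta"])
        write_jaspar(self.pwms, out / FILES["pwms"])
        self.motif_to_gene.to_csv(out / FILES["motif_to_gene"], sep="\t", index=False)
        self.manifest.to_json(out / FILES["truth"])
        return out


def _write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig):
    """Non-overlapping stranded genes plus intergenic enhancers."""
    rng = config.rng(1)
    genes: list[GeneModel] = []
    pos = 10_000
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        strand = "-" if rng.random() < config.frac_minus else "+"
        start, end = pos, pos + length
        if end + 2000 > config.chrom_length:
            raise ValueError(
                f"infeasible packing: {config.n_genes} genes exceed chromosome length"
            )
        n_ex = int(rng.integers(2, 7))
        cuts = np.sort(
            rng.choice(np.arange(start + 50, end - 50), size=2 * n_ex - 2, replace=False)
        )
        points = [start, *cuts.tolist(), end]
        exons = [
            GenomicInterval(config.chrom, points[2 * k], points[2 * k + 1], strand)
            for k in range(n_ex)
        ]
        genes.append(
            GeneModel(f"G{i:04d}", GenomicInterval(config.chrom, start, end, strand), exons)
        )
        pos = end + int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))

    margin = 2200  # keep enhancers clear of neighbouring promoter windows
    eligible = []
    for left, right in zip(genes, genes[1:]):
        gap_s = left.interval.end + margin
        gap_e = right.interval.start - margin
        if gap_e - gap_s >= config.enhancer_length[1]:
            eligible.append((gap_s, gap_e))
    if len(eligible) < config.n_enhancers:
        raise ValueError("infeasible packing: not enough intergenic space for enhancers")
    picks = rng.choice(len(eligible), size=config.n_enhancers, replace=False)
    enhancers: dict[str, GenomicInterval] = {}
    for j, gap_idx in enumerate(np.sort(picks)):
        gap_s, gap_e = eligible[gap_idx]
        length = int(rng.integers(config.enhancer_length[0], config.enhancer_length[1] + 1))
        centre = (gap_s + gap_e) // 2
        enhancers[f"enh_{j:04d}"] = GenomicInterval(
            config.chrom, centre - length // 2, centre - length // 2 + length
        )
    return genes, enhancers


# ---------------------------------------------------------------------------
# ground-truth planning


def _sample_states(rng, probs: dict) -> str:
    labels = list(probs)
    return str(rng.choice(labels, p=np.array([probs[l] for l in labels])))


def plan_truth(config: SimulationConfig, genes: list[GeneModel], enhancers: dict):
    """Draw DE truth, per-cell states, DMR plan and planted TFs."""
    rng = config.rng(2)
    gene_ids = [g.gene_id for g in genes]
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes = rng.choice(gene_ids, size=n_de, replace=False)
    up_a = sorted(de_genes[: n_de // 2].tolist())
    up_b = sorted(de_genes[n_de // 2 :].tolist())
    tf_a, tf_b = up_a[0], up_b[0]

    states: dict[str, dict[str, str]] = {}
    for gid in gene_ids:
        if gid in set(up_a):
            sa = _sample_states(rng, config.state_probs_up)
            sb = _sample_states(rng, config.state_probs_background)
        elif gid in set(up_b):
            sa = _sample_states(rng, config.state_probs_background)
            sb = _sample_states(rng, config.state_probs_up)
        else:
            sa = _sample_states(rng, config.state_probs_background)
            sb = _sample_states(rng, config.state_probs_background)
        states[gid] = {config.cell_a: sa, config.cell_b: sb}
    states[tf_a][config.cell_a] = "active"
    states[tf_b][config.cell_b] = "active"

    verdicts = {}
    for gid in gene_ids:
        ra = _RANK[states[gid][config.cell_a]]
        rb = _RANK[states[gid][config.cell_b]]
        verdicts[gid] = "gain" if ra > rb else ("loss" if ra < rb else "unchanged")

    # promoter DMRs: mostly concordant with the up-set, a few discordant
    promoter_dmrs = []
    n_prom = min(config.n_promoter_dmrs, len(up_a) - 1, len(up_b) - 1)
    pool_a = [g for g in up_a if g != tf_a]
    pool_b = [g for g in up_b if g != tf_b]
    for gid in rng.choice(pool_a, size=n_prom, replace=False):
        promoter_dmrs.append({"gene": str(gid), "direction": "hypo_a", "probe_ids": []})
    for gid in rng.choice(pool_b, size=n_prom, replace=False):
        promoter_dmrs.append({"gene": str(gid), "direction": "hypo_b", "probe_ids": []})
    taken = {d["gene"] for d in promoter_dmrs}
    n_disc = min(config.n_discordant_promoter_dmrs, len([g for g in pool_a if g not in taken]))
    if n_disc:
        for gid in rng.choice([g for g in pool_a if g not in taken], size=n_disc, replace=False):
            promoter_dmrs.append({"gene": str(gid), "direction": "hypo_b", "probe_ids": []})

    # enhancer DMRs, a fraction of them blocked by an H3K27me3 peak
    enh_ids = list(enhancers)
    n_enh = min(config.n_enhancer_dmrs, len(enh_ids) // 2)
    picked = rng.choice(enh_ids, size=2 * n_enh, replace=False)
    enhancer_dmrs = []
    for k, enh_id in enumerate(picked):
        direction = "hypo_a" if k < n_enh else "hypo_b"
        blocked = bool(rng.random() < config.k27_enhancer_fraction)
        enhancer_dmrs.append(
            {
                "enhancer_id": str(enh_id),
                "direction": direction,
                "probe_ids": [],
                "k27_blocked": blocked,
            }
        )
    selected = {
        config.cell_a: sorted(
            d["enhancer_id"]
            for d in enhancer_dmrs
            if d["direction"] == "hypo_a" and not d["k27_blocked"]
        ),
        config.cell_b: sorted(
            d["enhancer_id"]
            for d in enhancer_dmrs
            if d["direction"] == "hypo_b" and not d["k27_blocked"]
        ),
    }
    planted_tf = {
        config.cell_a: {"motif_id": "motif_a", "gene_id": tf_a},
        config.cell_b: {"motif_id": "motif_b", "gene_id": tf_b},
    }
    return TruthManifest(
        states=states,
        verdicts=verdicts,
        up_a=up_a,
        up_b=up_b,
        promoter_dmrs=promoter_dmrs,
        enhancer_dmrs=enhancer_dmrs,
        selected_enhancers=selected,
        planted_tf=planted_tf,
        config=dataclasses.asdict(config),
    )


# ---------------------------------------------------------------------------
# ChIP-seq


def simulate_chip(config: SimulationConfig, genes: list[GeneModel], truth: TruthManifest):
    """Peak sets and fold-enrichment tracks consistent with planted states.

    Replicate 1 realises the planted state directly; replicate 2 is
    replicate 1 with Gaussian boundary jitter and per-peak dropout.
    Enhancer DMRs flagged as K27-blocked receive an H3K27me3 peak in the
    hypomethylated cell type.
    """
    rng = config.rng(4)
    enh_blocks = {config.cell_a: [], config.cell_b: []}
    for d in truth.enhancer_dmrs:
        if d["k27_blocked"]:
            cell = config.cell_a if d["direction"] == "hypo_a" else config.cell_b
            enh_blocks[cell].append(d["enhancer_id"])

    peaks: dict[tuple[str, str, str], PeakSet] = {}
    signals: dict[tuple[str, str], SignalTrack] = {}
    for cell in (config.cell_a, config.cell_b):
        rep1: dict[str, list[Peak]] = {m: [] for m in MARKS}
        for gene in genes:
            state = truth.states[gene.gene_id][cell]
            prom = promoter_window(gene)
            score = float(rng.uniform(5, 20))
            if state == "active":
                rep1["H3K4me3"].append(Peak(prom, score))
            elif state == "bivalent":
                rep1["H3K4me3"].append(Peak(prom, score))
                rep1["H3K27me3"].append(Peak(prom, float(rng.uniform(5, 20))))
            elif state == "repressed":
                if rng.random() < 0.5:
                    rep1["H3K27me3"].append(Peak(prom, score))
                else:
                    frac = float(rng.uniform(*config.body_cov_range))
                    plen = int(frac * gene.length)
                    off = int(rng.integers(0, gene.length - plen + 1))
                    body_peak = GenomicInterval(
                        gene.interval.chrom,
                        gene.interval.start + off,
                        gene.interval.start + off + plen,
                    )
                    rep1["H3K27me3"].append(Peak(body_peak, score))
            # unmarked: no peaks
        for mark in MARKS:
            peaks[(mark, cell, "rep1")] = PeakSet(mark, cell, "rep1", list(rep1[mark]))
            rep2 = []
            for p in rep1[mark]:
                if rng.random() < config.peak_dropout:
                    continue
                iv = p.interval
                s = iv.start + int(round(rng.normal(0, config.jitter_sd)))
                e = iv.end + int(round(rng.normal(0, config.jitter_sd)))
                s = max(0, s)
                e = max(e, s + 50)
                rep2.append(Peak(GenomicInterval(iv.chrom, s, e), p.score))
            peaks[(mark, cell, "rep2")] = PeakSet(mark, cell, "rep2", rep2)
            signals[(mark, cell)] = _signal_from_peaks(
                config, rng, peaks[(mark, cell, "rep1")]
            )
    return peaks, signals, enh_blocks


def add_enhancer_k27(
    peaks: dict, config: SimulationConfig, enhancers: dict, enh_blocks: dict
) -> None:
    for cell, enh_ids in enh_blocks.items():
        for rep in ("rep1", "rep2"):
            ps = peaks[("H3K27me3", cell, rep)]
            extra = [Peak(enhancers[eid], 10.0) for eid in enh_ids]
            peaks[("H3K27me3", cell, rep)] = PeakSet(
                "H3K27me3", cell, rep, ps.peaks + extra
            )


def _signal_from_peaks(config, rng, peakset: PeakSet) -> SignalTrack:
    """Fold enrichment 5–10 inside peaks, baseline ~1 between them."""
    merged = merge_intervals([p.interval for p in peakset.peaks])
    bins = []
    prev_end = 0
    for iv in merged:
        if iv.start > prev_end:
            bins.append(
                (GenomicInterval(iv.chrom, prev_end, iv.start), config.fe_outside)
            )
        bins.append((iv, float(rng.uniform(*config.fe_inside))))
        prev_end = iv.end
    return SignalTrack(peakset.mark, peakset.cell_type, bins)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig, genes: list[GeneModel], truth: TruthManifest):
    """Negative-binomial counts with planted fold changes."""
    rng = config.rng(5)
    gene_ids = [g.gene_id for g in genes]
    mu = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, size=len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for cell in (config.cell_a, config.cell_b):
        tf = truth.planted_tf[cell]["gene_id"]
        mu[idx[tf]] = max(mu[idx[tf]], 500.0)
    fc = 2.0 ** config.planted_log2fc
    mean_a, mean_b = mu.copy(), mu.copy()
    up_a, up_b = set(truth.up_a), set(truth.up_b)
    for g, i in idx.items():
        if g in up_a:
            mean_a[i] *= fc
        elif g in up_b:
            mean_b[i] *= fc

    def draw(mean):
        if config.nb_dispersion <= 0:
            return rng.poisson(mean)
        n = 1.0 / config.nb_dispersion
        return rng.negative_binomial(n, n / (n + mean))

    data = {}
    for s in config.samples_a:
        data[s] = draw(mean_a)
    for s in config.samples_b:
        data[s] = draw(mean_b)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# methylation


def _genic_label(pos: int, gene: GeneModel) -> str:
    """Array-manifest-style genic category for a position near one gene."""
    iv, tss, strand = gene.interval, gene.tss, gene.strand
    upstream = (tss - 1 - pos) if strand == "+" else (pos - tss)
    if 0 <= upstream < 200:
        return "TSS200"
    if 200 <= upstream < 1500:
        return "TSS1500"
    if not (iv.start <= pos < iv.end):
        return "intergenic"
    exons = gene.exons or [iv]
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    three_prime = (
        iv.end - 500 <= pos < iv.end if strand == "+" else iv.start <= pos < iv.start + 500
    )
    if three_prime:
        return "3UTR"
    if first.start <= pos < first.end:
        mid = (first.start + first.end) // 2
        head = pos < mid if strand == "+" else pos >= mid
        return "1stExon" if head else "5UTR"
    for ex in exons[1:-1]:
        if abs(pos - ex.start) <= 25 or abs(pos - ex.end) <= 25:
            return "ExonBnd"
    return "Body"


def simulate_methylation(
    config: SimulationConfig,
    genes: list[GeneModel],
    enhancers: dict[str, GenomicInterval],
    truth: TruthManifest,
) -> pd.DataFrame:
    """Probe table with planted DMRs; fills probe ids into the manifest.

    Background β is drawn around region-specific means (hypomethylated
    promoters, methylated gene bodies, intermediate enhancers); a planted
    DMR raises the opposing cell type's mean by Δβ so the focal cell is
    hypomethylated.  Small fractions of non-planted probes carry
    cross-hybridisation/SNP flags or a failed detection p-value to
    exercise the filters.
    """
    rng = config.rng(6)
    prom_plan = {d["gene"]: d for d in truth.promoter_dmrs}
    enh_plan = {d["enhancer_id"]: d for d in truth.enhancer_dmrs}

    rows = []  # (pos, gene_id, region, enhancer_flag, base_beta, shift_a, shift_b, plan)
    for gene in genes:
        prom = promoter_window(gene)
        plan = prom_plan.get(gene.gene_id)
        if plan is not None:
            start = prom.start + 200
            positions = [start + 300 * k for k in range(5)]
            base = config.beta_promoter
        else:
            k = int(rng.integers(config.promoter_probes[0], config.promoter_probes[1] + 1))
            positions = sorted(
                int(x) for x in rng.choice(np.arange(prom.start, prom.end), k, replace=False)
            )
            base = None
        for pos in positions:
            b = base if base is not None else float(
                np.clip(config.beta_promoter + rng.normal(0, 0.05), 0.02, 0.98)
            )
            rows.append([pos, gene.gene_id, _genic_label(pos, gene), False, b, plan])
        kb = int(rng.integers(config.body_probes[0], config.body_probes[1] + 1))
        body_pos = sorted(
            int(x)
            for x in rng.choice(
                np.arange(gene.interval.start + 1500, gene.interval.end), kb, replace=False
            )
        )
        for pos in body_pos:
            b = float(np.clip(config.beta_body + rng.normal(0, 0.05), 0.02, 0.98))
            rows.append([pos, gene.gene_id, _genic_label(pos, gene), False, b, None])

    for enh_id, iv in enhancers.items():
        plan = enh_plan.get(enh_id)
        if plan is not None:
            start = iv.start + 20
            positions = [start + 150 * k for k in range(3)]
            base = config.beta_enhancer
        else:
            k = int(rng.integers(config.enhancer_probes[0], config.enhancer_probes[1] + 1))
            positions = sorted(
                int(x) for x in rng.choice(np.arange(iv.start, iv.end), k, replace=False)
            )
            base = None
        for pos in positions:
            b = base if base is not None else float(
                np.clip(config.beta_enhancer + rng.normal(0, 0.05), 0.02, 0.98)
            )
            rows.append([pos, "", "intergenic", True, b, plan])

    rows.sort(key=lambda r: r[0])
    samples = config.samples_a + config.samples_b
    n = len(rows)
    probe_ids = [f"cg{i:06d}" for i in range(n)]
    rec = {
        "probe_id": probe_ids,
        "chrom": [config.chrom] * n,
        "pos": [r[0] for r in rows],
        "gene_id": [r[1] for r in rows],
        "genic_region": [r[2] for r in rows],
        "enhancer": [r[3] for r in rows],
    }
    planted = np.array([r[5] is not None for r in rows])
    rec["cross_hyb"] = np.where(planted, False, rng.random(n) < config.cross_hyb_rate)
    rec["snp_overlap"] = np.where(planted, False, rng.random(n) < config.snp_rate)

    base = np.array([r[4] for r in rows])
    mean_a, mean_b = base.copy(), base.copy()
    for i, r in enumerate(rows):
        plan = r[5]
        if plan is None:
            continue
        if plan["direction"] == "hypo_a":
            mean_b[i] = base[i] + config.delta_beta
        else:
            mean_a[i] = base[i] + config.delta_beta
        plan["probe_ids"].append(probe_ids[i])
    n_clip = int(np.sum(mean_a > 1.0) + np.sum(mean_b > 1.0))
    if n_clip:
        log.warning("clipped %d planted probe means into [0, 1]", n_clip)
    mean_a, mean_b = np.clip(mean_a, 0.001, 0.999), np.clip(mean_b, 0.001, 0.999)

    fail = (~planted) & (rng.random(n) < config.detection_fail_rate)
    fail_sample = rng.integers(0, len(samples), size=n)
    for si, s in enumerate(samples):
        mean = mean_a if s in config.samples_a else mean_b
        beta = np.clip(mean + rng.normal(0, config.beta_noise_sd, size=n), 0.001, 0.999)
        det = rng.uniform(0, 0.005, size=n)
        det = np.where(fail & (fail_sample == si), rng.uniform(0.02, 0.2, size=n), det)
        rec[f"det_{s}"] = det
        rec[f"beta_{s}"] = beta
    return pd.DataFrame(rec)


# ---------------------------------------------------------------------------
# sequences and motifs


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _consensus_pwm(rng, motif_id: str, tf_name: str, length: int) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), 0.05)
    mat[np.arange(length), consensus] = 0.85
    return PWM(motif_id, tf_name, mat)


def _plant(rng, seq: str, pwm: PWM, mutation_rate: float) -> str:
    m = len(pwm)
    if len(seq) < m:
        log.warning("region shorter than motif; skipped planting")
        return seq
    inst = list(pwm.consensus)
    for i in range(m):
        if rng.random() < mutation_rate:
            inst[i] = "ACGT"[int(rng.integers(0, 4))]
    off = int(rng.integers(0, len(seq) - m + 1))
    return seq[:off] + "".join(inst) + seq[off + m :]


def simulate_sequences_and_pwms(
    config: SimulationConfig,
    genes: list[GeneModel],
    enhancers: dict[str, GenomicInterval],
    truth: TruthManifest,
):
    """Random sequences with planted motif instances, plus the PWM library.

    One informative PWM per lineage is planted (with per-base mutations)
    into that lineage's truth-selected enhancer DMRs and upregulated-gene
    promoters at the configured rate; decoy PWMs are equally informative
    but planted nowhere.  The motif→TF table maps each decoy to a
    non-differential gene.
    """
    rng = config.rng(7)
    promoter_seqs = {
        g.gene_id: _random_seq(rng, promoter_window(g).length) for g in genes
    }
    enhancer_seqs = {eid: _random_seq(rng, iv.length) for eid, iv in enhancers.items()}

    pwm_a = _consensus_pwm(
        rng, "motif_a", truth.planted_tf[config.cell_a]["gene_id"], config.motif_length
    )
    pwm_b = _consensus_pwm(
        rng, "motif_b", truth.planted_tf[config.cell_b]["gene_id"], config.motif_length
    )
    de = set(truth.up_a) | set(truth.up_b)
    non_de = [g.gene_id for g in genes if g.gene_id not in de]
    decoys = [
        _consensus_pwm(rng, f"decoy_{k:02d}", str(gid), config.motif_length)
        for k, gid in enumerate(
            rng.choice(non_de, size=config.n_decoy_pwms, replace=False)
        )
    ]
    pwms = [pwm_a, pwm_b] + decoys

    for cell, pwm in ((config.cell_a, pwm_a), (config.cell_b, pwm_b)):
        for enh_id in truth.selected_enhancers[cell]:
            if rng.random() < config.planting_rate:
                enhancer_seqs[enh_id] = _plant(
                    rng, enhancer_seqs[enh_id], pwm, config.motif_mutation_rate
                )
        up = truth.up_a if cell == config.cell_a else truth.up_b
        for gid in up:
            if rng.random() < config.planting_rate:
                promoter_seqs[gid] = _plant(
                    rng, promoter_seqs[gid], pwm, config.motif_mutation_rate
                )

    motif_to_gene = pd.DataFrame(
        {"motif_id": [p.motif_id for p in pwms], "gene_id": [p.tf_name for p in pwms]}
    )
    return promoter_seqs, enhancer_seqs, pwms, motif_to_gene


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset plus its ground-truth manifest."""
    genes, enhancers = simulate_genome(config)
    truth = plan_truth(config, genes, enhancers)
    peaks, signals, enh_blocks = simulate_chip(config, genes, truth)
    add_enhancer_k27(peaks, config, enhancers, enh_blocks)
    counts = simulate_expression(config, genes, truth)
    probes = simulate_methylation(config, genes, enhancers, truth)
    prom_seqs, enh_seqs, pwms, motif_to_gene = simulate_sequences_and_pwms(
        config, genes, enhancers, truth
    )
    return SyntheticDataset(
        config=config,
        manifest=truth,
        genes=genes,
        enhancers=enhancers,
        peaks=peaks,
        signals=signals,
        counts=counts,
        probes=probes,
        promoter_seqs=prom_seqs,
        enhancer_seqs=enh_seqs,
        pwms=pwms,
        motif_to_gene=motif_to_gene,
    )
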