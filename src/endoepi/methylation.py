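"""Simplified Infinium-EPIC-style differential methylation stage.

Probe-level records live in a pandas DataFrame with one row per CpG probe
and columns::

    probe_id  chrom  pos  gene_id  genic_region  enhancer  cross_hyb
    snp_overlap  det_<sample>...  beta_<sample>...

β-values (methylated / (methylated + unmethylated)) are used for
description; M-values, M = log2(β / (1 − β)), for testing.  Probes are
filtered on detection p-values and cross-hybridisation/SNP flags, tested
per probe with a variance-moderated t statistic, and aggregated into
differentially methylated regions (DMRs) of at least three CpGs whose
Stouffer-combined FDR falls below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_core import GeneModel, GenomicInterval, overlap_bp, promoter_window
from .stats import bh_adjust, stouffer_z, z_from_p

log = logging.getLogger(__name__)

GENIC_REGIONS = (
    "TSS1500",
    "TSS200",
    "5UTR",
    "1stExon",
    "Body",
    "ExonBnd",
    "3UTR",
    "intergenic",
)

BETA_EPS = 1e-6


@dataclass
class DMR:
    """A differentially methylated region of >= 3 consecutive CpG probes."""

    region: GenomicInterval
    probe_ids: list[str]
    stouffer_z: float
    stouffer_fdr: float
    mean_delta_beta: float
    assigned_genes: list[str] = field(default_factory=list)
    enhancer_dmr: bool = False

    def __post_init__(self):
        if len(self.probe_ids) < 3:
            raise ValueError("a DMR requires at least 3 probes")

    @property
    def direction(self) -> str:
        # delta_beta is mean(A) - mean(B): negative means lower in A
        return "hypo_a" if self.mean_delta_beta < 0 else "hypo_b"


def beta_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c.startswith("beta_")]


def detection_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c.startswith("det_")]


def filter_probes(probes: pd.DataFrame, detection_cut: float = 0.01) -> pd.DataFrame:
    """Retain probes detected in all samples and free of technical flags.

    A probe is kept when its detection p-value is below ``detection_cut``
    in every sample and it is neither cross-hybridising nor overlapping a
    common SNP.  Retention is logged.
    """
    det = probes[detection_columns(probes)]
    ok = (det < detection_cut).all(axis=1)
    ok &= ~probes["cross_hyb"].astype(bool)
    ok &= ~probes["snp_overlap"].astype(bool)
    kept = probes.loc[ok].reset_index(drop=True)
    log.info("probe filter: retained %d of %d probes", len(kept), len(probes))
    return kept


def beta_to_m(beta) -> np.ndarray:
    """M = log2(β / (1 − β)); β is clamped to [1e-6, 1 − 1e-6] first."""
    b = np.clip(np.asarray(beta, dtype=float), BETA_EPS, 1.0 - BETA_EPS)
    return np.log2(b / (1.0 - b))


def differential_probes(
    probes: pd.DataFrame,
    groups: Mapping[str, str],
    cell_a: str,
    cell_b: str,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-probe moderated t-test on M-values (cell A minus cell B).

    Per-probe pooled variances are shrunk toward the run-wide mean
    variance with a fixed prior weight (``prior_df``), keeping the test
    stable at two replicates per group; p-values are two-sided with the
    moderated degrees of freedom, q-values BH-adjusted across all probes.
    ``groups`` maps sample name (the suffix of ``beta_<sample>``) to cell
    type.  The returned frame adds mean_beta_a/b, delta_beta, delta_m, p,
    q and the signed z used downstream by the DMR caller.
    """
    samples_a = [s for s, c in groups.items() if c == cell_a]
    samples_b = [s for s, c in groups.items() if c == cell_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least two samples per group")
    beta_a = probes[[f"beta_{s}" for s in samples_a]].to_numpy(dtype=float)
    beta_b = probes[[f"beta_{s}" for s in samples_b]].to_numpy(dtype=float)
    m_a, m_b = beta_to_m(beta_a), beta_to_m(beta_b)
    na, nb = m_a.shape[1], m_b.shape[1]
    mean_a, mean_b = m_a.mean(axis=1), m_b.mean(axis=1)
    var_a, var_b = m_a.var(axis=1, ddof=1), m_b.var(axis=1, ddof=1)
    df_resid = na + nb - 2
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid
    s2_prior = float(np.nanmean(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    df_mod = prior_df + df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(np.abs(t), df=df_mod)
    p = np.where(np.isfinite(t), p, np.nan)  # zero variance everywhere -> NA

    out = probes[
        ["probe_id", "chrom", "pos", "gene_id", "genic_region", "enhancer"]
    ].copy()
    out["mean_beta_a"] = beta_a.mean(axis=1)
    out["mean_beta_b"] = beta_b.mean(axis=1)
    out["delta_beta"] = out["mean_beta_a"] - out["mean_beta_b"]
    out["delta_m"] = mean_a - mean_b
    out["t"] = t
    out["p"] = p
    out["q"] = bh_adjust(p)
    out["z"] = z_from_p(p, out["delta_beta"].to_numpy())
    return out


def call_dmrs(
    diff: pd.DataFrame,
    max_gap: int = 1000,
    min_probes: int = 3,
    fdr_cut: float = 0.05,
    seed_q: float = 0.25,
) -> list[DMR]:
    """Call DMRs from the per-probe differential table.

    Candidate regions are maximal runs of probes with q below ``seed_q``
    whose consecutive genomic gaps stay within ``max_gap`` and whose
    signed z-scores agree in sign.  Each candidate is scored by the
    unweighted Stouffer statistic sum(z)/sqrt(k); candidate-level p-values
    are BH-adjusted and regions with at least ``min_probes`` probes and
    Stouffer FDR below ``fdr_cut`` are returned.
    """
    pos = diff["pos"].to_numpy()
    chroms = diff["chrom"].to_numpy()
    order_ok = all(
        (chroms[i] < chroms[i + 1])
        or (chroms[i] == chroms[i + 1] and pos[i] <= pos[i + 1])
        for i in range(len(diff) - 1)
    )
    if not order_ok:
        raise ValueError("differential table must be sorted by (chrom, pos)")

    candidates: list[pd.DataFrame] = []
    run: list[int] = []
    for i in range(len(diff)):
        row_q, row_z = diff["q"].iat[i], diff["z"].iat[i]
        seeded = np.isfinite(row_q) and row_q < seed_q
        if not seeded:
            if run:
                candidates.append(diff.iloc[run])
            run = []
            continue
        if run:
            j = run[-1]
            same_chrom = chroms[i] == chroms[j]
            close = same_chrom and (pos[i] - pos[j]) <= max_gap
            same_sign = np.sign(row_z) == np.sign(diff["z"].iat[j])
            if not (close and same_sign):
                candidates.append(diff.iloc[run])
                run = []
        run.append(i)
    if run:
        candidates.append(diff.iloc[run])

    if not candidates:
        return []
    zs = np.array([stouffer_z(c["z"].to_numpy()) for c in candidates])
    region_p = 2.0 * sps.norm.sf(np.abs(zs))
    region_fdr = bh_adjust(region_p)

    dmrs = []
    for cand, z, fdr in zip(candidates, zs, region_fdr):
        if len(cand) < min_probes or not (fdr < fdr_cut):
            continue
        chrom = cand["chrom"].iat[0]
        dmrs.append(
            DMR(
                region=GenomicInterval(chrom, int(cand["pos"].min()), int(cand["pos"].max()) + 1),
                probe_ids=list(cand["probe_id"]),
                stouffer_z=float(z),
                stouffer_fdr=float(fdr),
                mean_delta_beta=float(cand["delta_beta"].mean()),
            )
        )
    log.info("DMR caller: %d candidates, %d DMRs", len(candidates), len(dmrs))
    return dmrs


def assign_dmrs(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    diff: pd.DataFrame,
    sig_q: float = 0.05,
    upstream: int = 2000,
    downstream: int = 1000,
) -> list[DMR]:
    """Annotate DMRs with promoter genes and the enhancer-DMR flag.

    A DMR is assigned to every gene whose −2 kb/+1 kb promoter window
    overlaps it by >= 1 bp.  It is an enhancer DMR when at least one
    member probe targets an enhancer and is individually significant
    (q < ``sig_q``).  Mutates and returns the input DMRs.
    """
    promoters = [(g, promoter_window(g, upstream, downstream)) for g in genes]
    probe_info = diff.set_index("probe_id")
    for dmr in dmrs:
        dmr.assigned_genes = [
            g.gene_id for g, prom in promoters if overlap_bp(prom, dmr.region) > 0
        ]
        member = probe_info.loc[dmr.probe_ids]
        dmr.enhancer_dmr = bool(
            (member["enhancer"].astype(bool) & (member["q"] < sig_q)).any()
        )
    return list(dmrs)


def genic_region_summary(
    diff: pd.DataFrame,
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-gene-set, per-genic-region β summaries for both cell types.

    Returns a tidy frame (gene_set, genic_region, cell_type, n_probes,
    mean_beta, median_beta) over the seven genic categories plus
    intergenic; probe counts per gene set are conserved across categories.
    """
    unknown = set(diff["genic_region"]) - set(GENIC_REGIONS)
    if unknown:
        raise ValueError(f"unknown genic region labels: {sorted(unknown)}")
    rows = []
    for set_name, gene_ids in gene_sets.items():
        sub = diff[diff["gene_id"].isin(gene_ids)]
        for region in GENIC_REGIONS:
            reg = sub[sub["genic_region"] == region]
            for cell, col in (("a", "mean_beta_a"), ("b", "mean_beta_b")):
                vals = reg[col].to_numpy(dtype=float)
                rows.append(
                    {
                        "gene_set": set_name,
                        "genic_region": region,
                        "cell_type": cell,
                        "n_probes": len(vals),
                        "mean_beta": float(vals.mean()) if len(vals) else np.nan,
                        "median_beta": float(np.median(vals)) if len(vals) else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def promoter_hypo_and_up(
    dmrs: Sequence[DMR], up_a: set[str], up_b: set[str]
) -> tuple[set[str], set[str]]:
    """Genes both upregulated and promoter-hypomethylated, per cell type.

    Intersects the genes assigned to promoter-overlapping DMRs
    hypomethylated in each cell type with that cell type's upregulated
    set (directions share the A-minus-B convention).
    """
    hypo_a_genes = {g for d in dmrs if d.direction == "hypo_a" for g in d.assigned_genes}
    hypo_b_genes = {g for d in dmrs if d.direction == "hypo_b" for g in d.assigned_genes}
    return hypo_a_genes & up_a, hypo_b_genes & up_b
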