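"""Four-level histone-state grading and cross-lineage gain/loss calls.

Each gene is graded per cell type from its consensus H3K4me3 and H3K27me3
peaks into one of four states of increasing transcriptional activity:

    repressed (0) < unmarked (1) < bivalent (2) < active (3)

* ``repressed`` — H3K27me3 covers the gene body (union coverage at or
  above a configurable threshold, default 0.5) or spans the promoter in
  the absence of H3K4me3;
* ``unmarked`` — neither mark touches the promoter or the transcript;
* ``bivalent`` — both marks reside in the promoter;
* ``active`` — the promoter is solely enriched for H3K4me3.

Between two cell types, a higher-ranked state is a gain of transcriptional
activity; equal-rank genes may still gain/lose through significantly
stronger H3K4me3 or weaker H3K27me3 enrichment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genomic_core import GeneModel, Peak, PeakSet, promoter_window
from .stats import bh_adjust


class HistoneState(enum.IntEnum):
    """Histone states ordered by transcriptional activity (the rank)."""

    REPRESSED = 0
    UNMARKED = 1
    BIVALENT = 2
    ACTIVE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def rank(self) -> int:
        return int(self)

    @classmethod
    def from_label(cls, label: str) -> "HistoneState":
        return cls[label.upper()]


@dataclass
class HistoneStateCall:
    gene_id: str
    cell_type: str
    state: HistoneState
    k4_promoter: bool
    k27_promoter: bool
    k27_body_fraction: float
    atypical: bool = False


@dataclass
class DifferentialEnrichment:
    """Simplified differential ChIP enrichment for one gene window."""

    gene_id: str
    mark: str
    log2_fold_change: float
    p_value: float
    q_value: float = np.nan

    @property
    def significant(self) -> bool:
        return abs(self.log2_fold_change) > 1.0 and self.q_value < 0.05


@dataclass
class StateComparison:
    gene_id: str
    state_a: HistoneState
    state_b: HistoneState
    verdict: str  # gain | loss | unchanged  (A relative to B)
    basis: str  # state_switch | same_state_signal | none


def consensus_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Peaks identified in both biological replicates.

    Returns the replicate-1 peaks that overlap (>= 1 bp) any replicate-2
    peak, keeping replicate-1 coordinates; reciprocity is not required.
    """
    if rep1.mark != rep2.mark or rep1.cell_type != rep2.cell_type:
        raise ValueError(
            f"replicates disagree: {rep1.mark}/{rep1.cell_type} vs {rep2.mark}/{rep2.cell_type}"
        )
    kept = [p for p in rep1.peaks if rep2.any_overlap(p.interval)]
    return PeakSet(rep1.mark, rep1.cell_type, "consensus", kept)


def state_from_flags(
    k4_promoter: bool,
    k27_promoter: bool,
    k27_body_high: bool,
    any_mark: bool,
) -> tuple[HistoneState, bool]:
    """Total, deterministic rule table behind the classifier.

    Rules are evaluated in order: bivalent, active, repressed, unmarked;
    gene-body repression overrides an otherwise active promoter.  Any
    residual configuration (e.g. a mark in the body only, below the
    repression threshold) maps to unmarked with the atypical flag set.
    """
    if k4_promoter and k27_promoter:
        return HistoneState.BIVALENT, False
    if k4_promoter and not k27_promoter and not k27_body_high:
        return HistoneState.ACTIVE, False
    if (k27_promoter and not k4_promoter) or k27_body_high:
        return HistoneState.REPRESSED, False
    if not any_mark:
        return HistoneState.UNMARKED, False
    return HistoneState.UNMARKED, True


def classify_gene_state(
    gene: GeneModel,
    k4: PeakSet,
    k27: PeakSet,
    body_cov_threshold: float = 0.5,
    upstream: int = 2000,
    downstream: int = 1000,
) -> HistoneStateCall:
    """Grade one gene into a histone state for one cell type.

    ``k4`` and ``k27`` must be consensus peak sets of the same cell type;
    the promoter is the strand-aware −2 kb/+1 kb TSS window and the gene
    body is the full transcript interval.
    """
    if k4.cell_type != k27.cell_type:
        raise ValueError("peak sets come from different cell types")
    promoter = promoter_window(gene, upstream, downstream)
    body = gene.interval
    k4_prom = k4.any_overlap(promoter)
    k27_prom = k27.any_overlap(promoter)
    body_frac = k27.coverage(body)
    any_mark = (
        k4_prom
        or k27_prom
        or body_frac > 0
        or k4.any_overlap(body)
    )
    state, atypical = state_from_flags(
        k4_prom, k27_prom, body_frac >= body_cov_threshold, any_mark
    )
    return HistoneStateCall(
        gene.gene_id, k4.cell_type, state, k4_prom, k27_prom, body_frac, atypical
    )


def classify_gene_states(
    genes: Sequence[GeneModel],
    k4: PeakSet,
    k27: PeakSet,
    body_cov_threshold: float = 0.5,
) -> list[HistoneStateCall]:
    return [classify_gene_state(g, k4, k27, body_cov_threshold) for g in genes]


def differential_enrichment(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    lib_sizes_a: Sequence[float],
    lib_sizes_b: Sequence[float],
) -> tuple[float, float]:
    """Pooled log2 fold change and Fisher p for one window (A over B).

    Replicates are pooled; rates are per million mapped reads with a
    pseudocount of 0.5 reads scaled to the smaller library.  The p-value
    comes from a two-sided Fisher exact test of in-window vs out-of-window
    pooled counts.  This is a deliberately simple surrogate for a
    dispersion-modelling differential-binding test, which two replicates
    per group cannot support.
    """
    ca, cb = float(np.sum(counts_a)), float(np.sum(counts_b))
    la, lb = float(np.sum(lib_sizes_a)), float(np.sum(lib_sizes_b))
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")
    pc = 0.5 / (min(la, lb) / 1e6)
    rate_a = ca / la * 1e6
    rate_b = cb / lb * 1e6
    log2fc = float(np.log2((rate_a + pc) / (rate_b + pc)))
    table = [[int(round(ca)), int(round(la - ca))], [int(round(cb)), int(round(lb - cb))]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return log2fc, p


def differential_enrichment_run(
    windows: Iterable[tuple[str, str, Sequence[float], Sequence[float], Sequence[float], Sequence[float]]],
) -> list[DifferentialEnrichment]:
    """Apply :func:`differential_enrichment` to many windows and BH-adjust.

    ``windows`` yields (gene_id, mark, counts_a, counts_b, libs_a, libs_b);
    q-values are adjusted over all windows tested in the run.
    """
    results = []
    for gene_id, mark, ca, cb, la, lb in windows:
        lfc, p = differential_enrichment(ca, cb, la, lb)
        results.append(DifferentialEnrichment(gene_id, mark, lfc, p))
    q = bh_adjust([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def compare_states(
    call_a: HistoneStateCall,
    call_b: HistoneStateCall,
    k4_diff: DifferentialEnrichment | None = None,
    k27_diff: DifferentialEnrichment | None = None,
) -> StateComparison:
    """Gain/loss verdict for one gene, cell type A relative to B.

    A higher-ranked state in A is a gain (basis ``state_switch``); equal
    ranks fall back to significant mark differences (stronger H3K4me3 or
    weaker H3K27me3 in A is a gain, the mirror a loss; conflicting or no
    significant signal leaves the gene unchanged).
    """
    if call_a.gene_id != call_b.gene_id:
        raise ValueError(f"gene ids differ: {call_a.gene_id} vs {call_b.gene_id}")
    ra, rb = call_a.state.rank, call_b.state.rank
    if ra > rb:
        return StateComparison(call_a.gene_id, call_a.state, call_b.state, "gain", "state_switch")
    if ra < rb:
        return StateComparison(call_a.gene_id, call_a.state, call_b.state, "loss", "state_switch")
    gain_sig = (
        k4_diff is not None and k4_diff.significant and k4_diff.log2_fold_change > 0
    ) or (k27_diff is not None and k27_diff.significant and k27_diff.log2_fold_change < 0)
    loss_sig = (
        k4_diff is not None and k4_diff.significant and k4_diff.log2_fold_change < 0
    ) or (k27_diff is not None and k27_diff.significant and k27_diff.log2_fold_change > 0)
    if gain_sig and not loss_sig:
        return StateComparison(call_a.gene_id, call_a.state, call_b.state, "gain", "same_state_signal")
    if loss_sig and not gain_sig:
        return StateComparison(call_a.gene_id, call_a.state, call_b.state, "loss", "same_state_signal")
    basis = "same_state_signal" if (gain_sig and loss_sig) else "none"
    return StateComparison(call_a.gene_id, call_a.state, call_b.state, "unchanged", basis)


def state_expression_summary(
    calls: Sequence[HistoneStateCall],
    expression: Mapping[str, float],
    expressed_only: bool = True,
) -> dict[str, dict]:
    """Per-state gene counts and median expression.

    With ``expressed_only`` (the default) genes with TPM == 0 are dropped
    first, mirroring analyses restricted to expressed genes (TPM > 0).
    Returns ``{state_label: {"n": int, "median_tpm": float | nan}}``.
    """
    groups: dict[str, list[float]] = {s.label: [] for s in HistoneState}
    for call in calls:
        if call.gene_id not in expression:
            raise KeyError(f"no expression value for gene {call.gene_id}")
        tpm = expression[call.gene_id]
        if expressed_only and tpm <= 0:
            continue
        groups[call.state.label].append(tpm)
    return {
        label: {
            "n": len(vals),
            "median_tpm": float(np.median(vals)) if vals else float("nan"),
        }
        for label, vals in groups.items()
    }
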