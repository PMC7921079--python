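"""Motif-based transcription-factor selection.

The meta-analysis step: take hypomethylated enhancer DMRs devoid of
H3K27me3 and promoters of upregulated genes, scan both against a library
of position weight matrices, test ZOOPS (zero-or-one occurrence per
sequence) enrichment against background sequence sets with a
hypergeometric tail, and keep transcription factors that are enriched in
both scans, sit in an 'active' histone state, and are themselves
upregulated in the focal cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_core import GenomicInterval, PeakSet
from .histone_states import HistoneState, HistoneStateCall
from .methylation import DMR
from .stats import bh_adjust

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PROB_FLOOR = 1e-3


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    background: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must span at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, _PROB_FLOOR)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass
class TFCandidate:
    tf_name: str
    enriched_in_promoters: bool
    enriched_in_enhancer_dmrs: bool
    histone_state: HistoneState | None
    upregulated: bool
    missing_state: bool = False

    @property
    def selected(self) -> bool:
        return (
            self.enriched_in_promoters
            and self.enriched_in_enhancer_dmrs
            and self.histone_state == HistoneState.ACTIVE
            and self.upregulated
        )


# ---------------------------------------------------------------------------
# PWM file formats


def read_jaspar(path) -> list[PWM]:
    """JASPAR-style PFM text: '>id name' header plus four base rows."""
    pwms, header, rows = [], None, []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for line in lines + [">__end__"]:
        if line.startswith(">"):
            if header is not None:
                pwms.append(_pfm_to_pwm(header, rows))
            parts = line[1:].split()
            header, rows = (parts[0], parts[1] if len(parts) > 1 else parts[0]), []
        else:
            rows.append(line)
    return pwms


def _pfm_to_pwm(header: tuple[str, str], rows: list[str]) -> PWM:
    if len(rows) != 4:
        raise ValueError(f"motif {header[0]}: expected 4 base rows, got {len(rows)}")
    counts = []
    for row in rows:
        body = row
        if body[:1].upper() in _BASE_INDEX:
            body = body[1:]
        body = body.replace("[", " ").replace("]", " ")
        counts.append([float(x) for x in body.split()])
    mat = np.asarray(counts, dtype=float).T  # rows were per-base
    probs = mat / mat.sum(axis=1, keepdims=True)
    return PWM(header[0], header[1], probs)


def read_meme(path) -> list[PWM]:
    """MEME minimal format reader (letter-probability matrices only)."""
    pwms = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            tf_name = parts[2] if len(parts) > 2 else motif_id
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            i += 1
            rows = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                vals = lines[i].split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                    i += 1
                else:
                    break
            pwms.append(PWM(motif_id, tf_name, np.asarray(rows)))
        else:
            i += 1
    return pwms


def write_jaspar(pwms: Sequence[PWM], path, pseudo_total: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            counts = np.round(pwm.matrix * pseudo_total).astype(int)
            for b, base in enumerate("ACGT"):
                row = " ".join(str(x) for x in counts[:, b])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# scanning and enrichment


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper()
        .translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04"))
        .encode("latin-1"),
        dtype=np.uint8,
    ).astype(np.int64)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; NaN where a window contains N."""
    m = log_odds.shape[0]
    n_win = codes.size - m + 1
    if n_win <= 0:
        return np.empty(0)
    safe = np.where(codes > 3, 0, codes)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(m):
        col = codes[j : j + n_win]
        scores += log_odds[j, safe[j : j + n_win]]
        bad |= col > 3
    scores[bad] = np.nan
    return scores


def scan_pwm(seq: str, pwm: PWM, score_cut: float | None = None) -> list[tuple[int, str, float]]:
    """Scan a sequence on both strands for PWM matches.

    Scores are log2-odds against the background at every offset; windows
    containing N are skipped.  The default cutoff is 0.8 × the maximal
    attainable score.  Hits are (forward-strand offset, strand, score).
    """
    if any(c not in "ACGTNacgtn" for c in seq):
        raise ValueError("sequence must be over {A, C, G, T, N}")
    if score_cut is None:
        score_cut = 0.8 * pwm.max_score
    m = len(pwm)
    if len(seq) < m:
        return []
    lo = pwm.log_odds
    hits = []
    fwd = _window_scores(_encode(seq), lo)
    for i in np.flatnonzero(fwd >= score_cut):
        hits.append((int(i), "+", float(fwd[i])))
    rev = _window_scores(_encode(seq.translate(_COMPLEMENT)[::-1]), lo)
    for i in np.flatnonzero(rev >= score_cut):
        hits.append((len(seq) - m - int(i), "-", float(rev[i])))
    return sorted(hits)


def _has_hit(codes: np.ndarray, codes_rc: np.ndarray, lo: np.ndarray, cut: float) -> bool:
    with np.errstate(invalid="ignore"):
        fwd = _window_scores(codes, lo)
        if fwd.size and np.nanmax(fwd) >= cut:
            return True
        rev = _window_scores(codes_rc, lo)
        return bool(rev.size and np.nanmax(rev) >= cut)


def motif_enrichment(
    fg: Mapping[str, str],
    bg: Mapping[str, str],
    pwms: Sequence[PWM],
    score_cut_frac: float = 0.8,
) -> pd.DataFrame:
    """ZOOPS hypergeometric motif enrichment of foreground vs background.

    Counts, per motif, the sequences with at least one hit; the p-value is
    the hypergeometric upper tail of drawing ``n_fg_hit`` hit sequences in
    ``n_fg`` draws from the pooled collection; q-values are BH-adjusted
    over motifs.  Foreground and background must be disjoint by id.
    """
    if not fg:
        raise ValueError("empty foreground")
    if not bg:
        raise ValueError("empty background")
    shared = set(fg) & set(bg)
    if shared:
        raise ValueError(f"foreground and background share ids: {sorted(shared)[:5]}")
    enc_fg = [(_encode(s), _encode(s.translate(_COMPLEMENT)[::-1])) for s in fg.values()]
    enc_bg = [(_encode(s), _encode(s.translate(_COMPLEMENT)[::-1])) for s in bg.values()]
    rows = []
    for pwm in pwms:
        lo, cut = pwm.log_odds, score_cut_frac * pwm.max_score
        n_fg_hit = sum(_has_hit(c, crc, lo, cut) for c, crc in enc_fg)
        n_bg_hit = sum(_has_hit(c, crc, lo, cut) for c, crc in enc_bg)
        pool = len(fg) + len(bg)
        successes = n_fg_hit + n_bg_hit
        p = float(sps.hypergeom.sf(n_fg_hit - 1, pool, successes, len(fg)))
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "tf_name": pwm.tf_name,
                "n_fg_hit": n_fg_hit,
                "n_fg": len(fg),
                "n_bg_hit": n_bg_hit,
                "n_bg": len(bg),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# region selection and candidate filtering


def select_enhancer_regions(
    dmrs: Sequence[DMR], k27: PeakSet, focal_direction: str
) -> list[GenomicInterval]:
    """Hypomethylated enhancer DMR regions devoid of H3K27me3.

    Keeps regions of enhancer DMRs hypomethylated in the focal cell type
    (``focal_direction`` is ``hypo_a`` or ``hypo_b``) with zero overlap
    with any consensus H3K27me3 peak of that cell type.
    """
    if focal_direction not in {"hypo_a", "hypo_b"}:
        raise ValueError("focal_direction must be 'hypo_a' or 'hypo_b'")
    selected = []
    for dmr in dmrs:
        if not dmr.enhancer_dmr or dmr.direction != focal_direction:
            continue
        if k27.any_overlap(dmr.region):
            continue
        selected.append(dmr.region)
    return selected


def select_tf_candidates(
    prom_enrich: pd.DataFrame,
    enh_enrich: pd.DataFrame,
    states: Mapping[str, HistoneStateCall],
    up_set: set[str],
    motif_to_gene: Mapping[str, str],
    q_cut: float = 0.05,
) -> list[TFCandidate]:
    """Filter motif hits down to candidate upstream regulators.

    A transcription factor is selected when its motif is enriched
    (q < ``q_cut``) in both the promoter and the enhancer-DMR scans, its
    own gene carries an 'active' histone state in the focal cell type,
    and it is upregulated there.  The motif-to-gene mapping is an
    explicit table; unresolvable genes are retained with a missing-state
    flag and never selected.  All candidates are returned for audit.
    """
    prom_q = dict(zip(prom_enrich["motif_id"], prom_enrich["q"]))
    enh_q = dict(zip(enh_enrich["motif_id"], enh_enrich["q"]))
    candidates = []
    for motif_id in sorted(set(prom_q) | set(enh_q)):
        gene = motif_to_gene.get(motif_id)
        in_prom = bool(prom_q.get(motif_id, np.nan) < q_cut)
        in_enh = bool(enh_q.get(motif_id, np.nan) < q_cut)
        if gene is None or gene not in states:
            candidates.append(
                TFCandidate(gene or motif_id, in_prom, in_enh, None, False, missing_state=True)
            )
            continue
        candidates.append(
            TFCandidate(gene, in_prom, in_enh, states[gene].state, gene in up_set)
        )
    n_sel = sum(c.selected for c in candidates)
    log.info("TF selection: %d candidates, %d selected", len(candidates), n_sel)
    return candidates
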