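"""Expression-side computations.

TPM normalisation, differential-expression table thresholding, percent-of-
max heatmap scaling, replicate correlation, a simple two-group test used
for synthetic pipelines, and qPCR 2^−ΔCT quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass
class QPCRRecord:
    """Relative qPCR expression of a target vs a reference gene."""

    gene_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        self.valid = np.isfinite(self.ct_target) and np.isfinite(self.ct_reference)
        self.delta_ct = self.ct_target - self.ct_reference if self.valid else np.nan
        self.rel_expr = 2.0 ** (-self.delta_ct) if self.valid else np.nan


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts Per Million from a genes × samples count matrix.

    Per sample, each gene's count is divided by its length in bp and the
    resulting rates are rescaled to sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise KeyError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    tpm = rates.div(totals.where(totals > 0, 1.0), axis=1) * 1e6
    return tpm


def filter_de(
    de_table: pd.DataFrame, lfc_cut: float = 1.0, fdr_cut: float = 0.01
) -> tuple[set[str], set[str]]:
    """Split a DE table (gene_id, log2fc, fdr; A over B) into up-sets.

    ``up_in_A`` holds genes with log2fc > lfc_cut and fdr < fdr_cut;
    ``up_in_B`` the mirror with log2fc < −lfc_cut.  The sets are disjoint.
    """
    fdr_ok = de_table["fdr"] < fdr_cut
    up_a = set(de_table.loc[(de_table["log2fc"] > lfc_cut) & fdr_ok, "gene_id"])
    up_b = set(de_table.loc[(de_table["log2fc"] < -lfc_cut) & fdr_ok, "gene_id"])
    return up_a, up_b


def percent_of_max(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to percent of its own maximum; all-zero rows stay 0."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    row_max = arr.max(axis=1, keepdims=True)
    safe = np.where(row_max > 0, row_max, 1.0)
    return pd.DataFrame(arr / safe * 100.0, index=values.index, columns=values.columns)


def replicate_correlation(table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Sample × sample correlation matrix; zero-variance samples give NaN."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    return table.corr(method=method)


def welch_de_test(
    tpm: pd.DataFrame, samples_a: list[str], samples_b: list[str]
) -> pd.DataFrame:
    """Two-group Welch test on log2(TPM + 1) with BH adjustment.

    A simple surrogate DE test for synthetic pipelines (count-model DE
    tables from a dedicated tool may be supplied to :func:`filter_de`
    directly instead).  Returns a table with gene_id, log2fc (mean A −
    mean B on the log2 scale) and fdr.
    """
    la = np.log2(tpm[samples_a].to_numpy(dtype=float) + 1.0)
    lb = np.log2(tpm[samples_b].to_numpy(dtype=float) + 1.0)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {"gene_id": tpm.index, "log2fc": log2fc, "fdr": bh_adjust(p)}
    ).reset_index(drop=True)


def moderated_de_test(
    tpm: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Variance-moderated two-group test on log2(TPM + 1).

    Per-gene pooled variances are shrunk toward the run-wide mean
    variance with prior weight ``prior_df``, which keeps the test usable
    at two replicates per group where a plain Welch test has no power.
    Returns the same (gene_id, log2fc, fdr) table as
    :func:`welch_de_test`.
    """
    la = np.log2(tpm[samples_a].to_numpy(dtype=float) + 1.0)
    lb = np.log2(tpm[samples_b].to_numpy(dtype=float) + 1.0)
    na, nb = la.shape[1], lb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least two samples per group")
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    df_resid = na + nb - 2
    s2 = ((na - 1) * la.var(axis=1, ddof=1) + (nb - 1) * lb.var(axis=1, ddof=1)) / df_resid
    s2_mod = (prior_df * float(np.mean(s2)) + df_resid * s2) / (prior_df + df_resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(np.abs(t), df=prior_df + df_resid)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {"gene_id": tpm.index, "log2fc": log2fc, "fdr": bh_adjust(p)}
    ).reset_index(drop=True)


def qpcr_relative_expression(
    ct_target: float, ct_reference: float, gene_id: str = ""
) -> QPCRRecord:
    """2^−ΔCT relative expression (ΔCT = CT_target − CT_reference)."""
    return QPCRRecord(gene_id, float(ct_target), float(ct_reference))


def qpcr_group_summary(records: list[QPCRRecord], scale: str = "rel_expr") -> dict:
    """Arithmetic mean and SD of a replicate group.

    ``scale`` chooses 2^−ΔCT (default) or the ΔCT scale; records with a
    missing CT are flagged invalid and excluded.
    """
    if scale not in {"rel_expr", "delta_ct"}:
        raise ValueError("scale must be 'rel_expr' or 'delta_ct'")
    vals = [getattr(r, scale) for r in records if r.valid]
    n = len(vals)
    return {
        "n": n,
        "mean": float(np.mean(vals)) if n else float("nan"),
        "sd": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
        "n_excluded": len(records) - n,
    }
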