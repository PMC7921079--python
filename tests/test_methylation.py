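"""Probe filtering, β/M transform, differential probes and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from endoepi.genomic_core import GeneModel, GenomicInterval
from endoepi.methylation import (
    assign_dmrs,
    beta_to_m,
    call_dmrs,
    differential_probes,
    filter_probes,
    genic_region_summary,
    promoter_hypo_and_up,
    DMR,
)
from endoepi.stats import bh_adjust, stouffer_z

SAMPLES = ["BEC_rep1", "BEC_rep2", "LEC_rep1", "LEC_rep2"]
GROUPS = {"BEC_rep1": "BEC", "BEC_rep2": "BEC", "LEC_rep1": "LEC", "LEC_rep2": "LEC"}


def probe_frame(rows):
    """rows: (probe_id, pos, betas tuple, det, cross_hyb, snp)"""
    rec = []
    for pid, pos, betas, det, ch, snp in rows:
        r = {
            "probe_id": pid, "chrom": "chr1", "pos": pos, "gene_id": "",
            "genic_region": "intergenic", "enhancer": False,
            "cross_hyb": ch, "snp_overlap": snp,
        }
        for s, b in zip(SAMPLES, betas):
            r[f"beta_{s}"] = b
        for s, d in zip(SAMPLES, det):
            r[f"det_{s}"] = d
        rec.append(r)
    return pd.DataFrame(rec)


class TestFilterProbes:
    def test_filter_rules(self):
        clean_det = (0.001,) * 4
        probes = probe_frame(
            [
                ("keep", 100, (0.5,) * 4, clean_det, False, False),
                ("fail_det", 200, (0.5,) * 4, (0.001, 0.02, 0.001, 0.001), False, False),
                ("xhyb", 300, (0.5,) * 4, clean_det, True, False),
                ("snp", 400, (0.5,) * 4, clean_det, False, True),
            ]
        )
        kept = filter_probes(probes)
        assert kept["probe_id"].tolist() == ["keep"]


class TestBetaToM:
    @pytest.mark.parametrize("beta, m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_antisymmetry(self, beta):
        assert beta_to_m(beta) == pytest.approx(-beta_to_m(1.0 - beta), abs=1e-9)

    def test_endpoints_finite_and_monotone(self):
        grid = np.linspace(0, 1, 101)
        m = beta_to_m(grid)
        assert np.all(np.isfinite(m))
        assert np.all(np.diff(m) >= 0)


class TestBH:
    def _brute_force(self, p):
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    def test_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("m", [1, 10, 1000, 10_000])
    def test_matches_brute_force_step_up(self, m):
        rng = np.random.default_rng(m)
        p = rng.uniform(size=m)
        assert np.allclose(bh_adjust(p), self._brute_force(p))

    def test_nan_entries_excluded(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], self._brute_force(np.array([0.01, 0.04])))


class TestDifferentialProbes:
    def test_null_probe_has_large_p_and_zero_delta(self):
        probes = probe_frame(
            [(f"p{i}", 100 * i, (0.4, 0.6, 0.4, 0.6), (0.001,) * 4, False, False) for i in range(20)]
        )
        diff = differential_probes(probes, GROUPS, "BEC", "LEC")
        assert np.allclose(diff["delta_beta"], 0.0)
        assert (diff["p"] > 0.9).all()

    def test_requires_two_samples_per_group(self):
        probes = probe_frame([("p1", 100, (0.5,) * 4, (0.001,) * 4, False, False)])
        with pytest.raises(ValueError):
            differential_probes(probes, {"BEC_rep1": "BEC", "LEC_rep1": "LEC"}, "BEC", "LEC")

    def test_shifted_probes_detected_among_nulls(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(300):
            base = 0.5
            if i < 20:  # planted hypomethylation in BEC
                betas = np.clip(
                    [base - 0.3, base - 0.3, base, base] + rng.normal(0, 0.02, 4), 0.01, 0.99
                )
            else:
                betas = np.clip(base + rng.normal(0, 0.02, 4), 0.01, 0.99)
            rows.append((f"p{i:03d}", 100 * i, tuple(betas), (0.001,) * 4, False, False))
        diff = differential_probes(probe_frame(rows), GROUPS, "BEC", "LEC")
        planted = diff.iloc[:20]
        assert (planted["q"] < 0.05).mean() >= 0.9
        assert (planted["delta_beta"] < 0).all()
        assert (diff.iloc[20:]["q"] < 0.05).mean() <= 0.02


def diff_frame(rows):
    """rows: (pos, q, z, delta_beta) on chr1, already sorted."""
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(rows))],
            "chrom": "chr1",
            "pos": [r[0] for r in rows],
            "gene_id": "",
            "genic_region": "intergenic",
            "enhancer": False,
            "q": [r[1] for r in rows],
            "z": [r[2] for r in rows],
            "delta_beta": [r[3] for r in rows],
        }
    )


class TestCallDMRs:
    def test_stouffer_closed_form_for_equal_z(self):
        diff = diff_frame([(100, 0.01, 1.96, 0.2), (200, 0.01, 1.96, 0.2), (300, 0.01, 1.96, 0.2)])
        (dmr,) = call_dmrs(diff, fdr_cut=0.05)
        assert dmr.stouffer_z == pytest.approx(1.96 * np.sqrt(3))
        assert dmr.direction == "hypo_b"
        assert stouffer_z([1.96] * 3) == pytest.approx(3.395, abs=0.001)

    def test_two_probe_runs_never_called(self):
        diff = diff_frame([(100, 0.001, 4.0, 0.3), (200, 0.001, 4.0, 0.3)])
        assert call_dmrs(diff) == []

    def test_large_gap_splits_runs(self):
        diff = diff_frame(
            [(100, 1e-4, 4.0, 0.3), (200, 1e-4, 4.0, 0.3), (5000, 1e-4, 4.0, 0.3),
             (5100, 1e-4, 4.0, 0.3), (5200, 1e-4, 4.0, 0.3)]
        )
        dmrs = call_dmrs(diff, max_gap=1000)
        assert len(dmrs) == 1 and dmrs[0].region.start == 5000

    def test_sign_change_splits_runs(self):
        diff = diff_frame(
            [(100, 1e-4, 4.0, 0.3), (200, 1e-4, -4.0, -0.3), (300, 1e-4, 4.0, 0.3)]
        )
        assert call_dmrs(diff) == []

    def test_unsorted_input_rejected(self):
        diff = diff_frame([(300, 0.01, 2.0, 0.1), (100, 0.01, 2.0, 0.1), (200, 0.01, 2.0, 0.1)])
        with pytest.raises(ValueError):
            call_dmrs(diff)

    def test_reported_dmrs_satisfy_their_invariants(self, small_run):
        _, ctx = small_run
        for dmr in ctx["dmrs"]:
            assert len(dmr.probe_ids) >= 3
            assert dmr.stouffer_fdr < 0.05
            assert (dmr.direction == "hypo_a") == (dmr.mean_delta_beta < 0)


class TestAssignDMRs:
    def make_diff(self, enhancer_q):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(3)],
                "enhancer": [True, False, False],
                "q": [enhancer_q, 0.001, 0.001],
            }
        )

    def make_dmr(self, start=900, end=1200):
        return DMR(GenomicInterval("chr1", start, end), ["p0", "p1", "p2"], 4.0, 0.001, -0.3)

    def test_promoter_overlap_assigns_genes(self):
        # plus-strand gene at 3000: promoter [1000, 4000)
        gene = GeneModel("G1", GenomicInterval("chr1", 3000, 8000, "+"))
        (dmr,) = assign_dmrs([self.make_dmr()], [gene], self.make_diff(0.001))
        assert dmr.assigned_genes == ["G1"]

    def test_dmr_spanning_two_promoters_lists_both(self):
        g1 = GeneModel("G1", GenomicInterval("chr1", 1300, 5000, "+"))  # promoter [0, 2300)
        g2 = GeneModel("G2", GenomicInterval("chr1", 500, 1000, "-"))  # promoter [0, 3000) via tss=1000
        (dmr,) = assign_dmrs([self.make_dmr(900, 1500)], [g1, g2], self.make_diff(0.001))
        assert sorted(dmr.assigned_genes) == ["G1", "G2"]

    def test_enhancer_flag_requires_significant_enhancer_probe(self):
        (with_sig,) = assign_dmrs([self.make_dmr()], [], self.make_diff(0.001))
        (without,) = assign_dmrs([self.make_dmr()], [], self.make_diff(0.5))
        assert with_sig.enhancer_dmr and not without.enhancer_dmr


class TestSummaries:
    def test_probe_counts_conserved_across_categories(self, small_run):
        ds, ctx = small_run
        summary = ctx["genic_summary"]
        up_a = ctx["up_a"]
        diff = ctx["diff_probes"]
        total = summary[(summary["gene_set"] == f"up_{ds.config.cell_a}") & (summary["cell_type"] == "a")][
            "n_probes"
        ].sum()
        assert total == diff["gene_id"].isin(up_a).sum()

    def test_unknown_category_rejected(self):
        diff = diff_frame([(100, 0.5, 0.1, 0.0)])
        diff.loc[0, "genic_region"] = "nonsense"
        diff["mean_beta_a"] = 0.5
        diff["mean_beta_b"] = 0.5
        with pytest.raises(ValueError):
            genic_region_summary(diff, {"set": {"G1"}})

    def test_promoter_hypo_and_up_direction_logic(self):
        hypo_a = DMR(GenomicInterval("chr1", 0, 10), ["a", "b", "c"], -4.0, 0.01, -0.3, ["G1", "G2"])
        hypo_b = DMR(GenomicInterval("chr1", 20, 30), ["d", "e", "f"], 4.0, 0.01, +0.3, ["G3"])
        got_a, got_b = promoter_hypo_and_up([hypo_a, hypo_b], up_a={"G1", "G3"}, up_b={"G3"})
        assert got_a == {"G1"}  # G2 not upregulated, G3 wrong direction
        assert got_b == {"G3"}
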