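"""Stability methods vs independent brute-force oracles and planted truth."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_panel

from refstab.simulate import CqPanelSpec, GeneSpec, simulate_cq_panel
from refstab.stability import (
    bestkeeper_stats,
    comprehensive_rank,
    delta_ct_stability,
    genorm_rank,
    genorm_v_curve,
    normfinder_stability,
    rank_panel,
    to_relative_quantities,
)


class TestRelativeQuantities:
    def test_transform_values(self):
        panel = make_panel([[20.0, 21.0, 22.0], [30.0, 32.0, 31.0]])
        q = to_relative_quantities(panel).q
        assert q.loc["G1", "s1"] == 1.0                       # at the min Cq
        assert q.loc["G1", "s2"] == pytest.approx(0.5)        # one cycle later, E=2
        assert q.max(axis=1).tolist() == [1.0, 1.0]

    def test_non_doubling_efficiency(self):
        panel = make_panel([[20.0, 22.0, 21.0], [25.0, 25.0, 25.0]], efficiency=1.9)
        q = to_relative_quantities(panel).q
        assert q.loc["G1", "s2"] == pytest.approx(1.9 ** -2)
        assert q.loc["G1", "s2"] == pytest.approx(0.27701, rel=1e-4)

    def test_implausible_cq_rejected(self):
        with pytest.raises(ValueError, match="implausible Cq"):
            make_panel([[20.0, 55.0, 21.0], [25.0, 25.0, 25.0]])

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="bad efficiency"):
            make_panel([[20.0, 21.0, 22.0], [25.0, 25.0, 25.0]], efficiency=2.5)


class TestGenorm:
    def test_m_values_match_oracle_on_random_panels(self, random_small_panels):
        for panel in random_small_panels:
            q = to_relative_quantities(panel)
            res = genorm_rank(q)
            # first-step M of every gene equals the definitional oracle
            expected = oracles.genorm_m_oracle(q.q.to_numpy())
            first_step = dict(zip(panel.gene_ids, expected))
            worst_val = max(first_step.values())
            assert first_step[res.exclusion_order[0]] == worst_val
            # the first-removed gene's stored M is its first-step M
            assert res.m_value[res.exclusion_order[0]] == pytest.approx(
                first_step[res.exclusion_order[0]], rel=1e-9
            )

    def test_proportional_genes_have_zero_mutual_variation(self):
        # G2 = 0.5 * G1 in quantity space -> one extra cycle
        panel = make_panel([[20.0, 21.0, 22.5], [21.0, 22.0, 23.5], [20.0, 23.0, 21.0]])
        res = genorm_rank(to_relative_quantities(panel))
        assert res.exclusion_order == ["G3"]
        assert set(res.ranking[:2]) == {"G1", "G2"}

    def test_sample_loading_factor_cancels(self):
        cq = np.array([[20.0, 21, 22, 23], [24.0, 23, 25, 22], [25.0, 26, 24, 27]])
        shifted = cq + np.array([0.0, 3.0, -2.0, 1.0])  # per-sample Cq shift
        m1 = genorm_rank(to_relative_quantities(make_panel(cq))).m_value
        m2 = genorm_rank(to_relative_quantities(make_panel(shifted))).m_value
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-9)

    def test_stepwise_exclusion_full_trace_matches_oracle(self, random_small_panels):
        for panel in random_small_panels:
            q = to_relative_quantities(panel)
            res = genorm_rank(q)
            genes = list(panel.gene_ids)
            logq = {g: np.log2(q.q.loc[g].to_numpy()) for g in genes}
            active = sorted(genes)
            exclusion = []
            while len(active) > 2:
                ms = {}
                for g in active:
                    ms[g] = np.mean(
                        [oracles.sd(logq[g] - logq[k]) for k in active if k != g]
                    )
                worst_val = max(ms.values())
                drop = min(g for g in active if ms[g] == worst_val)
                exclusion.append(drop)
                active.remove(drop)
            assert res.exclusion_order == exclusion
            assert res.ranking[2:] == list(reversed(exclusion))


class TestVCurve:
    def test_matches_oracle(self, random_small_panels):
        for panel in random_small_panels:
            q = to_relative_quantities(panel)
            res = genorm_rank(q)
            curve, _, _ = genorm_v_curve(q, res.ranking)
            order_idx = [panel.gene_ids.index(g) for g in res.ranking]
            expected = oracles.genorm_v_curve_oracle(q.q.to_numpy(), order_idx)
            assert np.allclose(curve, expected, rtol=1e-9)

    def test_third_gene_proportional_to_nf2_recommends_two(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(24, 0.8, 10)
        g2 = rng.normal(26, 0.8, 10)
        nf2 = (g1 + g2) / 2.0          # Cq of the two-gene geometric mean
        g4 = rng.normal(25, 1.5, 10)
        cq = np.vstack([g1, g2, nf2 + 1.0, g4])
        q = to_relative_quantities(make_panel(cq))
        curve, n, ok = genorm_v_curve(q, ["G1", "G2", "G3", "G4"], cutoff=0.15)
        assert curve[0] == pytest.approx(0.0, abs=1e-12)
        assert n == 2 and ok

    def test_cutoff_monotonicity(self, random_small_panels):
        for panel in random_small_panels:
            q = to_relative_quantities(panel)
            res = genorm_rank(q)
            ns = []
            for cutoff in (0.05, 0.15, 0.5, 2.0):
                _, n, _ = genorm_v_curve(q, res.ranking, cutoff=cutoff)
                ns.append(n)
            assert ns == sorted(ns, reverse=True)

    def test_no_cutoff_satisfied_flags_and_returns_m(self):
        rng = np.random.default_rng(11)
        cq = rng.normal(25, 3.0, size=(4, 8))
        q = to_relative_quantities(make_panel(cq))
        curve, n, ok = genorm_v_curve(q, ["G1", "G2", "G3", "G4"], cutoff=1e-6)
        assert not ok and n == 4


class TestNormFinder:
    def test_grouped_matches_loop_oracle(self, random_small_panels):
        for panel in random_small_panels:
            res = normfinder_stability(panel)
            q = to_relative_quantities(panel)
            y = np.log2(q.q.to_numpy())
            expected = oracles.normfinder_oracle(y, list(panel.groups))
            assert np.allclose(res.stability.to_numpy(), expected, rtol=1e-9)

    def test_ungrouped_constant_gene_ranks_first(self):
        # G1 follows the per-sample loading exactly -> zero centered residual
        shift = np.array([0.0, 1.0, -1.0, 0.5])
        rng = np.random.default_rng(3)
        cq = np.vstack([
            24.0 + shift,
            25.0 + shift + rng.normal(0, 0.5, 4),
            26.0 + shift + rng.normal(0, 0.7, 4),
            23.0 + shift + rng.normal(0, 0.9, 4),
        ])
        panel = make_panel(cq)    # single group -> ungrouped mode
        res = normfinder_stability(panel)
        assert not res.grouped
        assert res.stability["G1"] == pytest.approx(0.0, abs=1e-9)
        assert res.best_gene == "G1"

    def test_identical_genes_all_zero_stability(self):
        cq = np.tile(np.array([24.0, 25.0, 23.0, 26.0]), (4, 1))
        res = normfinder_stability(make_panel(cq, groups=["A", "A", "B", "B"]))
        assert np.allclose(res.stability.to_numpy(), 0.0, atol=1e-12)
        assert res.gamma2 == 0.0

    def test_group_effect_penalized_against_equal_noise_control(self):
        genes = [GeneSpec(f"N{i}", "stable", base=25.0, noise_sd=0.3) for i in range(6)]
        genes.append(GeneSpec("CTRL", "stable", base=24.0, noise_sd=0.3))
        genes.append(GeneSpec("SHIFT", "noisy", base=24.0, noise_sd=0.3,
                              effects={"g1": 2.0}))
        spec = CqPanelSpec("pen", genes, {"g1": 10, "g2": 10, "g3": 10},
                           sample_shift_sd=0.5, seed=42)
        panel, _ = simulate_cq_panel(spec)
        res = normfinder_stability(panel)
        assert res.stability["SHIFT"] > res.stability["CTRL"]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="too few genes"):
            normfinder_stability(make_panel([[20.0, 21, 22], [24.0, 23, 25]]))

    def test_degenerate_group_rejected(self):
        panel = make_panel(np.full((3, 3), 25.0), groups=["A", "A", "B"])
        with pytest.raises(ValueError, match="degenerate group"):
            normfinder_stability(panel)


class TestBestKeeper:
    def test_matches_oracle(self, random_small_panels):
        for panel in random_small_panels:
            res = bestkeeper_stats(panel)
            sds, cvs, index, rs = oracles.bestkeeper_oracle(panel.cq.to_numpy())
            assert np.allclose(res.sd_cq.to_numpy(), sds, rtol=1e-9)
            assert np.allclose(res.cv_pct.to_numpy(), cvs, rtol=1e-9)
            assert np.allclose(res.index.to_numpy(), index, rtol=1e-9)
            assert np.allclose(res.r_index.to_numpy(), rs, rtol=1e-9)

    def test_constant_gene_zero_sd_undefined_r(self):
        cq = np.array([[25.0, 25, 25, 25], [20.0, 22, 21, 23]])
        res = bestkeeper_stats(make_panel(cq))
        assert res.sd_cq["G1"] == 0.0
        assert np.isnan(res.r_index["G1"])
        assert res.sd_cq.idxmin() == "G1"

    def test_identical_rows_self_correlate(self):
        row = np.array([20.0, 22.0, 21.0, 23.0])
        res = bestkeeper_stats(make_panel(np.vstack([row, row])))
        assert np.allclose(res.index.to_numpy(), row)
        assert np.allclose(res.r_index.to_numpy(), 1.0)

    def test_mad_variant_differs_and_is_smaller_or_equal(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.normal(25, 1, size=(3, 6)))
        sd_res = bestkeeper_stats(panel, dispersion="sd")
        mad_res = bestkeeper_stats(panel, dispersion="mad")
        assert (mad_res.sd_cq.to_numpy() <= sd_res.sd_cq.to_numpy() + 1e-12).all()


class TestDeltaCt:
    def test_matches_oracle(self, random_small_panels):
        for panel in random_small_panels:
            res = delta_ct_stability(panel)
            expected = oracles.delta_ct_oracle(panel.cq.to_numpy())
            assert np.allclose(res.mean_pair_sd.to_numpy(), expected, rtol=1e-9)

    def test_constant_offset_pair_and_loading_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(24, 1, 5)
        cq = np.vstack([base, base + 3.0, rng.normal(25, 1, 5)])
        res = delta_ct_stability(make_panel(cq))
        # G1/G2 differ by a constant -> their pair SD is 0, so both average
        # only the G3 pairing over m-1 = 2 partners
        assert res.mean_pair_sd["G1"] == pytest.approx(
            oracles.sd(cq[0] - cq[2]) / 2, rel=1e-12
        )
        shifted = cq + rng.normal(0, 2, 5)[None, :]
        res2 = delta_ct_stability(make_panel(shifted))
        assert np.allclose(res.mean_pair_sd.to_numpy(), res2.mean_pair_sd.to_numpy())


class TestComprehensive:
    def test_geomean_of_known_ranks(self, random_small_panels):
        panel = random_small_panels[0]
        results = rank_panel(panel)
        comp = results["comprehensive"]
        for g in panel.gene_ids:
            expected = oracles.geomean(comp.method_ranks.loc[g].tolist())
            assert comp.geomean_rank[g] == pytest.approx(expected, rel=1e-12)
        assert oracles.geomean([1, 2, 3, 4]) == pytest.approx(24 ** 0.25)
        assert oracles.geomean([1, 2, 3, 4]) == pytest.approx(2.21336, rel=1e-5)

    def test_each_method_ranks_are_tie_averaged_permutation(self, random_small_panels):
        for panel in random_small_panels:
            comp = rank_panel(panel)["comprehensive"]
            m = len(panel.gene_ids)
            for col in comp.method_ranks:
                assert comp.method_ranks[col].sum() == pytest.approx(m * (m + 1) / 2)
            assert sorted(comp.final_order) == sorted(panel.gene_ids)

    def test_genorm_final_pair_tied_at_1_5(self, random_small_panels):
        panel = random_small_panels[0]
        results = rank_panel(panel)
        gn_ranks = results["comprehensive"].method_ranks["genorm"]
        assert sorted(gn_ranks.nsmallest(2).tolist()) == [1.5, 1.5]

    def test_argument_order_symmetry_and_mismatch(self, random_small_panels):
        panel = random_small_panels[0]
        r = rank_panel(panel)
        a = comprehensive_rank(r["genorm"], r["normfinder"], r["bestkeeper"], r["delta_ct"])
        assert a.final_order == r["comprehensive"].final_order
        other = make_panel(np.random.default_rng(0).normal(25, 1, (3, 4)),
                           gene_ids=["X1", "X2", "X3"])
        sub = delta_ct_stability(other)
        with pytest.raises(ValueError, match="inconsistent"):
            comprehensive_rank(r["genorm"], r["normfinder"], r["bestkeeper"], sub)


class TestPlantedRecovery:
    def test_minimum_noise_gene_ranks_first_without_group_effects(self):
        sds = [0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 1.0]
        genes = [GeneSpec(f"R{i}", "stable", base=24.0 + i * 0.5, noise_sd=s)
                 for i, s in enumerate(sds)]
        spec = CqPanelSpec("rec", genes, {"g1": 10, "g2": 10, "g3": 10},
                           sample_shift_sd=1.0, seed=2024)
        panel, gt = simulate_cq_panel(spec)
        results = rank_panel(panel)
        assert results["comprehensive"].final_order[0] == "R0"
        assert gt.true_stability.idxmin() == "R0"

    def test_zero_noise_panel_all_methods_flat(self):
        genes = [GeneSpec(f"Z{i}", "stable", base=22.0 + i, noise_sd=0.0)
                 for i in range(4)]
        spec = CqPanelSpec("flat", genes, {"g1": 5, "g2": 5}, sample_shift_sd=1.0, seed=3)
        panel, _ = simulate_cq_panel(spec)
        results = rank_panel(panel)
        assert np.allclose(results["genorm"].m_value.to_numpy(), 0.0, atol=1e-9)
        assert np.allclose(results["delta_ct"].mean_pair_sd.to_numpy(), 0.0, atol=1e-9)
        assert np.allclose(results["normfinder"].stability.to_numpy(), 0.0, atol=1e-9)
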