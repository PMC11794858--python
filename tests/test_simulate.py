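"""Generator contracts: determinism, stream separation, planted structure."""

import numpy as np
import pytest
from scipy import stats

import fcbiotype as fb
from fcbiotype.errors import DesignError
from fcbiotype.simulate import COUPLED_MAPS, planted_delta


class TestDesign:
    def test_bad_proportions_rejected(self):
        with pytest.raises(DesignError):
            fb.SimulationDesign(biotype_proportions=(0.5, 0.5, 0.5))

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(DesignError):
            fb.SimulationDesign(coupling_strength=1.0)

    def test_infeasible_map_rho_rejected(self):
        with pytest.raises(DesignError):
            fb.SimulationDesign(map_rho=1.5)

    def test_biotype_counts_sum(self):
        d = fb.SimulationDesign()
        counts = d.biotype_counts()
        assert counts.sum() == d.n_chr
        np.testing.assert_allclose(counts / d.n_chr, d.biotype_proportions, atol=0.01)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, small_atlas):
        d = fb.SimulationDesign(atlas=small_atlas, n_chr=40, n_hc=25, seed=5)
        c1, s1, t1 = fb.simulate_cohort(d)
        c2, s2, t2 = fb.simulate_cohort(fb.SimulationDesign(
            atlas=small_atlas, n_chr=40, n_hc=25, seed=5))
        np.testing.assert_array_equal(s1.edges, s2.edges)
        assert c1.table.equals(c2.table)
        np.testing.assert_array_equal(t1.biotype_labels, t2.biotype_labels)
        m1 = fb.simulate_maps(d, t1)
        m2 = fb.simulate_maps(d, t2)
        assert m1.values.equals(m2.values)

    def test_map_stream_separate_from_connectomes(self, small_atlas):
        """Changing the number of maps must not perturb the cohort draw."""
        d1 = fb.SimulationDesign(atlas=small_atlas, n_chr=30, n_hc=20, seed=9, n_maps=39)
        d2 = fb.SimulationDesign(atlas=small_atlas, n_chr=30, n_hc=20, seed=9, n_maps=5)
        _, s1, _ = fb.simulate_cohort(d1)
        _, s2, _ = fb.simulate_cohort(d2)
        np.testing.assert_array_equal(s1.edges, s2.edges)


class TestPlantedStructure:
    def test_null_design_group_equality(self, small_atlas):
        """With delta = 0 and no coupling, an edgewise two-sample t has
        type-I rate close to alpha."""
        d = fb.null_design(seed=3, atlas=small_atlas, n_chr=60, n_hc=40)
        cohort, stack, _ = fb.simulate_cohort(d)
        g = cohort.group_mask("CHR")
        t, p = stats.ttest_ind(stack.edges[g], stack.edges[~g], axis=0)
        rate = np.mean(p < 0.05)
        se = np.sqrt(0.05 * 0.95 / stack.n_edges)
        assert abs(rate - 0.05) < 4 * se

    def test_effect_recovery_on_affected_blocks(self, default_sim):
        """Edgewise t on a planted block matches the noncentral
        expectation: large for affected biotype, near zero otherwise."""
        design, cohort, stack, truth = default_sim
        chr_idx = np.flatnonzero(cohort.group_mask("CHR"))
        hc_idx = np.flatnonzero(cohort.group_mask("HC"))
        delta = truth.delta
        b1 = chr_idx[truth.biotype_labels == 1]
        affected = np.flatnonzero(delta[0] > 0)[:200]   # B1 increased edges
        tvals = stats.ttest_ind(
            stack.edges[np.ix_(b1, affected)], stack.edges[np.ix_(hc_idx, affected)]
        ).statistic
        assert np.mean(tvals) > 5  # delta ~0.3 over sd ~0.15-0.19 at n=45 vs 88
        unaffected = np.flatnonzero(np.abs(delta).sum(axis=0) == 0)[:200]
        t0 = stats.ttest_ind(
            stack.edges[np.ix_(b1, unaffected)], stack.edges[np.ix_(hc_idx, unaffected)]
        ).statistic
        assert abs(np.mean(t0)) < 0.5

    def test_coupling_strength_calibration(self):
        """Mean |r| between coupled edges and their domain's items hits
        the design target within Monte-Carlo error (20 seeds)."""
        from fcbiotype.cohort import SIPS_ITEMS

        dom_of_item = np.array([{"P": 0, "N": 1, "D": 2, "G": 3}[n[0]] for n in SIPS_ITEMS])
        vals = []
        for seed in range(20):
            d = fb.SimulationDesign(seed=seed)
            cohort, stack, truth = fb.simulate_cohort(d)
            chr_idx = np.flatnonzero(cohort.group_mask("CHR"))
            Z = stack.edges[chr_idx][:, truth.coupled_edge_ids]
            items = cohort.clinical_items(chr_idx).to_numpy(dtype=float)[:, :19]
            Zs = (Z - Z.mean(0)) / Z.std(0)
            Is = (items - items.mean(0)) / items.std(0)
            R = np.abs(Zs.T @ Is) / Z.shape[0]
            per_domain = [
                R[np.ix_(truth.coupled_edge_domains == k, dom_of_item == k)].mean()
                for k in range(4)
            ]
            vals.append(np.mean(per_domain))
        assert abs(np.mean(vals) - 0.4) < 0.05


class TestMaps:
    def test_perfect_coupling_gives_r_one(self, small_atlas):
        d = fb.SimulationDesign(atlas=small_atlas, n_chr=30, n_hc=20, map_rho=1.0, seed=2)
        truth = fb.planted_truth(d)
        maps = fb.simulate_maps(d, truth)
        for name, b in COUPLED_MAPS.items():
            r = np.corrcoef(truth.node_profiles[b - 1], maps.vector(name))[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_coupling_near_null(self):
        d = fb.SimulationDesign(map_rho=0.0, seed=4)
        truth = fb.planted_truth(d)
        maps = fb.simulate_maps(d, truth)
        rs = [
            np.corrcoef(truth.node_profiles[b - 1], maps.vector(name))[0, 1]
            for name, b in COUPLED_MAPS.items()
        ]
        assert np.max(np.abs(rs)) < 4 / np.sqrt(246)

    def test_map_count_and_names(self):
        d = fb.SimulationDesign(seed=0)
        maps = fb.simulate_maps(d, fb.planted_truth(d))
        assert maps.n_maps == 39
        assert len(set(maps.map_names)) == 39


def test_planted_delta_within_stated_range():
    """Default signed effects stay in the documented magnitude band."""
    d = fb.SimulationDesign()
    delta = planted_delta(d)
    nz = np.abs(delta[np.abs(delta) > 0])
    assert nz.min() >= 0.1 and nz.max() <= 0.6  # overlapping blocks may stack
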