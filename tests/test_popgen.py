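import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delcall import popgen
from delcall.panel import HaplotypePanel
from delcall.popgen import UndefinedStatistic


def panel_from_columns(*cols, del_index=None):
    alleles = np.array(cols, dtype=np.int8).T
    if alleles.shape[0] % 2:  # pad to an even chromosome count
        alleles = np.vstack([alleles, alleles[-1:]])
    n_var = alleles.shape[1]
    return HaplotypePanel(alleles=alleles,
                          variant_ids=[f"v{j}" for j in range(n_var)],
                          positions_bp=np.arange(1, n_var + 1) * 100,
                          del_index=del_index)


class TestPairwiseLD:
    def test_identical_columns_perfect_ld(self):
        col = [1, 1, 0, 0, 1, 0]
        ld = popgen.pairwise_ld(panel_from_columns(col, col), 0, 1)
        assert ld.r == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)
        assert ld.dprime == pytest.approx(1.0)

    def test_counting_oracle(self):
        # haplotype counts AB=4, Ab=1, aB=1, ab=4 over 10 chromosomes
        a = [1] * 4 + [1] + [0] + [0] * 4
        b = [1] * 4 + [0] + [1] + [0] * 4
        ld = popgen.pairwise_ld(panel_from_columns(a, b), 0, 1)
        assert ld.r == pytest.approx(0.6, abs=1e-12)
        assert ld.r2 == pytest.approx(0.36, abs=1e-12)
        assert ld.dprime == pytest.approx(0.6, abs=1e-12)

    def test_missing_gamete_class_dprime_one(self):
        a = [1, 1, 1, 0, 0, 0]
        b = [1, 1, 0, 0, 0, 0]  # gamete (0,1) absent, D>0
        ld = popgen.pairwise_ld(panel_from_columns(a, b), 0, 1)
        assert abs(ld.dprime) == pytest.approx(1.0)

    def test_monomorphic_is_error_not_nan(self):
        with pytest.raises(UndefinedStatistic):
            popgen.pairwise_ld(panel_from_columns([1, 1, 1, 1], [1, 0, 1, 0]), 0, 1)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=4, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_r2_equals_squared_pearson(self, pairs):
        if len(pairs) % 2:
            pairs = pairs + [pairs[0]]
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        if len(set(a)) < 2 or len(set(b)) < 2:
            return
        ld = popgen.pairwise_ld(panel_from_columns(a, b), 0, 1)
        assert ld.r2 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-10)
        assert ld.r2 == pytest.approx(ld.r ** 2, abs=1e-12)

    def test_relabel_invariance(self):
        a = [1, 0, 1, 1, 0, 0, 1, 0]
        b = [1, 1, 0, 1, 0, 0, 0, 1]
        ld = popgen.pairwise_ld(panel_from_columns(a, b), 0, 1)
        flipped = popgen.pairwise_ld(
            panel_from_columns([1 - v for v in a], [1 - v for v in b]), 0, 1)
        assert flipped.r == pytest.approx(ld.r, abs=1e-12)
        assert flipped.dprime == pytest.approx(ld.dprime, abs=1e-12)
        # flipping one locus only changes the sign of r
        one = popgen.pairwise_ld(panel_from_columns([1 - v for v in a], b), 0, 1)
        assert one.r == pytest.approx(-ld.r, abs=1e-12)


class TestLDProfile:
    def test_profile_length(self, default_dataset):
        panel = default_dataset.panel
        prof = popgen.ld_profile(panel, panel.del_index)
        assert len(prof) == panel.n_variants - 1

    def test_recurrent_origin_low_ld(self, default_dataset):
        panel = default_dataset.panel
        prof = popgen.ld_profile(panel, panel.del_index)
        assert np.nanmax(prof["r2"]) < 0.3

    def test_single_origin_high_ld(self, single_origin_dataset):
        panel = single_origin_dataset.panel
        prof = popgen.ld_profile(panel, panel.del_index)
        assert np.nanmax(prof["r2"]) > 0.8


class TestEHH:
    def test_identical_carriers_everywhere_one(self):
        col = [1, 1, 1, 1]
        same = [0, 0, 0, 0]
        panel = panel_from_columns(same, col, same, same)
        curve = popgen.ehh(panel, 1, 1)
        np.testing.assert_allclose(curve.ehh_values, 1.0)

    def test_all_unique_drops_to_zero(self):
        focal = [1, 1, 1, 1]
        split = [0, 0, 1, 1]
        split2 = [0, 1, 0, 1]
        panel = panel_from_columns(focal, split, split2)
        curve = popgen.ehh(panel, 0, 1)
        assert curve.ehh_values[2] == pytest.approx(0.0)

    def test_two_two_split_is_one_third(self):
        focal = [1, 1, 1, 1]
        split = [0, 0, 1, 1]
        panel = panel_from_columns(focal, split)
        curve = popgen.ehh(panel, 0, 1)
        assert curve.ehh_values[0] == pytest.approx(1.0)
        assert curve.ehh_values[1] == pytest.approx(1.0 / 3.0)

    def test_too_few_carriers(self):
        panel = panel_from_columns([1, 0, 0, 0], [0, 1, 0, 1])
        with pytest.raises(UndefinedStatistic):
            popgen.ehh(panel, 0, 1)

    def test_nonincreasing_outward(self, default_dataset):
        panel = default_dataset.panel
        for allele in (0, 1):
            curve = popgen.ehh(panel, panel.del_index, allele)
            f = panel.del_index
            right = curve.ehh_values[f:]
            left = curve.ehh_values[:f + 1][::-1]
            assert np.all(np.diff(right) <= 1e-12)
            assert np.all(np.diff(left) <= 1e-12)
            assert curve.ehh_values[f] == 1.0


class TestSpectrumDiversity:
    def test_all_identical_zero(self):
        panel = panel_from_columns([1, 1, 1, 1], [0, 0, 0, 0])
        spec = popgen.haplotype_spectrum(panel)
        assert popgen.haplotype_diversity(spec) == pytest.approx(0.0)

    def test_all_distinct_one(self):
        panel = panel_from_columns([0, 0, 1, 1], [0, 1, 0, 1])
        spec = popgen.haplotype_spectrum(panel)
        assert len(spec.haplotypes) == 4
        assert popgen.haplotype_diversity(spec) == pytest.approx(1.0)

    def test_three_one_counts(self):
        panel = panel_from_columns([0, 0, 0, 1])
        spec = popgen.haplotype_spectrum(panel)
        np.testing.assert_array_equal(np.sort(spec.counts), [1, 3])
        assert popgen.haplotype_diversity(spec) == pytest.approx(0.5)

    def test_frequencies_and_counts_conserve(self, default_dataset):
        spec = popgen.haplotype_spectrum(default_dataset.panel, window=(0, 30))
        assert spec.frequencies.sum() == pytest.approx(1.0)
        assert spec.counts.sum() == default_dataset.panel.n_chromosomes


class TestTajimasD:
    @staticmethod
    def naive_tajimas_d(alleles):
        """Brute-force re-implementation: explicit pairwise loops."""
        n, m = alleles.shape
        pi = 0.0
        npairs = 0
        for i, j in itertools.combinations(range(n), 2):
            pi += np.sum(alleles[i] != alleles[j])
            npairs += 1
        pi /= npairs
        S = sum(1 for k in range(m) if 0 < alleles[:, k].sum() < n)
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

    def test_second_implementation_oracle(self, rng):
        alleles = rng.integers(0, 2, size=(12, 25)).astype(np.int8)
        panel = HaplotypePanel(alleles=alleles,
                               variant_ids=[f"v{j}" for j in range(25)],
                               positions_bp=np.arange(25) * 10 + 1)
        assert popgen.tajimas_d(panel) == pytest.approx(
            self.naive_tajimas_d(alleles), abs=1e-10)

    def test_duplicated_panel_matches_oracle(self, rng):
        alleles = rng.integers(0, 2, size=(8, 15)).astype(np.int8)
        doubled = np.vstack([alleles, alleles])
        panel = HaplotypePanel(alleles=doubled,
                               variant_ids=[f"v{j}" for j in range(15)],
                               positions_bp=np.arange(15) * 10 + 1)
        assert popgen.tajimas_d(panel) == pytest.approx(
            self.naive_tajimas_d(doubled), abs=1e-10)

    def test_no_segregating_sites_error(self):
        panel = panel_from_columns([1, 1, 1, 1], [0, 0, 0, 0])
        with pytest.raises(UndefinedStatistic):
            popgen.tajimas_d(panel)

    def test_neutral_coalescent_band(self):
        # neutral panmictic coalescent replicates: mean D near 0
        msprime = pytest.importorskip("msprime")
        vals = []
        for seed in range(1, 21):
            ts = msprime.sim_ancestry(samples=20, ploidy=2, sequence_length=5e4,
                                      population_size=1e4, random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=seed)
            if mts.num_sites < 3:
                continue
            alleles = mts.genotype_matrix().T.astype(np.int8)
            alleles = np.clip(alleles, 0, 1)
            pos = np.unique(np.array([s.position for s in mts.sites()], dtype=int) + 1)
            if len(pos) != alleles.shape[1]:
                continue
            panel = HaplotypePanel(alleles=alleles,
                                   variant_ids=[f"v{j}" for j in range(alleles.shape[1])],
                                   positions_bp=pos)
            vals.append(popgen.tajimas_d(panel))
        assert len(vals) >= 10
        assert abs(np.mean(vals)) < 0.5


class TestClustering:
    def test_two_groups_merge_heights(self):
        panel = panel_from_columns([0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 1, 1])
        spec = popgen.haplotype_spectrum(panel)
        dend = popgen.cluster_haplotypes(spec)
        assert dend.linkage_matrix.shape[0] == len(spec.haplotypes) - 1

    def test_leaf_count_equals_distinct_haplotypes(self, default_dataset):
        spec = popgen.haplotype_spectrum(default_dataset.panel, window=(0, 25))
        dend = popgen.cluster_haplotypes(spec)
        assert len(dend.haplotypes) == len(spec.haplotypes)
        assert dend.linkage_matrix.shape == (len(spec.haplotypes) - 1, 4)

    def test_single_haplotype_single_leaf(self):
        panel = panel_from_columns([1, 1, 1, 1])
        spec = popgen.haplotype_spectrum(panel)
        dend = popgen.cluster_haplotypes(spec)
        assert dend.linkage_matrix.shape == (0, 4)
        assert len(dend.haplotypes) == 1

    @pytest.mark.parametrize("k", [1, 4, 8])
    def test_carrier_groups_track_origins(self, k):
        from delcall.synthetic import SimulationConfig, simulate_haplotype_panel
        cfg = SimulationConfig(n_individuals=500, n_del_origins=k,
                               copy_switch_scale=0.0, seed=31 + k)
        panel = simulate_haplotype_panel(cfg)
        assert popgen.carrier_subtree_count(panel) >= k
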