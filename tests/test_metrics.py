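"""Information-theoretic cluster metrics, split-half procedure, optimal-K
rule, hierarchy and symmetry indices."""

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

import connparc as cp
from connparc.errors import AlignmentError, DomainError
from connparc.io import SeedMask
from connparc.metrics import KSelection, VICurve

LOG10_2 = np.log10(2)


def all_partitions(n):
    """Every set partition of range(n), as label vectors (Bell(5) = 52)."""
    if n == 1:
        return [[1]]
    out = []
    for smaller in all_partitions(n - 1):
        k = max(smaller)
        for lab in range(1, k + 2):
            out.append(smaller + [lab])
    return out


class TestEntropy:
    def test_degenerate_single_cluster(self):
        assert cp.entropy([1, 1, 1]) == 0.0

    def test_two_equal_clusters_base10(self):
        assert cp.entropy([1, 1, 2, 2]) == pytest.approx(LOG10_2, abs=1e-12)
        assert cp.entropy([1, 1, 2, 2]) == pytest.approx(0.3010, abs=1e-4)

    def test_sizes_1_1_2_hand_value(self):
        # -2*(1/4)log10(1/4) - (1/2)log10(1/2) = 0.4515
        assert cp.entropy([1, 2, 3, 3]) == pytest.approx(0.4515, abs=1e-4)

    def test_natural_log_base(self):
        assert cp.entropy([1, 2], log_base=np.e) == pytest.approx(np.log(2))


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        c = [1, 1, 2, 3, 3, 3]
        assert cp.mutual_information(c, c) == pytest.approx(cp.entropy(c), abs=1e-12)

    def test_independent_joint_is_zero(self):
        assert cp.mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_hand_tallied_three_cell_joint(self):
        assert cp.mutual_information([1, 1, 2, 2], [1, 2, 3, 3]) == pytest.approx(
            LOG10_2, abs=1e-12
        )

    def test_agrees_with_sklearn_natural_log(self, rng):
        for _ in range(20):
            a = rng.integers(1, 5, size=60)
            b = rng.integers(1, 4, size=60)
            assert cp.mutual_information(a, b, log_base=np.e) == pytest.approx(
                mutual_info_score(a, b), abs=1e-10
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            cp.mutual_information([1, 2], [1, 2, 3])


class TestVariationOfInformation:
    def test_identical_clusterings_zero(self):
        assert cp.variation_of_information([1, 1, 2, 2], [2, 2, 1, 1]) == 0.0

    def test_crossed_halves(self):
        assert cp.variation_of_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(
            2 * LOG10_2, abs=1e-12
        )

    def test_refinement_equals_entropy_difference(self):
        c, c2 = [1, 1, 2, 2], [1, 2, 3, 3]
        assert cp.variation_of_information(c, c2) == pytest.approx(
            cp.entropy(c2) - cp.entropy(c), abs=1e-12
        )
        assert cp.variation_of_information(c, c2) == pytest.approx(0.1505, abs=1e-4)

    def test_upper_bound_formula(self):
        assert cp.vi_upper_bound(93) == pytest.approx(np.log10(93), abs=1e-12)
        assert cp.vi_upper_bound(100, log_base=10) == pytest.approx(2.0)

    def test_bounds_on_random_partitions(self, rng):
        n = 93
        for _ in range(50):
            a = rng.integers(1, rng.integers(2, 10), size=n)
            b = rng.integers(1, rng.integers(2, 10), size=n)
            vi = cp.variation_of_information(a, b)
            ha, hb = cp.entropy(a), cp.entropy(b)
            mi = cp.mutual_information(a, b)
            assert 0.0 <= vi <= ha + hb + 1e-12
            assert vi <= cp.vi_upper_bound(n) + 1e-12
            assert -1e-12 <= mi <= min(ha, hb) + 1e-12

    def test_metric_axioms_on_partitions_of_four(self):
        parts = [np.array(p) for p in all_partitions(4)]
        d = np.array(
            [[cp.variation_of_information(a, b) for b in parts] for a in parts]
        )
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        # identity of indiscernibles: off-diagonal distances are positive
        off = d[~np.eye(len(parts), dtype=bool)]
        assert np.all(off > 1e-12)
        # triangle inequality over all triples
        assert np.all(d[:, :, None] + d[None, :, :] >= d[:, None, :] - 1e-12)


class TestSplitHalf:
    def test_identical_participants_give_zero_vi(self):
        # three well-separated row groups make the k-means optimum unique at
        # K=2 and K=3, so identical halves must agree exactly
        v = np.array([0.0] * 4 + [1.0] * 3 + [30.0] * 3)
        values = np.add.outer(v, v)
        prof = cp.CorrelationProfile(values=values, transform="fisher_z")
        curve = cp.split_half_vi([prof, prof], k_range=(2, 3),
                                 n_repetitions=4, n_replicates=20, rng_seed=1)
        assert np.all(curve.repetition_values == 0.0)

    def test_deterministic_given_seed(self, small_profiles):
        kwargs = dict(k_range=(2, 3, 4), n_repetitions=4, n_replicates=20,
                      rng_seed=42)
        a = cp.split_half_vi(small_profiles, **kwargs)
        b = cp.split_half_vi(small_profiles, **kwargs)
        assert np.array_equal(a.repetition_values, b.repetition_values)
        assert np.array_equal(a.p_values, b.p_values, equal_nan=True)

    def test_planted_k_is_dip_of_curve(self, small_profiles):
        curve = cp.split_half_vi(small_profiles, k_range=(2, 3, 4, 5),
                                 n_repetitions=10, n_replicates=50, rng_seed=7)
        k_idx = {k: j for j, k in enumerate(curve.k_values)}
        assert curve.mean[k_idx[4]] < curve.mean[k_idx[3]]
        assert curve.mean[k_idx[4]] < curve.mean[k_idx[5]]

    def test_too_few_participants_rejected(self, small_profiles):
        with pytest.raises(DomainError):
            cp.split_half_vi(small_profiles[:1], k_range=(2, 3))


def _curve(means, p_values):
    k_values = tuple(range(2, 2 + len(means)))
    means = np.asarray(means, dtype=float)
    return VICurve(
        k_values=k_values,
        repetition_values=np.tile(means, (5, 1)),
        mean=means,
        ci_low=means,
        ci_high=means,
        t_stats=np.where(np.isnan(p_values), np.nan, 1.0),
        p_values=np.asarray(p_values, dtype=float),
    )


class TestSelectOptimalK:
    def test_every_step_significant_flags_no_selection(self):
        curve = _curve([0.1, 0.2, 0.3, 0.4], [np.nan, 0.001, 0.001, 0.001])
        sel = cp.select_optimal_k(curve)
        assert sel == KSelection(k=5, no_selection=True)

    def test_significant_decrease_at_six(self):
        # VI rises significantly at K=3,4,5 and drops at K=6 -> optimal K = 6
        curve = _curve(
            [0.1, 0.2, 0.3, 0.46, 0.26, 0.5],
            [np.nan, 0.001, 0.004, 0.001, 0.9999, 0.001],
        )
        assert cp.select_optimal_k(curve) == KSelection(k=6)

    def test_first_eligible_k_wins(self):
        curve = _curve([0.3, 0.2, 0.4], [np.nan, 0.8, 0.001])
        assert cp.select_optimal_k(curve) == KSelection(k=3)

    def test_curve_must_start_at_two(self):
        curve = _curve([0.1, 0.2], [np.nan, 0.5])
        bad = VICurve(
            k_values=(3, 4), repetition_values=curve.repetition_values,
            mean=curve.mean, ci_low=curve.ci_low, ci_high=curve.ci_high,
            t_stats=curve.t_stats, p_values=curve.p_values,
        )
        with pytest.raises(DomainError):
            cp.select_optimal_k(bad)


class TestHierarchyIndex:
    def test_perfect_nesting(self):
        assert cp.hierarchy_index(["A", "A", "B", "B", "B"], [1, 1, 2, 2, 3]) == 1.0

    def test_k_mismatch_rejected(self):
        with pytest.raises(DomainError):
            cp.hierarchy_index(["A", "A", "B", "B", "B"], [1, 2, 1, 2, 2])

    def test_hand_tallied_two_thirds(self):
        parent = ["A", "A", "B", "B", "B", "B"]
        child = [1, 3, 1, 2, 2, 3]
        assert cp.hierarchy_index(parent, child) == pytest.approx(2 / 3, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        parent = rng.integers(1, 4, size=40)
        parent[:3] = [1, 2, 3]
        child = parent.copy()
        split = np.flatnonzero(child == 1)
        child[split[: len(split) // 2]] = 4
        hi = cp.hierarchy_index(parent, child)
        perm_p = np.array([0, 3, 1, 2])[parent]  # relabel parents
        perm_c = np.array([0, 2, 4, 1, 3])[child]  # relabel children
        assert cp.hierarchy_index(perm_p, perm_c) == pytest.approx(hi, abs=1e-12)

    def test_lower_bound(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            k = 4
            parent = np.tile(np.arange(1, k + 1), 10)
            child = np.tile(np.arange(1, k + 2), 8)
            r.shuffle(parent)
            r.shuffle(child)
            hi = cp.hierarchy_index(parent, child)
            assert 1.0 / k - 1e-12 <= hi <= 1.0


def _pair_of_masks(n, spacing=2.0):
    left = cp.synthetic_seed_mask(n, "left", spacing)
    right = cp.synthetic_seed_mask(n, "right", spacing)
    return left, right


class TestSymmetryIndex:
    def test_exact_mirror_is_one(self):
        left_mask, right_mask = _pair_of_masks(30)
        labels = np.tile([1, 2, 3], 10)
        pl = cp.Parcellation(labels=labels, k=3, inertia=0.0)
        res = cp.symmetry_index(pl, pl, left_mask, right_mask)
        assert res.proportion == 1.0
        assert res.overlap_domain_size == 30

    def test_uniform_contingency_gives_half(self):
        left_mask, right_mask = _pair_of_masks(12)
        left = np.array([1] * 6 + [2] * 6)
        right = np.array([1, 1, 1, 2, 2, 2] * 2)  # contingency [[3,3],[3,3]]
        res = cp.symmetry_index(
            cp.Parcellation(labels=left, k=2, inertia=0.0),
            cp.Parcellation(labels=right, k=2, inertia=0.0),
            left_mask, right_mask,
        )
        assert res.proportion == pytest.approx(0.5)

    def test_planted_full_symmetry(self):
        cfg = cp.SyntheticConfig(n_seed_voxels=40, k_true=4, symmetry_level=1.0,
                                 rng_seed=8)
        tl, tr = cp.simulate_hemisphere_pair(cfg)
        left_mask, right_mask = _pair_of_masks(40)
        res = cp.symmetry_index(
            cp.Parcellation(labels=tl.labels, k=4, inertia=0.0),
            cp.Parcellation(labels=tr.labels, k=4, inertia=0.0),
            left_mask, right_mask,
        )
        assert res.proportion == 1.0

    def test_disjoint_masks_rejected(self):
        left = SeedMask(voxels=np.array([[0, 0, 0]]), shape=(5, 5, 5),
                        affine=np.eye(4))
        far = np.eye(4)
        far[:3, 3] = 100.0
        right = SeedMask(voxels=np.array([[0, 0, 0]]), shape=(5, 5, 5),
                         affine=far, hemisphere="right")
        with pytest.raises(DomainError):
            cp.symmetry_index(
                cp.Parcellation(labels=np.array([1]), k=1, inertia=0.0),
                cp.Parcellation(labels=np.array([1]), k=1, inertia=0.0),
                left, right,
            )
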