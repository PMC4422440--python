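"""Cross-correlation profile construction: downsampling, Pearson, Fisher-Z,
group averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connparc as cp
from connparc.connectivity import ConnectivityMatrix, CorrelationProfile, TargetGrid
from connparc.errors import AlignmentError, GridError, ZeroVarianceError


def _grid(shape, cell_mm=2.0):
    return TargetGrid(shape=shape, affine=np.diag([cell_mm] * 3 + [1.0]),
                      cell_mm=cell_mm)


def _matrix(counts, shape=None, cell_mm=2.0):
    counts = np.asarray(counts)
    grid = _grid(shape, cell_mm) if shape is not None else None
    return ConnectivityMatrix(counts=counts, target_grid=grid)


class TestDownsample:
    def test_identity_block(self):
        m = _matrix(np.arange(16).reshape(2, 8), shape=(2, 2, 2))
        out = cp.downsample_targets(m, 2.0)
        assert np.array_equal(out.counts, m.counts)

    def test_row_sums_conserved(self, rng):
        counts = rng.integers(0, 50, size=(5, 3 * 4 * 5))
        m = _matrix(counts, shape=(3, 4, 5))
        out = cp.downsample_targets(m, 4.0)
        assert np.array_equal(out.counts.sum(axis=1), counts.sum(axis=1))

    def test_all_ones_4mm_blocks(self):
        # 4x4x4 grid at 2 mm, every count 1, downsampled to 4 mm:
        # 2x2x2 = 8 cells, each summing a 2x2x2 block of 8 voxels
        m = _matrix(np.ones((3, 64), dtype=int), shape=(4, 4, 4))
        out = cp.downsample_targets(m, 4.0)
        assert out.counts.shape == (3, 8)
        assert np.all(out.counts == 8)
        assert out.target_grid.shape == (2, 2, 2)

    def test_non_integer_ratio_rejected(self):
        m = _matrix(np.ones((2, 8), dtype=int), shape=(2, 2, 2))
        with pytest.raises(GridError):
            cp.downsample_targets(m, 3.0)
        with pytest.raises(GridError):
            cp.downsample_targets(m, -2.0)


class TestCrossCorrelate:
    def test_identical_rows_correlate_to_one(self):
        m = _matrix([[1, 2, 3], [1, 2, 3]])
        p = cp.cross_correlate(m)
        assert p.values[0, 1] == pytest.approx(1.0)
        assert p.transform == "raw_r"

    def test_reversed_rows_anticorrelate(self):
        p = cp.cross_correlate(_matrix([[1, 2, 3], [3, 2, 1]]))
        assert p.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r((1,2,4),(2,2,5)) = 5 / sqrt(28) = 0.9449
        p = cp.cross_correlate(_matrix([[1, 2, 4], [2, 2, 5]]))
        assert p.values[0, 1] == pytest.approx(5 / np.sqrt(28), abs=1e-9)
        assert p.values[0, 1] == pytest.approx(0.9449, abs=1e-4)

    def test_zero_variance_row_raises_with_indices(self):
        m = _matrix([[1, 2, 3], [4, 4, 4], [5, 5, 5]])
        with pytest.raises(ZeroVarianceError) as exc:
            cp.cross_correlate(m)
        assert exc.value.voxel_indices == [1, 2]

    def test_zero_variance_drop_mode(self):
        m = _matrix([[1, 2, 3], [4, 4, 4], [3, 1, 2]])
        p = cp.cross_correlate(m, zero_variance="drop")
        assert p.values.shape == (2, 2)

    def test_symmetric_unit_diagonal(self, rng):
        counts = rng.integers(0, 30, size=(10, 25))
        p = cp.cross_correlate(_matrix(counts))
        assert np.allclose(p.values, p.values.T)
        assert np.allclose(np.diag(p.values), 1.0)
        assert p.values.min() >= -1.0 and p.values.max() <= 1.0

    def test_invariant_to_row_affine_rescaling(self, rng):
        """Pearson correlation ignores per-row positive affine maps."""
        base = rng.integers(1, 40, size=(6, 20)).astype(float)
        p0 = cp.cross_correlate(ConnectivityMatrix(counts=base))
        scales = rng.integers(2, 5, size=6)[:, None]
        offsets = rng.integers(0, 10, size=6)[:, None]
        p1 = cp.cross_correlate(ConnectivityMatrix(counts=base * scales + offsets))
        assert np.allclose(p0.values, p1.values, atol=1e-10)

    def test_commutes_with_target_permutation(self, rng):
        counts = rng.integers(0, 30, size=(8, 24))
        perm = rng.permutation(24)
        p0 = cp.cross_correlate(ConnectivityMatrix(counts=counts))
        p1 = cp.cross_correlate(ConnectivityMatrix(counts=counts[:, perm]))
        assert np.allclose(p0.values, p1.values, atol=1e-12)


class TestFisherZ:
    def test_fixed_point_and_closed_form(self):
        vals = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        p = CorrelationProfile(values=vals, transform="raw_r")
        z = cp.fisher_z(p)
        assert z.transform == "fisher_z"
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert z.values[0, 2] == pytest.approx(0.5493, abs=1e-4)

    def test_clipping_keeps_perfect_correlation_finite(self):
        p = CorrelationProfile(values=np.array([[1.0, 1.0], [1.0, 1.0]]),
                               transform="raw_r")
        z = cp.fisher_z(p, clip_epsilon=1e-6)
        assert np.all(np.isfinite(z.values))
        assert z.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-6))

    def test_requires_raw_r(self):
        p = CorrelationProfile(values=np.zeros((2, 2)), transform="fisher_z")
        with pytest.raises(AlignmentError):
            cp.fisher_z(p)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-0.999, max_value=0.998))
    def test_strictly_increasing_and_odd(self, r):
        vals = lambda v: CorrelationProfile(
            values=np.array([[1.0, v], [v, 1.0]]), transform="raw_r"
        )
        z = cp.fisher_z(vals(r)).values[0, 1]
        z_next = cp.fisher_z(vals(r + 1e-3)).values[0, 1]
        z_neg = cp.fisher_z(vals(-r)).values[0, 1]
        assert z_next > z
        assert z_neg == pytest.approx(-z, abs=1e-12)


class TestAverageGroup:
    def _zprof(self, values):
        return CorrelationProfile(values=np.asarray(values, dtype=float),
                                  transform="fisher_z")

    def test_single_profile_unchanged(self):
        p = self._zprof([[5.0, 0.3], [0.3, 5.0]])
        out = cp.average_group([p])
        assert np.array_equal(out.values, p.values)
        assert out.n_averaged == 1

    def test_opposite_profiles_cancel(self):
        a = self._zprof([[5.0, 0.7], [0.7, 5.0]])
        b = self._zprof([[5.0, -0.7], [-0.7, 5.0]])
        out = cp.average_group([a, b])
        assert out.values[0, 1] == 0.0

    def test_arithmetic_mean(self):
        profs = [self._zprof([[1.0, v], [v, 1.0]]) for v in (0.1, 0.2, 0.6)]
        out = cp.average_group(profs)
        assert out.values[0, 1] == pytest.approx(0.3)
        assert out.n_averaged == 3

    def test_mixed_transforms_rejected(self):
        a = self._zprof([[1.0, 0.1], [0.1, 1.0]])
        b = CorrelationProfile(values=np.eye(2), transform="raw_r")
        with pytest.raises(AlignmentError):
            cp.average_group([a, b])

    def test_mismatched_seed_orderings_rejected(self):
        a = CorrelationProfile(values=np.eye(2), transform="fisher_z",
                               seed_index=np.array([[0, 0, 0], [1, 0, 0]]))
        b = CorrelationProfile(values=np.eye(2), transform="fisher_z",
                               seed_index=np.array([[1, 0, 0], [0, 0, 0]]))
        with pytest.raises(AlignmentError):
            cp.average_group([a, b])
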