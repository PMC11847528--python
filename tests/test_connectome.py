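"""Structural / functional connectivity construction and lesion rules."""

import numpy as np
import pytest

from dyspredict.connectome import (
    ConnMatrix,
    FcExclusionError,
    affected_parcels,
    endpoint_labels,
    group_fc,
    group_sc,
    lesioned_fc,
    relative_change_matrix,
    subject_fc,
    subject_sc,
)
from dyspredict.core import ParcellationAtlas, RoiTimeSeries, Tractogram
from dyspredict.disconnectome import ThresholdedMap
from dyspredict.synthetic import default_grid


@pytest.fixture(scope="module")
def atlas9():
    """3x3x1-ish block atlas on a 24^3 grid: 8 parcels in the lower octants."""
    grid = default_grid(24, 2.0)
    labels = np.zeros(grid.shape, dtype=np.int32)
    lab = 0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                lab += 1
                labels[i * 12 : (i + 1) * 12, j * 12 : (j + 1) * 12, k * 12 : (k + 1) * 12] = lab
    return ParcellationAtlas(grid, labels)


def _straight(a, b, n=10):
    t = np.linspace(0, 1, n)[:, None]
    return a + t * (np.asarray(b) - np.asarray(a))


class TestSubjectSc:
    def test_counted_pairs(self, atlas9):
        grid = atlas9.grid
        # parcel centres in world coordinates
        c3 = grid.index_to_world(np.array([[6.0, 18.0, 6.0]]))[0]  # label 3
        c7 = grid.index_to_world(np.array([[18.0, 18.0, 6.0]]))[0]  # label 7
        sls = [_straight(c3, c7) for _ in range(5)]
        t = Tractogram("s", sls)
        m = subject_sc(t, atlas9)
        assert m.weights[2, 6] == 5 and m.weights[6, 2] == 5
        assert m.weights.sum() == 10

    def test_background_endpoints_ignored(self, atlas9):
        grid = atlas9.grid
        out = grid.index_to_world(np.array([[1.0, 1.0, 20.0]]))[0]  # background z
        t = Tractogram("s", [_straight(out, out + 5)])
        assert subject_sc(t, atlas9).weights.sum() == 0

    def test_matches_endpoint_recount_oracle(self, atlas9):
        rng = np.random.default_rng(4)
        grid = atlas9.grid
        sls = [
            _straight(rng.uniform(-22, 22, 3), rng.uniform(-22, 22, 3), 6)
            for _ in range(300)
        ]
        t = Tractogram("s", sls)
        m = subject_sc(t, atlas9)
        expected = np.zeros_like(m.weights)
        for s in sls:
            ends = np.floor(grid.world_to_index(np.array([s[0], s[-1]]))).astype(int)
            labs = []
            for e in ends:
                if np.all(e >= 0) and np.all(e < np.array(grid.shape)):
                    labs.append(int(atlas9.labels[tuple(e)]))
                else:
                    labs.append(0)
            a, b = labs
            if a > 0 and b > 0 and a != b:
                expected[a - 1, b - 1] += 1
                expected[b - 1, a - 1] += 1
        np.testing.assert_array_equal(m.weights, expected)


class TestGroupSc:
    def _mat(self, w):
        return ConnMatrix(w, "SC", "subject")

    def test_identical_subjects(self):
        w = np.array([[0, 3.0], [3.0, 0]])
        g = group_sc([self._mat(w)] * 4)
        np.testing.assert_allclose(g.weights, w)

    def test_rare_edge_dropped(self):
        base = np.zeros((3, 3))
        rare = base.copy()
        rare[0, 1] = rare[1, 0] = 8.0
        g = group_sc([self._mat(rare)] + [self._mat(base)] * 3)
        assert g.weights[0, 1] == 0.0

    def test_prevalence_edge_kept_at_exact_half(self):
        """An edge present in exactly ceil(N/2) subjects passes at 0.5."""
        for n in (4, 5):
            k = -(-n // 2)  # ceil
            present = np.zeros((2, 2))
            present[0, 1] = present[1, 0] = 2.0
            mats = [self._mat(present)] * k + [self._mat(np.zeros((2, 2)))] * (n - k)
            g = group_sc(mats)
            assert g.weights[0, 1] == pytest.approx(2.0 * k / n)

    def test_matches_prevalence_mask_then_mean_oracle(self):
        rng = np.random.default_rng(1)
        mats = []
        for _ in range(10):
            w = np.triu(rng.integers(0, 3, (6, 6)).astype(float), 1)
            mats.append(self._mat(w + w.T))
        g = group_sc(mats)
        stack = np.stack([m.weights for m in mats])
        keep = (stack != 0).sum(0) >= 5
        expected = np.where(keep, stack.mean(0), 0.0)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(g.weights, expected)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            group_sc([self._mat(np.zeros((2, 2)))])


class TestSubjectFc:
    def test_copied_column_correlates_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (50, 3))
        x[:, 2] = x[:, 0]
        m = subject_fc(RoiTimeSeries("s", x + 0.0))
        assert m.weights[0, 2] == pytest.approx(1.0)
        assert m.weights[0, 0] == 0.0

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        m = subject_fc(RoiTimeSeries("s", np.column_stack([a, -a, rng.normal(0, 1, 40)])))
        assert m.weights[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (120, 5))
        m = subject_fc(RoiTimeSeries("s", x))
        for i in range(5):
            for j in range(i + 1, 5):
                xc, yc = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert m.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_names_parcel(self):
        x = np.random.default_rng(0).normal(0, 1, (30, 4))
        x[:, 2] = 5.0
        with pytest.raises(ValueError, match="3"):
            subject_fc(RoiTimeSeries("s", x))


class TestAffectedParcels:
    def _tsdm(self, atlas, voxels):
        data = np.zeros(atlas.grid.shape, dtype=bool)
        for v in voxels:
            data[v] = True
        return ThresholdedMap("p", atlas.grid, data, 0.1, 1)

    def test_nine_voxels_excluded_ten_included(self, atlas9):
        vox9 = [(0, 0, z) for z in range(9)]
        vox10 = [(0, 0, z) for z in range(10)]
        assert affected_parcels(self._tsdm(atlas9, vox9), atlas9).parcels == set()
        aff = affected_parcels(self._tsdm(atlas9, vox10), atlas9)
        assert aff.parcels == {1}
        assert aff.overlap_voxels[1] == 10

    def test_matches_voxel_count_oracle(self, atlas9):
        rng = np.random.default_rng(5)
        data = rng.random(atlas9.grid.shape) < 0.02
        tsdm = ThresholdedMap("p", atlas9.grid, data, 0.1, 1)
        aff = affected_parcels(tsdm, atlas9, min_overlap=10)
        for p in range(1, atlas9.n_parcels + 1):
            count = int(np.sum(data & (atlas9.labels == p)))
            assert (p in aff.parcels) == (count >= 10)


class TestLesionedFc:
    def _subject_fcs(self, n=4, P=6, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n):
            out.append(subject_fc(RoiTimeSeries(f"s{s}", rng.normal(0, 1, (60, P)))))
        return out

    def _aff(self, parcels, pid="p"):
        from dyspredict.connectome import AffectedParcelSet

        return AffectedParcelSet(pid, set(parcels), {p: 10 for p in parcels})

    def test_empty_affected_raises_exclusion(self):
        with pytest.raises(FcExclusionError):
            lesioned_fc(self._subject_fcs(), self._aff([]))

    def test_all_parcels_zero_matrix(self):
        fl = lesioned_fc(self._subject_fcs(), self._aff([1, 2, 3, 4, 5, 6]))
        assert not fl.weights.any()

    def test_unaffected_submatrix_equals_group_fc(self):
        fcs = self._subject_fcs(seed=3)
        fg = group_fc(fcs)
        fl = lesioned_fc(fcs, self._aff([2, 5]))
        keep = np.array([0, 2, 3])  # parcels 1, 3, 4 (0-based)
        np.testing.assert_allclose(
            fl.weights[np.ix_(keep, keep)], fg.weights[np.ix_(keep, keep)], atol=1e-15
        )
        assert not fl.weights[1, :].any() and not fl.weights[:, 4].any()


class TestRelativeChange:
    def test_identity_gives_zero(self):
        w = np.array([[0, 2.0], [2.0, 0]])
        a = ConnMatrix(w, "SC", "group")
        out = relative_change_matrix(ConnMatrix(w, "SC", "lesioned"), a)
        assert not out.weights.any()

    def test_halving_gives_minus_half(self):
        intact = ConnMatrix(np.array([[0, 10.0], [10.0, 0]]), "SC", "group")
        les = ConnMatrix(np.array([[0, 5.0], [5.0, 0]]), "SC", "lesioned")
        assert relative_change_matrix(les, intact).weights[0, 1] == pytest.approx(-0.5)

    def test_elementwise_oracle_including_zero_guard(self):
        rng = np.random.default_rng(6)
        P = 8
        wi = np.triu(rng.integers(0, 3, (P, P)).astype(float), 1)
        wi += wi.T
        wl = wi * np.triu(rng.random((P, P)), 1).round(1)
        wl = np.triu(wl, 1) + np.triu(wl, 1).T
        out = relative_change_matrix(
            ConnMatrix(wl, "SC", "lesioned"), ConnMatrix(wi, "SC", "group")
        )
        for i in range(P):
            for j in range(P):
                exp = 0.0 if wi[i, j] == 0 else (wl[i, j] - wi[i, j]) / wi[i, j]
                assert out.weights[i, j] == pytest.approx(exp)
        # streamline removal never adds fibers
        assert out.weights.max() <= 0.0 and out.weights.min() >= -1.0

    def test_modality_mismatch(self):
        a = ConnMatrix(np.zeros((3, 3)), "SC", "group")
        b = ConnMatrix(np.zeros((3, 3)), "FC", "lesioned")
        with pytest.raises(ValueError):
            relative_change_matrix(b, a)


def test_pipeline_sc_monotonicity_and_fc_locality(small_cfg, small_cohort, small_maps):
    """On a full synthetic case: lesioned SC weights never exceed intact ones,
    and FC_LD is nonzero only on affected parcels' rows/columns."""
    from dyspredict.pipeline import stage_functional, stage_structural

    raster, psdms, tsdms, _, _ = small_maps
    sc_g, sc_ld, sc_l = stage_structural(small_cfg, small_cohort, raster)
    for pid, gl in sc_l.items():
        assert np.all(gl.weights <= sc_g.weights + 1e-12)
        assert sc_ld[pid].weights.min() >= -1 - 1e-12
        assert sc_ld[pid].weights.max() <= 1e-12
    fc_g, fc_l, fc_ld, affected, excluded = stage_functional(
        small_cfg, small_cohort, tsdms
    )
    for pid, m in fc_ld.items():
        idx = np.array(sorted(affected[pid].parcels)) - 1
        off = np.ones(m.n_parcels, bool)
        off[idx] = False
        assert not m.weights[np.ix_(off, off)].any()
    assert excluded, "small-lesion patients should exercise the FC exclusion rule"
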