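"""Heat-map sweeps, matrix distances and group comparisons."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from flockphi.binarize import BinarizationParams, binarize
from flockphi.info import mutual_information, transfer_entropy_sum
from flockphi.phi import phi_over_series
from flockphi.sweeps import (
    HeatMap,
    baseline_adjusted_md,
    compare_groups,
    matrix_distance,
    sweep,
)
from flockphi.synth import BoidsParams, simulate_boids
from flockphi.tpm import estimate_tpm


@pytest.fixture(scope="module")
def school():
    return simulate_boids(BoidsParams(n=3, seed=7), steps=3000)


class TestSweep:
    def test_single_cell_equals_direct_pipeline(self, school):
        hm = sweep(school, measure="mi", zetas=(300,), visual_fields=(1.6 * math.pi,))
        params = BinarizationParams(zeta=300, visual_field=1.6 * math.pi, delta=0.0, dt=0.05)
        direct = mutual_information(binarize(school, params))
        assert hm.cells[0, 0] == pytest.approx(direct, abs=1e-12)

    def test_cells_match_independent_runs(self, school):
        zetas, vfs = (200, 600), (1.2 * math.pi, 2.0 * math.pi)
        hm = sweep(school, measure="te", zetas=zetas, visual_fields=vfs)
        for r, vf in enumerate(vfs):
            for c, z in enumerate(zetas):
                params = BinarizationParams(zeta=z, visual_field=vf, delta=0.0, dt=0.05)
                ref = transfer_entropy_sum(binarize(school, params))
                assert hm.cells[r, c] == pytest.approx(ref, abs=1e-12)

    def test_phi_sweep_single_cell(self, school):
        hm = sweep(school, measure="phi", zetas=(400,), visual_fields=(2.0 * math.pi,))
        params = BinarizationParams(zeta=400, visual_field=2.0 * math.pi, delta=0.0, dt=0.05)
        tpm = estimate_tpm(binarize(school, params))
        ref = phi_over_series(tpm).mean
        assert hm.cells[0, 0] == pytest.approx(ref, abs=1e-10)

    def test_csv_roundtrip(self, tmp_path, school):
        hm = sweep(school, measure="mi", zetas=(200, 500), visual_fields=(1.2 * math.pi, 2 * math.pi))
        hm.to_csv(tmp_path / "hm.csv")
        back = HeatMap.from_csv(tmp_path / "hm.csv")
        np.testing.assert_allclose(back.cells, hm.cells)
        assert back.meta["measure"] == "mi"


def _hm(cells, rows=(1.0, 2.0), cols=(10.0, 20.0)):
    return HeatMap(rows=rows, cols=cols, cells=np.asarray(cells, dtype=float))


class TestMatrixDistance:
    def test_identity(self):
        a = _hm([[1.0, 2.0], [3.0, 4.0]])
        assert matrix_distance(a, a) == 0.0

    def test_uniform_offset(self):
        a = _hm([[1.0, 2.0], [3.0, 4.0]])
        b = _hm(a.cells + 0.7)
        assert matrix_distance(a, b) == pytest.approx(0.7)

    def test_hand_computed(self):
        a = _hm([[1.0, 0.0], [0.0, 0.0]])
        b = _hm([[0.0, 0.0], [0.0, 2.0]])
        assert matrix_distance(a, b) == pytest.approx(math.sqrt(5.0 / 4.0))
        assert matrix_distance(a, b, kind="mean_abs") == pytest.approx(0.75)

    def test_grid_mismatch(self):
        a = _hm([[1.0, 2.0], [3.0, 4.0]])
        b = HeatMap(rows=(1.0, 3.0), cols=(10.0, 20.0), cells=a.cells)
        with pytest.raises(ValueError):
            matrix_distance(a, b)


class TestBaselineAdjustedMD:
    def test_identical_maps_give_zero(self):
        m = _hm([[1.0, 2.0], [3.0, 4.0]])
        groups = {2: [m, m], 3: [m, m]}
        out = baseline_adjusted_md(groups)
        assert out[(2, 3)] == pytest.approx(0.0)

    def test_offset_between_groups(self):
        a = _hm([[1.0, 1.0], [1.0, 1.0]])
        b = _hm(a.cells + 2.0)
        out = baseline_adjusted_md({2: [a, a], 3: [b, b]})
        # intra distances all 0, inter all 2 -> adjusted = 2
        assert out[(2, 3)] == pytest.approx(2.0)

    def test_can_be_negative(self):
        a = _hm([[0.0, 0.0], [0.0, 0.0]])
        b = _hm([[4.0, 4.0], [4.0, 4.0]])
        # both groups span the same two maps: intra baseline 4, inter mean 2
        out = baseline_adjusted_md({2: [a, b], 3: [a, b]})
        assert out[(2, 3)] == pytest.approx(-2.0)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(3)
        g1 = [_hm(rng.random((2, 2))) for _ in range(3)]
        g2 = [_hm(rng.random((2, 2))) for _ in range(3)]
        d12 = baseline_adjusted_md({2: g1, 3: g2})[(2, 3)]
        d21 = baseline_adjusted_md({2: g2, 3: g1})[(2, 3)]
        assert d12 == pytest.approx(d21)


class TestCompareGroups:
    def test_identical_samples_welch(self):
        x = [1.0, 2.0, 3.0, 4.0]
        stat, p = compare_groups(x, list(x), test="welch_t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_normals(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(5, 1, 50)
        _, p = compare_groups(x, y, test="welch_t")
        assert p < 1e-10
        _, p = compare_groups(x, y, test="mann_whitney_u")
        assert p < 1e-10

    def test_welch_matches_second_implementation(self):
        x = [2.1, 3.5, 2.8, 4.0, 3.3]
        y = [1.0, 1.8, 2.2, 1.4]
        stat, p = compare_groups(x, y, test="welch_t")
        from statsmodels.stats.weightstats import ttest_ind

        stat2, p2, _ = ttest_ind(x, y, usevar="unequal")
        assert stat == pytest.approx(stat2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    def test_wilcoxon_requires_pairs(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0], test="wilcoxon_signed")

    def test_wilcoxon_matches_scipy_directly(self, rng):
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0.5, 0.5, 20)
        stat, p = compare_groups(x, y, test="wilcoxon_signed")
        ref = sps.wilcoxon(x, y)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
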