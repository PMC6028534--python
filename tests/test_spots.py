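"""Spot detection, DBSCAN clustering, multiplicity and spacing statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from condensinmap import spots as sp, synthetic_data as syn
from condensinmap.axis import ChromatidAxis
from condensinmap.stack import ImageStack

STED_VOX = (140.0, 20.0, 20.0)


def _spot_table(positions, intensities):
    positions = np.atleast_2d(positions)
    return pd.DataFrame(
        {
            "z_nm": positions[:, 0],
            "y_nm": positions[:, 1],
            "x_nm": positions[:, 2],
            "intensity": intensities,
            "sigma_nm": 30.0,
        }
    )


def _straight_axis_obj(length_nm, step=20.0):
    pts = syn.straight_axis(length_nm, step_nm=step)
    tans = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return ChromatidAxis(points=pts, tangents=tans, spacing_nm=step)


class TestDetection:
    def test_noise_only_false_positive_budget(self):
        """Pure noise at k=3: at most one detection per megapixel."""
        n_px = 0
        n_det = 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            stack = ImageStack(rng.normal(100.0, 5.0, (2, 512, 512)), STED_VOX)
            n_det += len(sp.detect_spots(stack))
            n_px += 2 * 512 * 512
        assert n_det <= n_px / 1e6

    def test_single_spot_localized_within_10nm(self):
        img = syn._render_gaussians(
            (3, 64, 64), STED_VOX, np.array([[140.0, 500.0, 1000.0]]),
            np.array([3000.0]), (250.0, 30.0, 30.0),
        )
        rng = np.random.default_rng(1)
        stack = ImageStack(img + rng.normal(0, 2.0, img.shape), STED_VOX)
        table = sp.detect_spots(stack)
        mid = table[table.z_nm == 140.0]
        assert len(mid) == 1
        assert mid.y_nm.iloc[0] == pytest.approx(500.0, abs=10.0)
        assert mid.x_nm.iloc[0] == pytest.approx(1000.0, abs=10.0)

    def test_resolved_pair_gives_two_detections(self):
        img = syn._render_gaussians(
            (1, 64, 96), (140.0, 20.0, 20.0),
            np.array([[0.0, 500.0, 600.0], [0.0, 500.0, 1000.0]]),
            np.array([3000.0, 3000.0]), (250.0, 30.0, 30.0),
        )
        rng = np.random.default_rng(2)
        stack = ImageStack(img + rng.normal(0, 2.0, img.shape), STED_VOX)
        table = sp.detect_spots(stack)
        assert len(table) == 2


class TestClustering:
    def test_two_close_detections_merge(self):
        tab = _spot_table([[0, 0, 0], [0, 0, 10.0]], [100.0, 100.0])
        cl = sp.cluster_spots(tab)
        assert len(cl) == 1
        assert cl.member_count.iloc[0] == 2

    def test_two_far_detections_stay_singletons(self):
        tab = _spot_table([[0, 0, 0], [0, 0, 100.0]], [100.0, 100.0])
        cl = sp.cluster_spots(tab)
        assert len(cl) == 2
        assert (cl.member_count == 1).all()

    def test_z_scaling_merges_across_slices(self):
        # 140-nm z gap scales to 17.5 < eps, so same-complex detections
        # on adjacent slices join one cluster
        tab = _spot_table([[0, 0, 0], [140.0, 0, 0]], [100.0, 100.0])
        assert len(sp.cluster_spots(tab)) == 1
        assert len(sp.cluster_spots(tab, z_scale=1.0)) == 2

    def test_multiplicity_corrected_count_recovery(self):
        """56-nm truth spacing, 10-nm detection jitter: the corrected
        complex count stays within 5% of truth even where neighbouring
        detections merge."""
        _, truth = syn.gen_sted_chromatid(syn.straight_axis(8000.0), 56.0, seed=5)
        rng = np.random.default_rng(11)
        pos = truth.spot_positions + rng.normal(0, 10.0, truth.spot_positions.shape)
        tab = _spot_table(pos, truth.spot_multiplicities * 3000.0)
        cl = sp.correct_multiplicity(sp.cluster_spots(tab))
        assert cl.multiplicity.sum() == pytest.approx(len(truth.spot_positions), rel=0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 2000.0, (40, 3))
        tab = _spot_table(pos, np.full(40, 500.0))
        cl1 = sp.cluster_spots(tab)
        cl2 = sp.cluster_spots(tab.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(
            cl1.drop(columns="cluster_id"), cl2.drop(columns="cluster_id")
        )

    def test_empty_table(self):
        assert sp.cluster_spots(_spot_table(np.empty((0, 3)), [])).empty

    def test_eps_unit_pixels_option(self):
        tab = _spot_table([[0, 0, 0], [0, 0, 600.0]], [100.0, 100.0])
        assert len(sp.cluster_spots(tab, unit="px")) == 1  # 45 px = 900 nm
        assert len(sp.cluster_spots(tab, unit="nm")) == 2


class TestMultiplicity:
    @pytest.mark.parametrize(
        "intensity, expected", [(2999.0, 1), (3001.0, 2), (6500.0, 3)]
    )
    def test_threshold_rule(self, intensity, expected):
        cl = sp.cluster_spots(_spot_table([[0, 0, 0]], [intensity]))
        out = sp.correct_multiplicity(cl)
        assert out.multiplicity.iloc[0] == expected

    def test_nonpositive_unit_rejected(self):
        cl = sp.cluster_spots(_spot_table([[0, 0, 0]], [100.0]))
        with pytest.raises(ValueError):
            sp.correct_multiplicity(cl, intensity_unit=0.0)

    @given(unit_a=st.floats(500, 5000), unit_b=st.floats(500, 5000))
    @settings(max_examples=25, deadline=None)
    def test_total_multiplicity_monotone_in_unit(self, unit_a, unit_b):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 5000.0, (30, 3))
        cl = sp.cluster_spots(_spot_table(pos, rng.uniform(100, 10000, 30)))
        lo, hi = sorted([unit_a, unit_b])
        assert (
            sp.correct_multiplicity(cl, hi).multiplicity.sum()
            <= sp.correct_multiplicity(cl, lo).multiplicity.sum()
        )


class TestSpacingStats:
    def test_equidistant_on_axis(self):
        pos = np.array([[0.0, 0.0, 50.0 * i] for i in range(20)])
        cl = sp.correct_multiplicity(sp.cluster_spots(_spot_table(pos, np.full(20, 100.0))))
        st_ = sp.spacing_stats(cl, _straight_axis_obj(1000.0))
        assert st_.median_as_nm == pytest.approx(50.0, abs=1e-6)
        assert np.allclose(st_.axis_distances_nm, 0.0, atol=1e-6)

    def test_detected_density_at_60pct_efficiency(self):
        """28 complexes per µm thinned at 60% detection: ~16-17 observed
        clusters per µm, the detected-density regime."""
        _, truth = syn.gen_sted_chromatid(
            syn.straight_axis(10000.0), 1000.0 / 28.0,
            detection_efficiency=0.6, seed=8,
        )
        tab = _spot_table(truth.spot_positions, np.full(len(truth.spot_positions), 3000.0))
        cl = sp.correct_multiplicity(sp.cluster_spots(tab))
        st_ = sp.spacing_stats(cl, _straight_axis_obj(10000.0))
        assert 15.0 <= st_.clusters_per_um_axis <= 18.5

    def test_poisson_placements_give_exponential_spacings(self):
        """Uniform 1D placements at density lambda: axial spacings match
        Exponential(lambda) by a KS test at alpha = 0.01."""
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 20000.0, 300))
        pos = np.column_stack([np.zeros(300), np.zeros(300), x])
        cl = pd.DataFrame(
            {
                "cluster_id": range(300),
                "z_nm": 0.0, "y_nm": 0.0, "x_nm": x,
                "total_intensity": 1000.0, "multiplicity": 1, "member_count": 1,
            }
        )
        st_ = sp.spacing_stats(cl, _straight_axis_obj(20000.0))
        res = stats.kstest(st_.axial_spacings_nm, "expon", args=(0, 20000.0 / 300))
        assert res.pvalue > 0.01

    def test_fewer_than_two_clusters_errors(self):
        cl = sp.correct_multiplicity(sp.cluster_spots(_spot_table([[0, 0, 0]], [100.0])))
        with pytest.raises(ValueError):
            sp.spacing_stats(cl, _straight_axis_obj(1000.0))


class TestEndToEndRecovery:
    def _as_median(self, efficiency, seed):
        _, truth = syn.gen_sted_chromatid(
            syn.straight_axis(8000.0), 56.0, detection_efficiency=efficiency, seed=seed
        )
        rng = np.random.default_rng(500 + seed)
        pos = truth.spot_positions + rng.normal(0, 5.0, truth.spot_positions.shape)
        tab = _spot_table(pos, truth.spot_multiplicities * 3000.0)
        cl = sp.correct_multiplicity(sp.cluster_spots(tab))
        axis = ChromatidAxis(
            points=truth.axis_points,
            tangents=np.tile([0.0, 0.0, 1.0], (len(truth.axis_points), 1)),
            spacing_nm=10.0,
        )
        return sp.spacing_stats(cl, axis).median_as_nm

    def test_full_efficiency_recovers_56nm(self):
        assert self._as_median(1.0, seed=1) == pytest.approx(56.0, rel=0.1)

    def test_thinning_inflates_axial_spacing(self):
        """60% detection thins the point process geometrically, so the
        observed median spacing grows beyond the truth spacing."""
        full = self._as_median(1.0, seed=2)
        thinned = self._as_median(0.6, seed=2)
        assert thinned > full * 1.2
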