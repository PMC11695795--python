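"""CT pore-space analysis: segmentation, imprint isolation, radial profiles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from circumpen import ct
from circumpen.ct import (
    ImprintResult,
    VoxelVolume,
    compactness,
    cylinder_mask,
    exclude_rim,
    fit_compaction_decay,
    isolate_imprint,
    label_pores,
    pore_metrics,
    radial_porosity_profile,
    region_masks,
    segment_pores,
    structural_estimates,
)
from circumpen.synthetic import GeneratorConfig, PhantomConfig, gen_ct_phantom, phantom_truth_mask

from conftest import flood_fill_components, partition_sets


class TestSegmentation:
    def test_bimodal_phantom_recovered_exactly(self):
        rng = np.random.default_rng(0)
        truth = rng.random((20, 30, 30)) < 0.2
        grey = np.where(truth, 60, 180).astype(np.uint8)
        vol = VoxelVolume(grey, 24.0)
        seg = segment_pores(vol, 120.0)
        dom = vol.domain()
        assert (seg.values[dom] == truth[dom]).all()

    def test_degenerate_thresholds_warn(self):
        vol = VoxelVolume(np.full((5, 10, 10), 100, dtype=np.uint8), 24.0)
        with pytest.warns(UserWarning):
            all_pore = segment_pores(vol, 255.0)
        assert all_pore.values.all()
        with pytest.warns(UserWarning):
            all_matrix = segment_pores(vol, 0.0)
        assert not all_matrix.values.any()


class TestRimExclusion:
    def test_zero_rim_is_identity(self):
        vol = VoxelVolume(np.ones((4, 40, 40), dtype=np.uint8), 24.0)
        assert exclude_rim(vol, 0.0).domain().sum() == vol.domain().sum()

    @pytest.mark.parametrize("edge_um,expected_vox", [(12.0, 50), (24.0, 25)])
    def test_rim_voxel_conversion(self, edge_um, expected_vox):
        n = 130
        vol = VoxelVolume(np.ones((2, n, n), dtype=np.uint8), edge_um)
        shrunk = exclude_rim(vol, 0.6)
        base_radius = n / 2.0 - 0.5
        expected = cylinder_mask((2, n, n), base_radius - expected_vox).sum()
        assert shrunk.domain().sum() == expected

    def test_rim_larger_than_radius_rejected(self):
        vol = VoxelVolume(np.ones((2, 20, 20), dtype=np.uint8), 24.0)
        with pytest.raises(ValueError, match="rim"):
            exclude_rim(vol, 1.0)


class TestLabelling:
    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 21, size=3))
        binary = rng.random(shape) < rng.uniform(0.2, 0.7)
        labels, _ = label_pores(binary, connectivity)
        oracle = flood_fill_components(binary, connectivity)
        assert partition_sets(labels) == partition_sets(oracle)

    def test_diagonal_touch_distinguishes_connectivities(self):
        binary = np.zeros((3, 3, 3), dtype=bool)
        binary[0, 0, 0] = binary[1, 1, 1] = True
        assert label_pores(binary, 26)[1] == 1
        assert label_pores(binary, 6)[1] == 2


def _ball(shape, centre, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    ) <= radius**2


class TestPoreMetrics:
    def test_zero_pores(self):
        region = np.ones((10, 10, 10), dtype=bool)
        out = pore_metrics(np.zeros_like(region), region, 24.0)
        assert out["visible_porosity"] == 0.0
        assert np.isnan(out["mean_pore_diameter_um"])

    def test_sphere_equivalent_diameter(self):
        shape = (30, 30, 30)
        pores = _ball(shape, (15, 15, 15), 10.0)
        region = np.ones(shape, dtype=bool)
        out = pore_metrics(pores, region, 12.0)
        assert out["mean_pore_diameter_um"] == pytest.approx(20 * 12.0, rel=0.05)

    def test_constructed_porosity_exact(self):
        rng = np.random.default_rng(1)
        region = np.ones((20, 20, 20), dtype=bool)
        pores = rng.random(region.shape) < 0.17
        out = pore_metrics(pores, region, 24.0)
        assert out["visible_porosity"] == pores.mean()

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            pore_metrics(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool), 12.0)


class TestCompactness:
    @pytest.mark.parametrize(
        "eps,ref,expected", [(0.17, 0.17, 0.0), (0.45 * 0.17, 0.17, 0.55), (0.0, 0.17, 1.0)]
    )
    def test_relative_change(self, eps, ref, expected):
        assert compactness(eps, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compactness(0.1, 0.0)


class TestStructuralEstimates:
    def test_no_change_recovers_packing_density(self):
        est = structural_estimates(0.17, 0.17, rho_b=1.4, rho_p=2.56)
        assert est.eps == pytest.approx(0.453125)
        assert est.eps_prime[0] == pytest.approx(est.eps)
        assert est.rho_b_prime[0] == pytest.approx(1.4, abs=1e-12)

    def test_printed_porosity_drop_gives_17pct_density_increase(self):
        eps = 1.0 - 1.4 / 2.56
        est = structural_estimates(0.17 - 0.21 * eps, 0.17)
        assert est.rho_b_prime[0] == pytest.approx(1.644, abs=0.002)
        increase = 100.0 * (est.rho_b_prime[0] - 1.4) / 1.4
        assert increase == pytest.approx(17.4, abs=0.1)

    def test_full_collapse_limit(self):
        eps = 1.0 - 1.4 / 2.56
        est = structural_estimates(0.17 - eps, 0.17)
        assert est.eps_prime[0] == pytest.approx(0.0, abs=1e-12)
        assert est.rho_b_prime[0] == pytest.approx(2.56)

    def test_identity_density_porosity_every_bin(self):
        rng = np.random.default_rng(3)
        eps_vis = rng.uniform(0.05, 0.17, size=40)
        est = structural_estimates(eps_vis, 0.17)
        assert np.allclose(est.rho_b_prime, (1 - est.eps_prime) * est.rho_p, rtol=1e-15)

    def test_impossible_porosity_rejected(self):
        with pytest.raises(ValueError):
            structural_estimates(0.0, 0.9)


class TestImprintIsolation:
    def test_pure_cone_void_is_entire_pore_space(self):
        cfg = GeneratorConfig(
            seed=5,
            phantom=PhantomConfig(
                diameter_mm=3.0, height_mm=4.0, background_porosity=1e-6
            ),
        )
        _, binary, _ = gen_ct_phantom(cfg)
        vol = exclude_rim(binary, 0.12)
        result = isolate_imprint(vol)
        total = vol.binary().sum()
        assert result.imprint_mask.sum() >= 0.97 * total
        assert result.residual_pores.sum() <= 0.03 * total

    def test_thin_neck_severed(self):
        shape = (40, 80, 40)
        big = _ball(shape, (20, 25, 20), 12.0)
        small = _ball(shape, (20, 48, 20), 8.0)
        neck = np.zeros(shape, dtype=bool)
        neck[19:22, 25:49, 19:22] = True  # 3x3 bridge
        binary = big | small | neck
        vol = VoxelVolume(binary, 24.0, domain_mask=np.ones(shape, dtype=bool))
        result = isolate_imprint(vol)
        # the big blob is kept, the small blob lands in the residual
        assert result.imprint_mask[20, 25, 20]
        assert not result.imprint_mask[20, 48, 20]
        assert result.residual_pores[20, 48, 20]

    def test_masks_partition_pore_space(self, small_phantom):
        vol = small_phantom["vol"]
        result = isolate_imprint(vol)
        binary = vol.binary()
        assert not (result.imprint_mask & result.residual_pores).any()
        assert ((result.imprint_mask | result.residual_pores) == binary).all()

    def test_empty_volume_rejected(self):
        vol = VoxelVolume(np.zeros((10, 20, 20), dtype=np.uint8), 24.0)
        with pytest.raises(ValueError, match="empty"):
            isolate_imprint(vol)

    def test_small_phantom_recovery(self, small_phantom):
        vol = small_phantom["vol"]
        truth_mask = phantom_truth_mask(small_phantom["config"])
        result = isolate_imprint(vol)
        true_vol = small_phantom["truth"]["cone_volume_mm3"]
        assert result.imprint_volume_mm3 == pytest.approx(true_vol, rel=0.10)
        inter = (result.imprint_mask & truth_mask).sum()
        union = (result.imprint_mask | truth_mask).sum()
        assert inter / union >= 0.9


class TestRegions:
    def test_region_volumes_hit_scaled_targets(self, default_phantom_run):
        vol = default_phantom_run["vol"]
        truth_mask = default_phantom_run["cone"]
        res = vol.binary() & ~truth_mask
        imp = ImprintResult(truth_mask, truth_mask.sum() * vol.voxel_volume_mm3, res)
        regions = region_masks(imp, vol)
        dom_mm3 = vol.domain().sum() * vol.voxel_volume_mm3
        scale = dom_mm3 / ct.REFERENCE_DOMAIN_MM3
        vv = vol.voxel_volume_mm3
        layer_mm3 = vol.domain()[0].sum() * vv  # one full voxel layer
        below = regions["below_tip"].sum() * vv
        around = regions["around"].sum() * vv
        assert below == pytest.approx(1000.0 * scale, abs=layer_mm3)
        assert around == pytest.approx(2000.0 * scale, abs=vv * 2)
        assert not (regions["below_tip"] & regions["around"]).any()
        assert not (regions["below_tip"] & truth_mask).any()

    def test_imprint_at_bottom_rejected(self):
        shape = (20, 60, 60)
        mask = np.zeros(shape, dtype=bool)
        mask[-3:, 28:32, 28:32] = True
        vol = VoxelVolume(mask.astype(np.uint8), 24.0)
        imp = ImprintResult(mask, 1.0, np.zeros(shape, dtype=bool))
        with pytest.raises(ValueError, match="exceeds the domain"):
            region_masks(imp, vol)


class TestRadialProfile:
    def test_far_shells_at_background_porosity(self):
        rng = np.random.default_rng(4)
        shape = (60, 60, 60)
        imprint = _ball(shape, (30, 30, 30), 6.0)
        pores = (rng.random(shape) < 0.17) & ~imprint
        vol = VoxelVolume(
            (pores | imprint).astype(np.uint8), 24.0, np.ones(shape, dtype=bool)
        )
        imp = ImprintResult(imprint, 0.0, pores)
        prof = radial_porosity_profile(imp, vol, 0.5)
        assert prof.eps_vis[-1] == pytest.approx(0.17, abs=0.01)

    def test_zero_distance_empty_profile(self, small_phantom):
        vol = small_phantom["vol"]
        mask = phantom_truth_mask(small_phantom["config"])
        imp = ImprintResult(mask, 1.0, vol.binary() & ~mask)
        prof = radial_porosity_profile(imp, vol, 0.0)
        assert prof.eps_vis.size == 0

    def test_compaction_profile_non_decreasing(self, small_phantom):
        vol = small_phantom["vol"]
        mask = phantom_truth_mask(small_phantom["config"])
        imp = ImprintResult(mask, 1.0, vol.binary() & ~mask)
        prof = radial_porosity_profile(imp, vol, 1.2)
        # smoothed monotone rise from the compaction halo
        smooth = np.convolve(prof.eps_vis, np.ones(3) / 3, mode="valid")
        assert (np.diff(smooth) > -0.01).all()

    def test_truncation_warns_beyond_domain(self, small_phantom):
        vol = small_phantom["vol"]
        mask = phantom_truth_mask(small_phantom["config"])
        imp = ImprintResult(mask, 1.0, vol.binary() & ~mask)
        with pytest.warns(UserWarning, match="truncated"):
            radial_porosity_profile(imp, vol, 30.0)

    def test_resolution_convergence_12_vs_24_um(self):
        profiles = {}
        for edge in (24.0, 12.0):
            cfg = GeneratorConfig(
                seed=21,
                phantom=PhantomConfig(
                    diameter_mm=3.0,
                    height_mm=3.0,
                    voxel_edge_um=edge,
                    halo_decay_mm=0.4,
                ),
            )
            _, binary, _ = gen_ct_phantom(cfg)
            vol = exclude_rim(binary, 0.12)
            mask = phantom_truth_mask(cfg)
            imp = ImprintResult(mask, 1.0, vol.binary() & ~mask)
            step = 5 if edge == 24.0 else 10  # same 120 um physical shells
            prof = radial_porosity_profile(imp, vol, 0.96, step_voxels=step)
            profiles[edge] = prof.eps_vis
        n = min(len(profiles[12.0]), len(profiles[24.0]))
        assert np.allclose(profiles[12.0][:n], profiles[24.0][:n], atol=0.02)


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        d = np.linspace(0.06, 2.4, 20)
        a, lam = fit_compaction_decay(d, 0.55 * np.exp(-d / 0.6))
        assert a == pytest.approx(0.55, rel=1e-6)
        assert lam == pytest.approx(0.6, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_compaction_decay(np.array([0.1, 0.2]), np.array([0.5, 0.4]))
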