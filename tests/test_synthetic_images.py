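"""Generators for fibril masks, cell populations and rendered channels."""

import numpy as np
import pytest

from fibrilcyte import (
    CellPopulationModel,
    FibrilArraySpec,
    ImagingModel,
    generate_fibril_mask,
    render_channels,
    sample_alignment_angles,
    sample_cells,
)
from fibrilcyte.cells import PackingError
from fibrilcyte.fibril import DegenerateGeometryError

UNIFORM_AXIAL_STD = 180.0 / np.sqrt(12.0)


class TestFibrilMask:
    def test_stripe_pitch_matches_unit_conversion(self):
        # 40 um pitch at 0.51 um/px -> ~78.4 px between stripe centers
        spec = FibrilArraySpec(spacing=40.0, pixel_size=0.51,
                               field_width=500, field_height=500)
        assert spec.pitch_px == pytest.approx(40.0 / 0.51)
        mask = generate_fibril_mask(spec)
        # stripe centers along a column: distance between runs of True
        col = mask[:, 0]
        centers = []
        in_run = False
        for i, v in enumerate(col):
            if v and not in_run:
                start, in_run = i, True
            elif not v and in_run:
                centers.append((start + i - 1) / 2)
                in_run = False
        gaps = np.diff(centers)
        assert np.allclose(gaps, spec.pitch_px, atol=1.0)

    def test_line_density_20_per_mm_at_50um_spacing(self):
        # 50 um spacing <-> 20 stripes across a 1 mm transect perpendicular
        # to the fibril axis (axis 0 deg: stripes run along x)
        spec = FibrilArraySpec(spacing=50.0, fibril_width=5.0,
                               field_width=40, field_height=1000,
                               pixel_size=0.51)
        mask = generate_fibril_mask(spec)
        col = mask[:, 0].astype(int)
        n_stripes = int(np.sum(np.diff(col) == 1) + col[0])
        assert n_stripes == 20

    def test_wide_fibril_fills_almost_all(self):
        spec = FibrilArraySpec(spacing=40.0, fibril_width=39.9,
                               field_width=200, field_height=200)
        mask = generate_fibril_mask(spec)
        assert mask.mean() > 0.97

    def test_angled_mask_invariant_along_axis(self):
        # moving along the fibril axis never leaves a stripe; moving
        # perpendicular by half a pitch always does
        spec = FibrilArraySpec(axis_angle=30.0, field_width=300,
                               field_height=300, fibril_width=8.0)
        mask = generate_fibril_mask(spec)
        a = np.deg2rad(30.0)
        ys, xs = np.nonzero(mask)
        sel = slice(0, len(xs), 97)
        for step_um in (5.0, 15.0):
            dx = step_um * np.cos(a) / spec.pixel_size
            dy = step_um * np.sin(a) / spec.pixel_size
            xi = np.round(xs[sel] + dx).astype(int)
            yi = np.round(ys[sel] + dy).astype(int)
            ok = (xi >= 0) & (xi < mask.shape[1]) & (yi >= 0) & (yi < mask.shape[0])
            assert mask[yi[ok], xi[ok]].mean() > 0.95
        # perpendicular displacement by half a pitch leaves the stripes
        dpx = spec.spacing / 2 * -np.sin(a) / spec.pixel_size
        dpy = spec.spacing / 2 * np.cos(a) / spec.pixel_size
        xi = np.round(xs[sel] + dpx).astype(int)
        yi = np.round(ys[sel] + dpy).astype(int)
        ok = (xi >= 0) & (xi < mask.shape[1]) & (yi >= 0) & (yi < mask.shape[0])
        assert mask[yi[ok], xi[ok]].mean() < 0.05

    def test_sub_pixel_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            generate_fibril_mask(FibrilArraySpec(spacing=40.0, fibril_width=0.4,
                                                 pixel_size=0.51))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FibrilArraySpec(spacing=-1)
        with pytest.raises(ValueError):
            FibrilArraySpec(fibril_width=50.0, spacing=40.0)

    def test_mask_deterministic(self, small_spec):
        assert np.array_equal(generate_fibril_mask(small_spec),
                              generate_fibril_mask(small_spec))


class TestAlignmentSampling:
    def test_uniform_axial_moments(self):
        # closed form: uniform on (-90, 90] has mean 0, std 180/sqrt(12)
        ang = sample_alignment_angles(0.0, 10**6, seed=5)
        se = UNIFORM_AXIAL_STD / 1000.0
        assert abs(ang.mean()) < 3 * se
        assert ang.std() == pytest.approx(UNIFORM_AXIAL_STD, abs=0.15)
        assert ang.min() > -90.0 and ang.max() <= 90.0

    def test_infinite_concentration_degenerates_to_axis(self, small_spec):
        model = CellPopulationModel(orientation_kappa=1e9)
        _, truth = sample_cells(small_spec, model, dose=0.0, seed=1)
        assert np.allclose(truth["alignment_deg"], 0.0, atol=0.01)

    def test_concentration_reduces_spread(self):
        spreads = [sample_alignment_angles(k, 20000, seed=2).std()
                   for k in (0.0, 2.0, 8.0)]
        assert spreads[0] > spreads[1] > spreads[2]


class TestSampleCells:
    def test_cell_count_poisson_around_density(self, small_spec):
        model = CellPopulationModel()
        lam = model.density * (small_spec.field_width *
                               small_spec.field_height) / 1e6
        counts = [len(sample_cells(small_spec, model, seed=s)[1])
                  for s in range(20)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 20)

    def test_truth_labels_all_in_table(self, small_spec, aligned_model):
        labels, truth = sample_cells(small_spec, aligned_model, seed=3)
        present = set(np.unique(labels)) - {0}
        assert present <= set(truth["label"])

    def test_determinism(self, small_spec, aligned_model):
        l1, t1 = sample_cells(small_spec, aligned_model, dose=5.0, seed=9)
        l2, t2 = sample_cells(small_spec, aligned_model, dose=5.0, seed=9)
        assert np.array_equal(l1, l2)
        assert t1.equals(t2)

    def test_dose_only_rescales_protrusions(self, small_spec, aligned_model):
        # common random numbers: geometry identical across doses
        _, t0 = sample_cells(small_spec, aligned_model, dose=0.0, seed=4)
        _, t1 = sample_cells(small_spec, aligned_model, dose=25.0, seed=4)
        assert np.allclose(t0["x_um"], t1["x_um"])
        assert np.allclose(t0["orientation_deg"], t1["orientation_deg"])
        grew = t0["n_protrusions"] > 0
        assert (t1.loc[grew, "protrusion_total_um"]
                > t0.loc[grew, "protrusion_total_um"]).all()

    def test_protrusion_scale_monotone_in_dose(self):
        model = CellPopulationModel()
        doses = [0.0, 0.5, 2.5, 5.0, 25.0, 50.0]
        scales = [model.protrusion_length_scale(d) for d in doses]
        assert all(np.diff(scales) > 0)

    def test_overcrowding_raises_packing_error(self):
        spec = FibrilArraySpec(field_width=100, field_height=100)
        with pytest.raises(PackingError):
            sample_cells(spec, CellPopulationModel(density=20000), seed=0)

    def test_flat_substrate_does_not_snap(self, small_spec):
        model = CellPopulationModel(on_fibril_fraction=1.0)
        _, truth = sample_cells(small_spec, model, seed=7, substrate="flat")
        assert not truth["on_fibril"].any()

    def test_flat_substrate_orientations_uniform_despite_kappa(self):
        # no fibrils -> no alignment cue: concentration is ignored
        spec = FibrilArraySpec(field_width=1000, field_height=1000)
        model = CellPopulationModel(orientation_kappa=50.0)
        _, truth = sample_cells(spec, model, seed=7, substrate="flat")
        assert truth["alignment_deg"].std() > 0.6 * UNIFORM_AXIAL_STD

    def test_snapped_cells_sit_on_fibril_lines(self, small_spec):
        model = CellPopulationModel(on_fibril_fraction=1.0)
        _, truth = sample_cells(small_spec, model, seed=8)
        on = truth[truth["on_fibril"]]
        d = small_spec.across_axis_coordinate(on["x_um"].to_numpy(),
                                              on["y_um"].to_numpy())
        offset = np.abs(d - small_spec.nearest_fibril_center(d))
        assert np.all(offset < 1e-6)


class TestRenderChannels:
    def test_noise_free_actin_support_equals_labels(self, small_spec, aligned_model):
        labels, _ = sample_cells(small_spec, aligned_model, seed=2)
        clean = ImagingModel(psf_sigma_um=0.0, background_photons=0.0,
                             read_noise_sd=0.0, shot_noise=False)
        _, actin = render_channels(labels, small_spec.pixel_size, clean, seed=0)
        assert np.array_equal(actin > 0, labels > 0)

    def test_fixed_seed_bit_identical(self, small_spec, aligned_model):
        labels, _ = sample_cells(small_spec, aligned_model, seed=2)
        im = ImagingModel()
        a = render_channels(labels, small_spec.pixel_size, im, seed=11)
        b = render_channels(labels, small_spec.pixel_size, im, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("bg,read", [(10.0, 2.0), (20.0, 2.0)])
    def test_background_variance_follows_noise_model(self, bg, read):
        # Poisson(bg) + N(0, read): variance = bg + read^2
        im = ImagingModel(background_photons=bg, read_noise_sd=read)
        empty = np.zeros((150, 150), dtype=np.uint16)
        nuc, _ = render_channels(empty, 0.51, im, seed=3)
        assert nuc.size >= 10**4
        assert nuc.var() == pytest.approx(bg + read**2, rel=0.1)
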