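import numpy as np
import pytest

from ustongue.contour import ContourTable
from ustongue.phantom import (
    DeformationModel,
    FrameStack,
    ImagingConfig,
    PhantomGeometry,
    generate_scatterers,
    render_frame,
)
from ustongue.piv import (
    PivConfig,
    PivError,
    RoiPlacement,
    RoiSpec,
    anchor_roi,
    clahe,
    correlate_pair,
    depth_profile_map,
    grid_shape,
    piv_pair,
    piv_sequence,
    subpixel_peak,
    surface_trace,
)
from ustongue.piv import _peak_ratio


@pytest.fixture(scope="module")
def speckle_pair_factory():
    geo = PhantomGeometry()
    cfg = ImagingConfig(seed=3)
    field = generate_scatterers(geo, 6.0, seed=3)
    base = render_frame(field, cfg).astype(float)

    def make(ux_px, uy_px):
        ux = np.broadcast_to(np.asarray(ux_px) / cfg.pixels_per_mm, (len(field),))
        uy = np.broadcast_to(-np.asarray(uy_px) / cfg.pixels_per_mm, (len(field),))
        return base, render_frame(field, cfg, (ux, uy)).astype(float)

    return field, cfg, make


PLACEMENT = RoiPlacement(200, 199, 105, 370)


class TestClahe:
    def test_constant_unchanged(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        assert np.allclose(clahe(img), 77.0)

    def test_contrast_increases_on_low_contrast_speckle(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(100, 5, (128, 128)), 0, 255).astype(np.uint8)
        out = clahe(img)
        assert out.std() > img.std()

    def test_near_idempotent(self):
        rng = np.random.default_rng(1)
        img = np.clip(rng.normal(100, 5, (128, 128)), 0, 255).astype(np.uint8)
        once = clahe(img)
        twice = clahe(np.clip(once, 0, 255).astype(np.uint8))
        d1 = np.abs(once - img).mean()
        d2 = np.abs(twice - once).mean()
        assert d2 < d1

    def test_tile_too_large_raises(self):
        with pytest.raises(PivError):
            clahe(np.zeros((4, 4), dtype=np.uint8), tiles=8)


class TestGridShape:
    def test_published_column_count(self):
        assert grid_shape(RoiSpec(width=370, height=105), PivConfig())[1] == 22

    def test_single_column(self):
        assert grid_shape(RoiSpec(width=64, height=64), PivConfig(pass_windows=(64,)))[0] == 1

    def test_quarter_overlap_rows(self):
        # floor((105 - 32) / 8) + 1 = 10
        cfg = PivConfig(overlap_fraction=0.75)
        assert grid_shape(RoiSpec(width=370, height=105), cfg)[0] == 10

    def test_window_larger_than_roi_raises(self):
        with pytest.raises(PivError):
            grid_shape(RoiSpec(width=16, height=16), PivConfig())

    def test_config_validation(self):
        with pytest.raises(PivError):
            PivConfig(pass_windows=(32, 64))
        with pytest.raises(PivError):
            PivConfig(overlap_fraction=0.9)


class TestAnchorRoi:
    def _table(self, depths):
        depths = np.atleast_2d(np.asarray(depths, dtype=float))
        return ContourTable(depths, np.linspace(0, 767, depths.shape[1]), 60.0, 512)

    def test_flat_surface(self):
        table = self._table(np.full(100, 150.0))
        p = anchor_roi(table, RoiSpec(), (512, 768))
        assert p.row0 == 150 and p.height == 105
        assert p.col0 == (768 - 370) // 2

    def test_tilted_surface_uses_median(self):
        depths = np.linspace(140, 160, 100)
        p = anchor_roi(self._table(depths), RoiSpec(), (512, 768))
        assert p.row0 == int(round(np.median(depths[25:75])))

    def test_roi_exceeding_frame_raises(self):
        table = self._table(np.full(100, 480.0))
        with pytest.raises(PivError):
            anchor_roi(table, RoiSpec(), (512, 768))

    def test_phantom_roi_nodes_below_surface(self, stickslip_run):
        _, _, stack, truth, _ = stickslip_run
        k0 = int(np.ceil(truth.schedule.strokes()[0].t_start * 60))
        table = ContourTable(truth.surface_depth, truth.station_cols, 60.0, 512)
        p = anchor_roi(table, RoiSpec(), stack.frame_shape, frame_index=k0)
        # every interrogation node (first row center at +15.5 px) lies below
        # the surface at its lateral position, for every frame
        in_roi = (truth.station_cols >= p.col0) & (truth.station_cols < p.col0 + p.width)
        deepest = truth.surface_depth[:, in_roi].max()
        first_node_row = p.row0 + 32 / 2.0 - 0.5
        assert first_node_row >= deepest


class TestCorrelatePair:
    def test_identical_windows_zero_peak(self):
        rng = np.random.default_rng(2)
        w = rng.random((32, 32))
        corr, ok = correlate_pair(w, w)
        assert ok
        assert np.unravel_index(np.argmax(corr), corr.shape) == (16, 16)

    def test_rolled_window_peak_at_shift(self):
        rng = np.random.default_rng(3)
        a = rng.random((64, 64))
        b = np.roll(np.roll(a, 3, axis=0), -2, axis=1)
        corr, ok = correlate_pair(a, b)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        assert (i - 32, j - 32) == (3, -2)

    def test_zero_variance_flagged(self):
        corr, ok = correlate_pair(np.zeros((32, 32)), np.ones((32, 32)))
        assert not ok

    def test_independent_noise_fails_peak_ratio(self):
        rng = np.random.default_rng(4)
        below = 0
        reps = 200
        for _ in range(reps):
            a = rng.random((32, 32))
            b = rng.random((32, 32))
            corr, ok = correlate_pair(a, b)
            if _peak_ratio(corr, 5) < 1.3:
                below += 1
        assert below / reps > 0.8

    def test_shape_mismatch_raises(self):
        with pytest.raises(PivError):
            correlate_pair(np.zeros((32, 32)), np.zeros((16, 16)))


class TestSubpixelPeak:
    def test_symmetric_peak_no_refinement(self):
        corr = np.zeros((33, 33))
        corr[16, 16] = 1.0
        corr[15, 16] = corr[17, 16] = corr[16, 15] = corr[16, 17] = 0.5
        dv, du, ok = subpixel_peak(corr)
        assert ok and dv == pytest.approx(0.0) and du == pytest.approx(0.0)

    def test_gaussian_offset_recovered(self):
        x = np.arange(33) - 16.0
        xx, yy = np.meshgrid(x, x, indexing="ij")
        corr = np.exp(-((xx - 0.3) ** 2 + yy**2) / (2 * 1.5**2))
        dv, du, ok = subpixel_peak(corr)
        assert ok and abs(dv - 0.3) <= 0.05

    def test_plateau_uses_parabolic_fallback(self):
        corr = np.zeros((33, 33))
        corr[15:18, 15:18] = 1.0  # flat top: log-Gaussian denominator vanishes
        dv, du, ok = subpixel_peak(corr)
        assert ok and abs(dv) <= 0.5 and abs(du) <= 0.5

    def test_border_peak_flagged(self):
        corr = np.zeros((33, 33))
        corr[0, 5] = 1.0
        _, _, ok = subpixel_peak(corr)
        assert not ok


class TestPivPair:
    def test_identical_frames_zero_field(self, speckle_pair_factory):
        _, _, make = speckle_pair_factory
        a, _ = make(0.0, 0.0)
        g = piv_pair(a, a, PLACEMENT)
        assert np.allclose(g.u, 0.0, atol=1e-9) and np.allclose(g.v, 0.0, atol=1e-9)

    def test_uniform_shift_recovered(self, speckle_pair_factory):
        _, _, make = speckle_pair_factory
        a, b = make(3.0, 0.0)
        g = piv_pair(a, b, PLACEMENT)
        assert np.abs(g.u - 3.0).mean() <= 0.1

    @pytest.mark.parametrize("shift", [1.0, 4.5, 8.0])
    def test_uniform_shift_rms(self, speckle_pair_factory, shift):
        # integer and half-integer shifts up to a quarter of the final window
        _, _, make = speckle_pair_factory
        a, b = make(shift, shift / 2.0)
        g = piv_pair(a, b, PLACEMENT)
        rms = np.sqrt(((g.u - shift) ** 2 + (g.v - shift / 2.0) ** 2).mean())
        assert rms <= 0.1

    def test_linear_shear_gradient_within_10_percent(self, speckle_pair_factory):
        field, cfg, _ = speckle_pair_factory
        base = render_frame(field, cfg).astype(float)
        rows = (512 - 1) - field.h * cfg.pixels_per_mm
        rate = 0.02
        u_px = 6.0 - rate * (rows - PLACEMENT.row0)
        shifted = render_frame(field, cfg, (u_px / cfg.pixels_per_mm, np.zeros(len(field)))).astype(float)
        g = piv_pair(base, shifted, PLACEMENT)
        slope = np.polyfit(np.repeat(g.row_px, g.u.shape[1]), g.u.ravel(), 1)[0]
        assert abs(slope + rate) <= 0.1 * rate

    def test_window_deformation_beats_single_pass(self, speckle_pair_factory):
        # large displacement + gradient: a bare 32 px pass violates the
        # quarter-window rule, the 64 px predictor pass does not
        field, cfg, _ = speckle_pair_factory
        base = render_frame(field, cfg).astype(float)
        rows = (512 - 1) - field.h * cfg.pixels_per_mm
        u_px = 12.0 - 0.03 * (rows - PLACEMENT.row0)
        shifted = render_frame(field, cfg, (u_px / cfg.pixels_per_mm, np.zeros(len(field)))).astype(float)
        truth = lambda g: 12.0 - 0.03 * g.row_px
        g2 = piv_pair(base, shifted, PLACEMENT, PivConfig())
        g1 = piv_pair(base, shifted, PLACEMENT, PivConfig(pass_windows=(32,)))
        e2 = np.sqrt(((g2.u - truth(g2)[:, None]) ** 2).mean())
        e1 = np.sqrt(((g1.u - truth(g1)[:, None]) ** 2).mean())
        assert e2 <= e1

    def test_grid_matches_grid_shape(self, speckle_pair_factory):
        _, _, make = speckle_pair_factory
        a, b = make(1.0, 0.0)
        g = piv_pair(a, b, PLACEMENT)
        assert g.shape == grid_shape(RoiSpec(), PivConfig())
        assert g.row_px.size == g.shape[0] and g.col_px.size == g.shape[1]


class TestPivSequence:
    def test_static_stack_zero(self, static_run):
        _, stack, truth, _ = static_run
        place = RoiPlacement(int(truth.surface_depth[0, 50]), 199, 105, 370)
        hist = piv_sequence(stack, t_start=0.0, t_end=0.5, placement=place)
        assert np.abs(hist.u).max() <= 0.05 and np.abs(hist.v).max() <= 0.05

    def test_pair_count(self, stickslip_run):
        _, _, stack, truth, _ = stickslip_run
        place = RoiPlacement(int(truth.surface_depth[:, 50].max()) + 1, 199, 105, 370)
        t0, t1 = 3.0, 5.0
        hist = piv_sequence(stack, t_start=t0, t_end=t1, placement=place)
        expected = sum(1 for k in range(len(stack) - 1) if t0 <= k / 60.0 < t1)
        assert len(hist) == expected

    def test_empty_window_raises(self, stickslip_run):
        _, _, stack, _, _ = stickslip_run
        with pytest.raises(PivError):
            piv_sequence(stack, t_start=100.0, t_end=101.0,
                         placement=RoiPlacement(300, 199, 105, 370))

    def test_requires_table_or_placement(self, stickslip_run):
        _, _, stack, _, _ = stickslip_run
        with pytest.raises(PivError):
            piv_sequence(stack, t_start=3.0, t_end=4.0)


@pytest.fixture(scope="module")
def stickslip_history(stickslip_run):
    _, _, stack, truth, _ = stickslip_run
    sched = truth.schedule
    table = ContourTable(truth.surface_depth, truth.station_cols, 60.0, 512)
    hist = piv_sequence(
        stack,
        t_start=sched.strokes()[0].t_start,
        t_end=sched.total_duration - 0.02,
        table=table,
    )
    return hist


class TestStickSlipRecovery:
    def test_surface_u_correlates_with_truth(self, stickslip_run, stickslip_history):
        _, _, _, truth, _ = stickslip_run
        tr = surface_trace(stickslip_history)
        gt = truth.surface_velocity_px_per_frame(tr.times)
        assert np.corrcoef(tr.u, gt)[0, 1] >= 0.9

    def test_stroke_direction_flips(self, stickslip_run, stickslip_history):
        _, _, _, truth, _ = stickslip_run
        tr = surface_trace(stickslip_history)
        strokes = truth.schedule.strokes()
        means = []
        for s in strokes:
            m = (tr.times >= s.t_start) & (tr.times < s.t_start + s.duration / 2)
            means.append(tr.u[m].mean())
        assert means[0] * means[1] < 0

    def test_surface_peak_near_stroke_onset(self, stickslip_run, stickslip_history):
        _, _, _, truth, _ = stickslip_run
        tr = surface_trace(stickslip_history)
        for s in truth.schedule.strokes():
            m = (tr.times >= s.t_start) & (tr.times <= s.t_end)
            sg = np.sign(s.velocity)
            t_peak = tr.times[m][np.argmax(sg * tr.u[m])]
            assert t_peak - s.t_start <= 1.5  # within the stick phase

    def test_trace_length_matches_history(self, stickslip_history):
        tr = surface_trace(stickslip_history)
        assert tr.times.size == len(stickslip_history) == tr.u.size

    def test_depth_profile_monotone_during_stick(self, stickslip_run, stickslip_history):
        _, _, _, truth, _ = stickslip_run
        prof = depth_profile_map(stickslip_history)
        tr = surface_trace(stickslip_history)
        s = truth.schedule.strokes()[0]
        k = int(np.argmin(np.abs(tr.times - (s.t_start + 0.3))))
        col = prof[:, k]
        assert np.all(np.diff(np.abs(col)) < 0)  # |u| decays with depth

    def test_depth_profile_shape(self, stickslip_history):
        prof = depth_profile_map(stickslip_history)
        assert prof.shape == (stickslip_history.row_px.size, len(stickslip_history))
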