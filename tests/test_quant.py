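"""Grid registration and comet segmentation against generator ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepacomet.presets import agent_preset, make_scenario
from hepacomet.quant import (
    NoGridFound,
    QuantConfig,
    extract_windows,
    qc_filter,
    quantify_field,
    reflect_split,
    register_grid,
    segment_comet,
)
from hepacomet.synth import ArrayGeometry, CometSpec, make_condition_images, render_field


def uv_field(seed=42, rotation=0.0, n_wells=1, grid=(8, 6), **kw):
    geom = ArrayGeometry(rotation_deg=rotation)
    sc = make_scenario("uv_c", 5.0, cell_line_name="fibroblast")
    return make_condition_images(
        sc, agent_preset("uv_c"), n_wells=n_wells, grid_shape=grid,
        geometry=geom, seed=seed, **kw
    )


class TestReflectSplit:
    def test_toy_profile_hand_computed(self):
        """[0,10,20,10,5,3,2] peaked at index 2: leading half {0,10} mirrors
        to the trailing side, so head = 0+10+20+10+0 = 40 of total 50."""
        head, tail = reflect_split([0, 10, 20, 10, 5, 3, 2], 2)
        assert head == 40.0
        assert tail == 10.0
        assert 100 * tail / (head + tail) == pytest.approx(20.0)

    def test_symmetric_profile_has_no_tail(self):
        prof = np.exp(-0.5 * ((np.arange(21) - 10) / 3.0) ** 2)
        head, tail = reflect_split(prof, 10)
        assert tail == pytest.approx(0.0, abs=1e-12)

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=3, max_size=40),
        st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_head_plus_tail_is_total_for_any_profile(self, values, data):
        center = data.draw(st.integers(0, len(values) - 1))
        head, tail = reflect_split(values, center)
        assert head + tail == pytest.approx(sum(values), rel=1e-12, abs=1e-9)
        assert head >= 0 or sum(values) < 0


class TestRegisterGrid:
    def test_recovers_240um_pitch_within_2pct(self):
        fld, _ = uv_field(seed=5)[0]
        grid = register_grid(fld)
        assert grid.pitch_um == pytest.approx(240.0, rel=0.02)

    @pytest.mark.parametrize("rotation", [-2.0, 1.0])
    def test_recovers_rotation_within_0p2_degrees(self, rotation):
        fld, _ = uv_field(seed=6, rotation=rotation)[0]
        grid = register_grid(fld)
        assert grid.rotation_deg == pytest.approx(rotation, abs=0.2)
        assert grid.pitch_um == pytest.approx(240.0, rel=0.02)

    def test_blank_field_raises_nogridfound(self):
        blank, _ = render_field([], ArrayGeometry(), shape=(600, 600),
                                background=20.0, seed=1)
        with pytest.raises(NoGridFound):
            register_grid(blank)

    def test_nodes_cover_every_lattice_site(self):
        fld, manifest = uv_field(seed=7, occupancy=1.0)[0]
        grid = register_grid(fld)
        assert len(grid.nodes) == len(manifest.comets)
        # every true center has a node within a fraction of the pitch
        centers = manifest.comets[["cy", "cx"]].to_numpy()
        for c in centers:
            d = np.linalg.norm(grid.nodes - c, axis=1).min()
            assert d < 0.1 * grid.pitch_px


class TestSegmentation:
    @pytest.mark.parametrize("tail_frac", [0.0, 0.1, 0.3, 0.5, 0.7, 0.9])
    def test_noiseless_oracle_within_5_points(self, single_comet_window, tail_frac):
        win, _, _ = single_comet_window(tail_frac)
        rec = segment_comet(win, um_per_px=1.6)
        assert rec.percent_tail == pytest.approx(100 * tail_frac, abs=5.0)

    def test_noiseless_bias_is_monotone_toward_head(self, single_comet_window):
        """The reflection rule counts the tail's center column once into the
        head, so the bias is small, negative and grows with tail fraction."""
        errs = []
        for f in np.arange(0.1, 1.0, 0.1):
            win, _, _ = single_comet_window(float(f))
            rec = segment_comet(win, um_per_px=1.6)
            errs.append(rec.percent_tail - 100 * f)
        assert all(e <= 0 for e in errs)
        assert np.all(np.diff(errs) <= 1e-6)

    def test_conservation_exact(self, single_comet_window):
        win, _, _ = single_comet_window(0.4)
        rec = segment_comet(win, um_per_px=1.6)
        assert rec.head + rec.tail == pytest.approx(rec.total, rel=1e-12)
        assert 0.0 <= rec.percent_tail <= 100.0

    def test_all_zero_window_flagged_empty(self, single_comet_window):
        win, _, _ = single_comet_window(0.3)
        win.image = np.zeros_like(win.image)
        rec = segment_comet(win, um_per_px=1.6)
        assert "empty_well" in rec.flags
        assert np.isnan(rec.percent_tail)

    def test_tail_moment_grows_with_migration(self, single_comet_window):
        tms = []
        for f in (0.1, 0.4, 0.7):
            win, _, _ = single_comet_window(f)
            rec = segment_comet(win, um_per_px=1.6)
            tms.append(rec.tail_moment_um)
        assert tms[0] < tms[1] < tms[2]
        # physical units: moment in um is the px moment times the pixel size
        assert tms[-1] == pytest.approx(
            segment_comet(single_comet_window(0.7)[0], um_per_px=1.6).tail_moment_px * 1.6
        )

    def test_noise_robustness_of_condition_median(self, single_comet_window):
        """Poisson noise at the default level shifts the condition-level
        summary by well under 2 percentage points."""
        rng = np.random.default_rng(123)
        for f in (0.1, 0.745):
            clean_rec = segment_comet(single_comet_window(f)[0], um_per_px=1.6)
            noisy = []
            for _ in range(40):
                win, _, _ = single_comet_window(
                    f, background=20.0, noise="poisson", rng=rng
                )
                noisy.append(segment_comet(win, um_per_px=1.6).percent_tail)
            assert abs(np.median(noisy) - clean_rec.percent_tail) < 2.0


class TestWindowsAndFlags:
    def test_one_window_per_node(self):
        fld, _ = uv_field(seed=8)[0]
        grid = register_grid(fld)
        windows = extract_windows(fld, grid)
        assert len(windows) == len(grid.nodes)

    def test_unoccupied_wells_flagged_empty(self):
        fld, manifest = uv_field(seed=9, occupancy=0.7)[0]
        rec = quantify_field(fld)
        n_empty_true = int((~manifest.comets["occupied"]).sum())
        n_empty_called = int(rec["flags"].str.contains("empty_well").sum())
        assert abs(n_empty_called - n_empty_true) <= 2

    def test_saturated_pixels_flagged(self, geometry):
        specs = [CometSpec(0, 0, 150.0, 120.0, 2.0e5, 0.3)]
        fld, _ = render_field(specs, geometry, shape=(300, 420),
                              background=0.0, noise="none")
        img = np.asarray(fld.image).copy()
        img[148:152, 118:122] = np.iinfo(np.uint16).max
        fld.image = img
        win = extract_windows(
            fld,
            register_grid_stub(fld, geometry),
        )[0]
        rec = segment_comet(win, um_per_px=1.6)
        assert "saturated" in rec.flags


def register_grid_stub(fld, geometry):
    """Known-truth grid for a single comet at (150, 120)."""
    from hepacomet.quant import GridFit

    return GridFit(
        pitch_px=geometry.pitch_px,
        pitch_um=geometry.pitch_um,
        rotation_deg=0.0,
        offset=(150.0, 120.0),
        nodes=np.array([[150.0, 120.0]]),
        node_index=np.array([[0, 0]]),
        score=1.0,
    )


class TestQcFilter:
    def _records(self, n_clean, n_flagged, condition="c1"):
        rows = []
        for i in range(n_clean):
            rows.append({"percent_tail": 10.0, "flags": "", "condition": condition})
        for i in range(n_flagged):
            rows.append({"percent_tail": 10.0, "flags": "overlap", "condition": condition})
        return pd.DataFrame(rows)

    def test_99_clean_comets_fails_gate(self):
        _, status = qc_filter(self._records(99, 0))
        assert not status["qc_pass"].iloc[0]

    def test_100_clean_comets_passes_gate(self):
        clean, status = qc_filter(self._records(100, 0))
        assert status["qc_pass"].iloc[0]
        assert len(clean) == 100

    def test_flagged_records_do_not_count(self):
        # 150 records, 60 flagged -> 90 clean -> below the gate
        _, status = qc_filter(self._records(90, 60))
        assert status["n_clean"].iloc[0] == 90
        assert not status["qc_pass"].iloc[0]

    def test_no_flags_is_identity(self):
        df = self._records(120, 0)
        clean, status = qc_filter(df)
        assert len(clean) == len(df)
        assert status["qc_pass"].iloc[0]
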