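"""Visual disturbance index, halo extents, and results rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import halometry as h
from conftest import matrix_with_misses


def naive_vdi(misses, radii, weight):
    """Independent double-loop oracle for the weighted miss index."""
    num = 0.0
    den = 0.0
    for p_i, r_i in zip(misses, radii):
        num += p_i * r_i * r_i
    for r_i in radii:
        den += weight * r_i * r_i
    return num / den


class TestComputeVdi:
    def test_full_detection_gives_zero(self, study_layout):
        m = matrix_with_misses(study_layout, np.zeros(72))
        assert h.compute_vdi(m, study_layout) == 0.0

    def test_total_miss_gives_one(self, study_layout):
        m = matrix_with_misses(study_layout, np.full(72, 2))
        assert h.compute_vdi(m, study_layout) == pytest.approx(1.0, abs=1e-15)

    def test_one_semiaxis_missed_once(self, study_layout):
        # the per-semiaxis ring sums cancel: one of 18 semiaxes missed once
        # out of weight 2 contributes exactly 1/36
        misses = np.zeros(72, dtype=int)
        misses[study_layout.to_frame()["semiaxis_index"] == 5] = 1
        m = matrix_with_misses(study_layout, misses)
        assert h.compute_vdi(m, study_layout) == pytest.approx(1 / 36, abs=1e-12)

    def test_outermost_ring_missed_twice(self, study_layout):
        # ring radii 26/38/49/60: sum of squares 676+1444+2401+3600 = 8121
        misses = np.zeros(72, dtype=int)
        misses[study_layout.to_frame()["ring_index"] == 3] = 2
        m = matrix_with_misses(study_layout, misses)
        assert h.compute_vdi(m, study_layout) == pytest.approx(3600 / 8121, abs=1e-12)

    def test_mismatched_ids_rejected(self, study_layout):
        m = h.DetectionMatrix(np.arange(10), np.full(10, 2), np.zeros(10))
        with pytest.raises(ValueError, match="ids"):
            h.compute_vdi(m, study_layout)

    @given(st.integers(0, 2**30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_oracle_equivalence_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        lay = h.generate_layout(None)
        misses = rng.integers(0, 3, size=72)
        m = matrix_with_misses(lay, misses)
        assert h.compute_vdi(m, lay) == pytest.approx(
            naive_vdi(misses, lay.radii, 2), abs=1e-12
        )

    @given(st.integers(0, 2**30))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_monotone_in_each_miss_count(self, seed):
        rng = np.random.default_rng(seed)
        lay = h.generate_layout(None)
        misses = rng.integers(0, 2, size=72)  # leave room to increment
        base = h.compute_vdi(matrix_with_misses(lay, misses), lay)
        i = int(rng.integers(0, 72))
        bumped = misses.copy()
        bumped[i] += 1
        assert h.compute_vdi(matrix_with_misses(lay, bumped), lay) > base

    def test_scale_invariance_under_radius_rescaling(self):
        # r^2 cancels between numerator and denominator
        lay1 = h.generate_layout({"main_radius_px": 10, "peripheral_radius_px": 2,
                                  "max_radius_px": 40, "n_semiaxes": 6, "n_per_semiaxis": 2})
        lay2 = h.generate_layout({"main_radius_px": 30, "peripheral_radius_px": 6,
                                  "max_radius_px": 120, "n_semiaxes": 6, "n_per_semiaxis": 2})
        np.testing.assert_allclose(lay2.radii, 3 * lay1.radii)
        rng = np.random.default_rng(0)
        misses = rng.integers(0, 3, size=lay1.n_stimuli)
        v1 = h.compute_vdi(matrix_with_misses(lay1, misses), lay1)
        v2 = h.compute_vdi(matrix_with_misses(lay2, misses), lay2)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_moving_a_miss_outward_increases_vdi(self, study_layout):
        frame = study_layout.to_frame()
        inner = frame[(frame.semiaxis_index == 0) & (frame.ring_index == 0)].stimulus_id.iloc[0]
        outer = frame[(frame.semiaxis_index == 0) & (frame.ring_index == 3)].stimulus_id.iloc[0]
        a = np.zeros(72, dtype=int)
        a[inner] = 1
        b = np.zeros(72, dtype=int)
        b[outer] = 1
        assert h.compute_vdi(matrix_with_misses(study_layout, b), study_layout) > \
            h.compute_vdi(matrix_with_misses(study_layout, a), study_layout)


class TestVdisci:
    @pytest.mark.parametrize("vdi, expected", [(0.0, 1.0), (1.0, 0.0), (0.25, 0.75)])
    def test_complement(self, vdi, expected):
        assert h.compute_vdisci(vdi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h.compute_vdisci(1.5)


class TestHaloExtent:
    def test_all_detected_zero_extent(self, study_layout):
        m = matrix_with_misses(study_layout, np.zeros(72))
        ext = h.halo_extent(m, study_layout)
        assert (ext["extent_px"] == 0).all()
        assert len(ext) == 18

    def test_all_missed_full_extent(self, study_layout):
        m = matrix_with_misses(study_layout, np.full(72, 2))
        ext = h.halo_extent(m, study_layout)
        assert (ext["extent_px"] == 60).all()

    def test_contiguous_core_stops_at_first_detected_ring(self, study_layout):
        frame = study_layout.to_frame()
        misses = np.zeros(72, dtype=int)
        on_axis = frame.semiaxis_index == 2
        misses[(on_axis & (frame.ring_index <= 1)).to_numpy()] = 2  # rings 26, 38 missed
        m = matrix_with_misses(study_layout, misses)
        ext = h.halo_extent(m, study_layout, miss_fraction_threshold=1.0)
        assert ext.loc[ext.semiaxis_index == 2, "extent_px"].iloc[0] == 38
        assert (ext.loc[ext.semiaxis_index != 2, "extent_px"] == 0).all()

    def test_gap_beyond_detected_ring_excluded(self, study_layout):
        # a missed outer ring behind a detected one is not part of the core
        frame = study_layout.to_frame()
        misses = np.zeros(72, dtype=int)
        misses[((frame.semiaxis_index == 0) & (frame.ring_index == 3)).to_numpy()] = 2
        m = matrix_with_misses(study_layout, misses)
        ext = h.halo_extent(m, study_layout)
        assert (ext["extent_px"] == 0).all()

    def test_threshold_validation(self, study_layout):
        m = matrix_with_misses(study_layout, np.zeros(72))
        with pytest.raises(ValueError):
            h.halo_extent(m, study_layout, miss_fraction_threshold=0.0)


class TestRendering:
    def test_all_detected_map_shows_counts(self, study_layout):
        m = matrix_with_misses(study_layout, np.zeros(72))
        result = h.score_session(m, study_layout)
        text = h.render_text_map(result)
        assert text.count("2") >= 1 and "X" not in text.splitlines()[0:-1][0]
        assert "X" not in "\n".join(text.splitlines()[:-1])
        assert "0.00" in text  # rho printed to two decimals

    def test_all_missed_map_shows_x(self, study_layout):
        m = matrix_with_misses(study_layout, np.full(72, 2))
        text = h.render_text_map(h.score_session(m, study_layout))
        body = "\n".join(text.splitlines()[:-1])
        assert "X" in body and "1" not in body and "2" not in body

    def test_mixed_glyphs_follow_detected_count(self, study_layout):
        # detected count p - p_i when > 0, else X
        misses = np.zeros(72, dtype=int)
        misses[0] = 1  # detected once -> glyph "1"
        misses[1] = 2  # never detected -> glyph "X"
        text = h.render_text_map(h.score_session(matrix_with_misses(study_layout, misses),
                                                 study_layout))
        body = "\n".join(text.splitlines()[:-1])
        assert "1" in body and "X" in body and "2" in body

    def test_figure_render(self, tmp_path, study_layout):
        m = matrix_with_misses(study_layout, (np.arange(72) % 3).astype(int))
        result = h.score_session(m, study_layout, pupil_mm=5.5)
        out = tmp_path / "map.png"
        h.render_figure(result, out)
        assert out.exists() and out.stat().st_size > 0

    def test_result_json_export(self, tmp_path, study_layout):
        m = matrix_with_misses(study_layout, np.zeros(72))
        result = h.score_session(m, study_layout)
        out = tmp_path / "result.json"
        result.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["vdi"] == 0.0 and data["vdisci"] == 1.0
        assert len(data["stimuli"]) == 72 and len(data["extents"]) == 18


def test_vdi_plus_vdisci_is_one_for_scored_sessions(study_layout):
    rng = np.random.default_rng(4)
    m = matrix_with_misses(study_layout, rng.integers(0, 3, 72))
    result = h.score_session(m, study_layout)
    assert result.vdi + result.vdisci == pytest.approx(1.0, abs=1e-15)
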