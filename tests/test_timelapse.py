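"""Time-lapse generation and behavior scoring (scaled-down movies)."""

import numpy as np
import pandas as pd
import pytest

from junctionscope.behaviors import (DivisionTrack, RosetteTrack,
                                     area_trajectory, build_frame_contexts,
                                     classify_rosette_fate,
                                     cumulative_new_interface,
                                     division_summary, gap_radius_series,
                                     track_division, track_rosettes)
from junctionscope.geometry import RegionSpec
from junctionscope.movies import make_timelapse
from junctionscope.synth import preset


def _small_movie_cfg(**kw):
    base = dict(n_cells=120, field_um=(60.0, 60.0), n_order4=6,
                rosette_count=3, movie_duration_min=180.0)
    base.update(kw)
    return preset("mutant_movie", **base)


@pytest.fixture(scope="module")
def mutant_movie():
    cfg = _small_movie_cfg(p_no_new_interface=0.5, p_neighbor_gap=0.6,
                           p_rosette_gap=1.0, division_rate_per_hour=0.06)
    mov = make_timelapse(cfg, seed=61)
    ctx = build_frame_contexts(mov.labels, mov.channels["aj"],
                               mov.pixel_size_um)
    return mov, ctx


class TestGeneration:
    def test_frame_grid_and_shapes(self, mutant_movie):
        mov, _ = mutant_movie
        assert mov.labels.shape[0] == 31
        np.testing.assert_allclose(np.diff(mov.times_min), 6.0)

    def test_deterministic(self):
        cfg = _small_movie_cfg(noise_sd=0.0)
        a = make_timelapse(cfg, seed=62)
        b = make_timelapse(cfg, seed=62)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.channels["aj"], b.channels["aj"])

    def test_constriction_is_definitionally_exact(self):
        cfg = _small_movie_cfg(noise_sd=0.0, rosette_count=0,
                               division_rate_per_hour=0.0,
                               constriction_fraction_at={180.0: 0.22})
        mov = make_timelapse(cfg, seed=63)
        a0 = (mov.labels[0] > 0).sum()
        a1 = (mov.labels[-1] > 0).sum()
        assert a1 / a0 == pytest.approx(0.78, abs=0.01)  # half-pixel box edges

    def test_divisions_within_first_90_minutes(self, mutant_movie):
        mov, _ = mutant_movie
        div = mov.truth[mov.truth["event"] == "division"]
        assert (div["frame"] <= 15).all()
        assert (div["frame"] >= 1).all()


class TestRosettes:
    def test_builtin_order5_is_preexisting(self):
        cfg = _small_movie_cfg(n_order5=2, rosette_count=0,
                               division_rate_per_hour=0.0, noise_sd=0.0)
        mov = make_timelapse(cfg, seed=64)
        ctx = build_frame_contexts(mov.labels, mov.channels["aj"],
                                   mov.pixel_size_um)
        tracks = track_rosettes(ctx)
        assert len(tracks) >= 1
        assert all(t.formation_mode == "preexisting" for t in tracks
                   if t.frames[0] == 0)

    def test_t1_rosettes_detected_at_truth_frame(self, mutant_movie):
        mov, ctx = mutant_movie
        tracks = track_rosettes(ctx)
        truth = mov.truth[mov.truth["event"] == "rosette"]
        assert len(tracks) >= len(truth) - 1
        matched = 0
        for r in truth.itertuples():
            for tr in tracks:
                if abs(tr.frames[0] - r.frame) <= 1:
                    d = np.hypot(tr.centers_um[0][0] - r.x_um,
                                 tr.centers_um[0][1] - r.y_um)
                    if d < 6.0:
                        matched += 1
                        assert tr.formation_mode == "rearrangement"
                        break
        assert matched >= len(truth) - 1

    def test_gap_fates_recovered(self, mutant_movie):
        mov, ctx = mutant_movie
        tracks = track_rosettes(ctx)
        truth = mov.truth[mov.truth["event"] == "rosette"]
        fates = [classify_rosette_fate(
            t, gap_radius_series(t, ctx, mov.channels["aj"])) for t in tracks]
        n_gapped = sum(f != "no_gap" for f in fates)
        assert n_gapped >= int(truth["gapped"].sum()) - 1


class TestFateRules:
    def _track(self):
        return RosetteTrack(id=1, frames=list(range(8)),
                            centers_um=[(0, 0)] * 8, max_order=5)

    def test_no_gap(self):
        assert classify_rosette_fate(self._track(), [0] * 8) == "no_gap"

    def test_repaired(self):
        fate = classify_rosette_fate(self._track(),
                                     [0, 0.7, 0.7, 0, 0, 0, 0, 0])
        assert fate == "repaired"

    def test_persistent_constant_radius(self):
        fate = classify_rosette_fate(self._track(),
                                     [0, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7])
        assert fate == "persistent"

    def test_expanding_strict_increase(self):
        fate = classify_rosette_fate(self._track(),
                                     [0, 0.7, 0.95, 1.2, 1.45, 1.7, 1.95, 2.2])
        assert fate == "expanding"

    def test_fates_exhaustive_and_exclusive(self):
        series = [[0] * 8, [0, 0.7, 0.7, 0, 0, 0, 0, 0],
                  [0.7] * 8, [0.5, 0.8, 1.1, 1.4, 1.7, 2.0, 2.3, 2.6]]
        fates = [classify_rosette_fate(self._track(), s) for s in series]
        assert set(fates) == {"no_gap", "repaired", "persistent", "expanding"}


class TestDivisions:
    def test_summary_matches_truth(self, mutant_movie):
        mov, ctx = mutant_movie
        truth = mov.truth[mov.truth["event"] == "division"]
        tracks = [track_division(mov.labels, ctx, mov.channels["aj"],
                                 int(r.label), int(r.frame))
                  for r in truth.itertuples()]
        summary = division_summary(tracks)
        usable = [t for t in tracks if not t.excluded]
        assert summary["n_divisions"] == len(usable)
        truth_fail = truth["failed"].mean()
        assert summary["failure_fraction"] == pytest.approx(truth_fail,
                                                            abs=0.15)

    def test_completion_time_on_frame_grid(self, mutant_movie):
        mov, ctx = mutant_movie
        truth = mov.truth[mov.truth["event"] == "division"]
        for r in truth.itertuples():
            t = track_division(mov.labels, ctx, mov.channels["aj"],
                               int(r.label), int(r.frame))
            if t.completed:
                assert t.completion_time_min % 6.0 == 0
                assert t.completion_time_min <= 90.0
                assert t.completion_time_min == pytest.approx(
                    (r.completion_frame - r.frame) * 6.0)
            else:
                assert t.censored_at_90

    def test_unknown_cell_excluded(self, mutant_movie):
        mov, ctx = mutant_movie
        t = track_division(mov.labels, ctx, mov.channels["aj"], 99999, 2)
        assert t.excluded


class TestCumulativeCurve:
    def _tracks(self, times):
        out = []
        for tm in times:
            out.append(DivisionTrack(cell_label=1, t0_frame=0,
                                     completed=tm is not None,
                                     completion_time_min=tm,
                                     censored_at_90=tm is None,
                                     neighbor_gap=False))
        return out

    def test_step_function(self):
        curve = cumulative_new_interface(self._tracks([30.0, 30.0, 30.0]))
        frac = curve.set_index("t_min")["cumulative_fraction"]
        assert frac[24.0] == 0.0
        assert frac[30.0] == 1.0

    def test_monotone_and_ends_at_one(self):
        curve = cumulative_new_interface(
            self._tracks([6.0, 30.0, 60.0, 90.0, None]))
        f = curve["cumulative_fraction"].to_numpy()
        assert np.all(np.diff(f) >= 0)
        assert f[-1] == pytest.approx(1.0)

    def test_matches_brute_force_counting(self):
        times = [6.0, 12.0, 12.0, 48.0, None, 84.0]
        curve = cumulative_new_interface(self._tracks(times))
        comp = [t for t in times if t is not None]
        for _, row in curve.iterrows():
            expected = sum(t <= row.t_min for t in comp) / len(comp)
            assert row.cumulative_fraction == pytest.approx(expected)

    def test_all_denominator(self):
        curve = cumulative_new_interface(self._tracks([30.0, None]),
                                         denominator="all")
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(0.5)


class TestAreaTrajectory:
    def test_no_change_movie(self):
        cfg = _small_movie_cfg(constriction_fraction_at={}, rosette_count=0,
                               division_rate_per_hour=0.0, noise_sd=0.0,
                               movie_duration_min=36.0)
        mov = make_timelapse(cfg, seed=66)
        out = area_trajectory(mov.labels, mov.pixel_size_um,
                              RegionSpec((5, 5), (50, 50)),
                              checkpoint_min=(36.0,))
        assert out["percent_decrease"][36.0] == pytest.approx(0.0, abs=0.5)

    def test_recovers_configured_constriction(self):
        cfg = _small_movie_cfg(rosette_count=0, division_rate_per_hour=0.0,
                               noise_sd=0.0)
        mov = make_timelapse(cfg, seed=67)
        out = area_trajectory(mov.labels, mov.pixel_size_um,
                              RegionSpec((5, 5), (50, 50)))
        assert out["percent_decrease"][90.0] == pytest.approx(17.0, abs=1.0)
        assert out["percent_decrease"][180.0] == pytest.approx(22.0, abs=1.0)
        assert not out["unreliable"]
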