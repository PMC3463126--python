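"""Wavelet ridge-line peak caller: kernel arithmetic, translation invariance,
maxima oracles, exhaustive-assignment ridge linking, planted-peak recovery."""

import itertools
import math

import numpy as np
import pytest

from genomekit.coverage_engine import CoverageTrack
from genomekit.errors import ContractError
from genomekit.fixtures import make_peak_track
from genomekit.wavelet_peaks import (
    RidgeLine,
    RidgePoint,
    ScaleMaxima,
    SmoothedTrack,
    auto_min_signal,
    call_peaks,
    call_peaks_from_tracks,
    cwt_scales,
    find_scale_maxima,
    gaussian_smooth_peaks,
    link_ridges,
    prepare_signal,
    ricker_kernel,
    windowed_maxima,
)


def track_from_dense(values, contig="chr1", reads=None):
    t = CoverageTrack(contig_lengths={contig: len(values)})
    arr = t.array(contig, "total")
    fwd = t.array(contig, "forward")
    for i, v in enumerate(values):
        if v:
            arr[i] = float(v)
            fwd[i] = float(v)
    t.reads_counted = reads if reads is not None else max(1, int(round(sum(values))))
    return t


class TestPrepareSignal:
    def test_identical_sample_control_cancels(self):
        vals = [0, 3, 5, 2, 0, 0, 7, 1]
        s = track_from_dense(vals)
        c = track_from_dense(vals)
        sig = prepare_signal(s, c, bin_size=1)["chr1"]
        assert np.all(sig.values == 0)

    def test_identity_path(self):
        vals = [0.0, 2.0, 4.0, 0.0]
        s = track_from_dense(vals, reads=2)
        sig = prepare_signal(s, None, bin_size=1, kernel="none")["chr1"]
        np.testing.assert_allclose(sig.values, np.array(vals) * (1e6 / 2))

    def test_binning_sums(self):
        s = track_from_dense([1.0] * 10, reads=1)
        sig = prepare_signal(s, None, bin_size=5)["chr1"]
        np.testing.assert_allclose(sig.values, [5e6, 5e6])

    def test_gaussian_kernel_mass_and_symmetry(self):
        vals = [0.0] * 101
        vals[50] = 1.0
        s = track_from_dense(vals, reads=1)
        sig = prepare_signal(s, None, bin_size=1, kernel=("gaussian", 4.0))["chr1"]
        assert sig.values.sum() == pytest.approx(1e6, rel=1e-6)
        np.testing.assert_allclose(sig.values, sig.values[::-1], atol=1e-9)

    def test_zero_reads_errors(self):
        t = CoverageTrack(contig_lengths={"chr1": 10})
        with pytest.raises(ContractError):
            prepare_signal(t, None)


class TestCwt:
    def test_zero_signal_zero_coefficients(self):
        sig = SmoothedTrack("c", 1, np.zeros(500))
        for arr in cwt_scales(sig, [4, 16, 64]).values():
            np.testing.assert_allclose(arr, 0, atol=1e-12)

    def test_constant_signal_zero_response(self):
        sig = SmoothedTrack("c", 1, np.full(500, 7.0))
        co = cwt_scales(sig, [8])
        np.testing.assert_allclose(co[8][100:400], 0, atol=1e-9)

    def test_output_length_preserved(self):
        sig = SmoothedTrack("c", 1, np.abs(np.sin(np.arange(300) / 7.0)))
        for arr in cwt_scales(sig, [2, 8, 32]).values():
            assert len(arr) == 300

    def test_translation_invariance_interior(self, rng):
        base = np.abs(rng.normal(size=2000))
        k = 37
        shifted = np.concatenate([np.zeros(k), base])[:2000]
        c1 = cwt_scales(SmoothedTrack("c", 1, base), [4, 16])
        c2 = cwt_scales(SmoothedTrack("c", 1, shifted), [4, 16])
        for s in (4, 16):
            pad = int(math.ceil(5 * math.sqrt(2) * s)) + k + 2
            np.testing.assert_allclose(
                c2[s][pad : 2000 - pad], c1[s][pad - k : 2000 - pad - k], atol=1e-9
            )

    def test_matched_scale_argmax(self):
        """A sigma=20 Gaussian bump peaks at the grid scale nearest 20."""
        x = np.arange(4000)
        sig = SmoothedTrack("c", 1, np.exp(-((x - 2000) ** 2) / (2 * 20.0**2)))
        co = cwt_scales(sig, [2, 4, 8, 16, 32, 64, 128, 256])
        center_vals = {s: arr[2000] for s, arr in co.items()}
        best = max(center_vals, key=center_vals.get)
        assert best == min(co, key=lambda s: abs(s - 20))

    def test_matched_response_scale_independent(self):
        """Matched bumps of very different widths give equal coefficients."""
        responses = []
        for sigma in (8, 32, 128):
            n = 20 * sigma
            x = np.arange(n)
            sig = SmoothedTrack("c", 1, np.exp(-((x - n // 2) ** 2) / (2 * sigma**2)))
            co = cwt_scales(sig, [sigma])
            responses.append(co[sigma][n // 2])
        assert max(responses) - min(responses) < 1e-3
        assert all(abs(r - 0.9649) < 5e-3 for r in responses)

    def test_subbin_scales_skipped(self):
        sig = SmoothedTrack("c", 10, np.zeros(100))
        co = cwt_scales(sig, [2, 4, 80])
        assert list(co) == [80.0]


class TestScaleMaxima:
    def brute_force(self, values, window):
        half = window // 2
        out = []
        for i in range(half, len(values) - half):
            lo, hi = i - half, i + half + 1
            left_ok = all(values[j] < values[i] for j in range(lo, i))
            right_ok = all(values[j] <= values[i] for j in range(i + 1, hi))
            if left_ok and right_ok:
                out.append(i)
        return out

    def test_strictly_monotone_no_maxima(self):
        pos, _ = windowed_maxima(np.arange(50, dtype=float), 5)
        assert list(pos) == []

    def test_single_impulse(self):
        v = np.zeros(100)
        v[40] = 3.0
        pos, val = windowed_maxima(v, 7)
        assert list(pos) == [40] and list(val) == [3.0]

    def test_plateau_leftmost(self):
        v = np.array([0, 0, 5, 5, 5, 0, 0], dtype=float)
        pos, _ = windowed_maxima(v, 3)
        assert list(pos) == [2]

    def test_random_arrays_match_brute_force(self, rng):
        for _ in range(25):
            v = rng.integers(0, 8, size=200).astype(float)  # ties common
            for window in (3, 7, 11):
                pos, _ = windowed_maxima(v, window)
                assert list(pos) == self.brute_force(v, window)

    def test_find_scale_maxima_orders_descending(self, rng):
        co = {4.0: rng.normal(size=300), 16.0: rng.normal(size=300)}
        out = find_scale_maxima(co, 1.0, bin_size=1)
        assert [m.scale for m in out] == [16.0, 4.0]


def exhaustive_link_oracle(maxima, gap_tolerance, position_tolerance_factor):
    """Exhaustive enumeration of per-level one-to-one matchings, selecting
    the one the priority order prescribes (each higher-priority ridge gets
    the nearest available maximum), computed without the greedy shortcut."""
    ridges = []
    for sm in maxima:
        cand = list(range(len(sm.positions)))
        active = [r for r in ridges if r["alive"]]
        order = sorted(
            range(len(active)),
            key=lambda k: (
                -active[k]["points"][-1].coefficient,
                -len(active[k]["points"]),
                active[k]["points"][-1].position,
            ),
        )
        # enumerate all assignments of ridges (in priority order) to distinct
        # maxima-or-nothing; keep the lexicographically best by (distance,
        # position) per ridge in priority order
        best_assign = None
        best_key = None
        choices = [cand + [None] for _ in order]
        for assign in itertools.product(*choices):
            used = [a for a in assign if a is not None]
            if len(used) != len(set(used)):
                continue
            key = []
            ok = True
            for k, a in zip(order, assign):
                cur = active[k]["points"][-1]
                tol = position_tolerance_factor * cur.scale
                if a is None:
                    key.append((math.inf, math.inf))
                else:
                    d = abs(int(sm.positions[a]) - cur.position)
                    if d > tol:
                        ok = False
                        break
                    key.append((d, int(sm.positions[a])))
            if not ok:
                continue
            if best_key is None or key < best_key:
                best_key = key
                best_assign = assign
        claimed = set()
        if best_assign is not None:
            for k, a in zip(order, best_assign):
                r = active[k]
                if a is None:
                    r["gap"] += 1
                    if r["gap"] > gap_tolerance:
                        r["alive"] = False
                else:
                    claimed.add(a)
                    r["points"].append(
                        RidgePoint(
                            sm.scale,
                            int(sm.positions[a]),
                            float(sm.coefficients[a]),
                        )
                    )
                    r["gap"] = 0
        for j in range(len(sm.positions)):
            if j not in claimed:
                ridges.append(
                    {
                        "points": [
                            RidgePoint(sm.scale, int(sm.positions[j]),
                                       float(sm.coefficients[j]))
                        ],
                        "gap": 0,
                        "alive": True,
                    }
                )
    return [[(p.scale, p.position) for p in r["points"]] for r in ridges]


class TestRidgeLinking:
    def _maxima(self, spec):
        # spec: list of (scale, [(pos, coeff), ...]) descending scale
        out = []
        for scale, pts in spec:
            pts = sorted(pts)
            out.append(
                ScaleMaxima(
                    scale,
                    np.array([p for p, _ in pts], dtype=int),
                    np.array([c for _, c in pts], dtype=float),
                )
            )
        return out

    def test_persistent_maximum_single_full_ridge(self):
        spec = [(s, [(100, 1.0)]) for s in (64, 32, 16, 8)]
        ridges = link_ridges(self._maxima(spec), 2, 1.0)
        assert len(ridges) == 1 and ridges[0].length == 4
        assert ridges[0].summit == 100

    def test_lone_maxima_length_one(self):
        spec = [(64, []), (32, [(50, 1.0), (200, 2.0)]), (16, [])]
        ridges = link_ridges(self._maxima(spec), 0, 1.0)
        assert sorted(r.length for r in ridges) == [1, 1]

    def test_gap_tolerance_bridges_missing_scale(self):
        spec = [(64, [(100, 1.0)]), (32, []), (16, [(101, 2.0)])]
        ridges = link_ridges(self._maxima(spec), 1, 1.0)
        assert len(ridges) == 1 and ridges[0].length == 2

    def test_gap_exhaustion_kills_ridge(self):
        spec = [(64, [(100, 1.0)]), (32, []), (16, []), (8, [(100, 2.0)])]
        ridges = link_ridges(self._maxima(spec), 1, 1.0)
        assert sorted(r.length for r in ridges) == [1, 1]

    def test_greedy_equals_exhaustive_oracle(self, rng):
        """On all enumerable instances (≤4 scales × ≤6 maxima) the greedy
        linker reproduces the exhaustive-assignment optimum."""
        for trial in range(200):
            n_scales = int(rng.integers(1, 5))
            scales = [64.0 / (2**k) for k in range(n_scales)]
            spec = []
            for s in scales:
                n_max = int(rng.integers(0, 7))
                pts = []
                used = set()
                for _ in range(n_max):
                    p = int(rng.integers(0, 120))
                    if p in used:
                        continue
                    used.add(p)
                    pts.append((p, float(rng.integers(1, 10))))
                spec.append((s, pts))
            maxima = self._maxima(spec)
            gap = int(rng.integers(0, 3))
            ptf = float(rng.choice([0.5, 1.0, 2.0]))
            got = [
                [(p.scale, p.position) for p in r.points]
                for r in link_ridges(maxima, gap, ptf)
            ]
            expect = exhaustive_link_oracle(maxima, gap, ptf)
            assert sorted(got) == sorted(expect), (trial, spec, gap, ptf)


class TestCallPeaks:
    def test_no_ridges_no_peaks(self):
        sig = SmoothedTrack("c", 1, np.zeros(100))
        assert call_peaks(sig, [], min_signal=1.0) == []

    def test_planted_gaussian_recovered(self):
        track, truth = make_peak_track(
            50_000, [(25_000, 100.0, 50.0)], noise_rate=1.0, seed=4
        )
        peaks = call_peaks_from_tracks(track, bin_size=10, min_signal="auto")
        assert len(peaks) >= 1
        top = peaks[0]
        center = truth.peaks[0].center
        assert abs(top.summit - center) <= 50  # within sigma/2
        assert top.interval.start <= center < top.interval.end

    def test_spike_filtered_vs_kept(self):
        track, _ = make_peak_track(
            20_000, [], noise_rate=0.0, seed=5, spikes=[(10_000, 1000.0)]
        )
        with_filter = call_peaks_from_tracks(
            track, bin_size=10, min_signal=1.0, max_spike_sharpness=2.0
        )
        assert with_filter == []
        without = call_peaks_from_tracks(
            track, bin_size=10, min_signal=1.0, max_spike_sharpness=None
        )
        assert len(without) == 1 and without[0].filtered_reason == "none"
        assert abs(without[0].summit - 10_000) <= 10

    def test_amplitude_monotonicity(self):
        track, _ = make_peak_track(
            40_000,
            [(10_000, 80.0, 10.0), (30_000, 300.0, 8.0)],
            noise_rate=1.0,
            seed=6,
        )
        scaled = track.copy()
        for arrays in scaled.contigs.values():
            for vec in arrays.values():
                vec.scale(3.0)
        p1 = call_peaks_from_tracks(track, bin_size=10)
        p2 = call_peaks_from_tracks(scaled, bin_size=10)
        assert [(p.summit, p.ridge_length) for p in p1] == [
            (p.summit, p.ridge_length) for p in p2
        ]

    def test_isolated_ridge_longer_than_crowded(self):
        """An isolated peak's ridge outlasts the same peak crowded by an
        equal neighbor at 1.5x its width."""
        width, amp = 300.0, 30.0  # full width at half maximum, bases
        iso, _ = make_peak_track(60_000, [(30_000, width, amp)], 0.0, seed=7)
        crowd, _ = make_peak_track(
            60_000,
            [(int(30_000 - 1.5 * width), width, amp), (30_000, width, amp)],
            0.0,
            seed=7,
        )
        def ridge_len_at(track, center):
            peaks = call_peaks_from_tracks(
                track, bin_size=10, min_signal=1.0, min_ridge_length=1
            )
            best = min(peaks, key=lambda p: abs(p.summit - center))
            return best.ridge_length
        assert ridge_len_at(iso, 30_000) > ridge_len_at(crowd, 30_000)

    def test_auto_threshold_homogeneous(self, rng):
        v = np.abs(rng.normal(size=500)) + 1
        assert auto_min_signal(3 * v) == pytest.approx(3 * auto_min_signal(v))


class TestGaussianSmoothPeaks:
    def test_flat_no_peaks(self):
        sig = SmoothedTrack("c", 1, np.full(200, 2.0))
        assert gaussian_smooth_peaks(sig, 4.0, min_signal=3.0) == []

    def test_single_bump(self):
        x = np.arange(600)
        sig = SmoothedTrack("c", 1, 10 * np.exp(-((x - 300) ** 2) / (2 * 25.0**2)))
        peaks = gaussian_smooth_peaks(sig, 5.0, min_signal=1.0)
        assert len(peaks) == 1 and abs(peaks[0].summit - 300) <= 3

    def test_merge_behavior(self):
        x = np.arange(2000)
        two = 10 * (
            np.exp(-((x - 600) ** 2) / (2 * 20.0**2))
            + np.exp(-((x - 1400) ** 2) / (2 * 20.0**2))
        )
        close = 10 * (
            np.exp(-((x - 990) ** 2) / (2 * 20.0**2))
            + np.exp(-((x - 1010) ** 2) / (2 * 20.0**2))
        )
        far_peaks = gaussian_smooth_peaks(
            SmoothedTrack("c", 1, two), 10.0, min_signal=1.0
        )
        near_peaks = gaussian_smooth_peaks(
            SmoothedTrack("c", 1, close), 40.0, min_signal=1.0
        )
        assert len(far_peaks) == 2
        assert len(near_peaks) == 1
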