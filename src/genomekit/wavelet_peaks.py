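"""Multiscale wavelet ridge-line ChIP-seq peak calling.

The method addresses the core difficulty of peak detection — peaks come in a
wide range of widths and heights — by smoothing the (optionally
control-subtracted) coverage with a translation-invariant wavelet at a ladder
of scales, finding local maxima of the coefficients at every scale, and
linking maxima across adjacent scales into *ridge lines*.  A genuine,
isolated enrichment shows up as a maximum at many scales, so its ridge is
long; noise spikes and crowded signal produce short ridges.  Putative peaks
are therefore ranked by ridge length, and optional filters drop low-signal
peaks and single-bin spikes.

Pipeline (each stage is a public function):

1. :func:`prepare_signal`  — bin, normalize to reads-per-million, subtract
   the scaled control (floored at zero), optionally pre-smooth.
2. :func:`cwt_scales`      — dense Ricker (Mexican-hat) transform at a
   dyadic scale ladder, reflective boundaries.
3. :func:`find_scale_maxima` — windowed strict local maxima per scale.
4. :func:`link_ridges`     — greedy largest-to-smallest-scale linking with a
   per-scale position tolerance and a consecutive-gap budget.
5. :func:`call_peaks`      — summit, boundaries, score and filters.

Scale convention: the scale parameter is the sigma (in bases) of the
Gaussian bump the wavelet responds to maximally; the internal Ricker width
is sqrt(2)*scale and the kernel is amplitude-normalized so a matched bump of
any width yields the same coefficient (~0.965 * bump amplitude).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .coverage_engine import CoverageTrack
from .errors import ContractError
from .interval_algebra import GenomicInterval

log = logging.getLogger("genomekit.wavelet")

#: Default dyadic scale ladder, in bases.
DEFAULT_SCALES = tuple(2**k for k in range(1, 11))  # 2 .. 1024


@dataclass
class SmoothedTrack:
    """Binned, background-corrected, non-negative signal for one contig."""

    contig: str
    bin_size: int
    values: np.ndarray
    kernel: str = "none"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ContractError("signal contains non-finite values")
        if np.any(self.values < 0):
            raise ContractError("signal contains negative values")


@dataclass
class ScaleMaxima:
    """Local maxima of the wavelet coefficients at one scale (bin indices)."""

    scale: float  # bases
    positions: np.ndarray
    coefficients: np.ndarray


@dataclass
class RidgePoint:
    scale: float  # bases
    position: int  # bin index
    coefficient: float


@dataclass
class RidgeLine:
    """Chain of per-scale maxima, ordered from largest to smallest scale."""

    points: List[RidgePoint]

    @property
    def length(self) -> int:
        return len(self.points)

    @property
    def summit(self) -> int:
        """Position at the smallest scale present in the chain."""
        return self.points[-1].position

    @property
    def best_point(self) -> RidgePoint:
        return max(self.points, key=lambda p: p.coefficient)

    @property
    def best_scale(self) -> float:
        return self.best_point.scale

    @property
    def score(self) -> float:
        return float(self.length)


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int  # bases
    score: float
    ridge_length: int
    best_scale: float
    max_height: float
    filtered_reason: str = "none"  # none | low_signal | spike


# ---------------------------------------------------------------------------
# 1. Signal preparation
# ---------------------------------------------------------------------------


def _bin_track(track: CoverageTrack, contig: str, bin_size: int) -> np.ndarray:
    length = track.length_of(contig)
    nbins = -(-length // bin_size) if length else 0
    out = np.zeros(max(nbins, 1))
    vec = track.array(contig, "total")
    for pos, value in vec.items():
        b = pos // bin_size
        if b >= len(out):  # positions beyond the declared length
            out = np.concatenate([out, np.zeros(b + 1 - len(out))])
        out[b] += value
    return out


def prepare_signal(
    sample: CoverageTrack,
    control: Optional[CoverageTrack] = None,
    bin_size: int = 10,
    kernel: Union[str, Tuple[str, float]] = "none",
) -> Dict[str, SmoothedTrack]:
    """Bin, RPM-normalize, control-subtract (floor 0) and smooth per contig.

    ``kernel`` is ``"none"``, ``("gaussian", bandwidth_bins)`` or
    ``("box", width_bins)``.  Both tracks must have counted at least one
    read (RPM normalization is undefined otherwise).
    """
    if bin_size < 1:
        raise ContractError(f"bin_size must be >= 1, got {bin_size}")
    if sample.reads_counted == 0:
        raise ContractError("sample track has zero counted reads")
    if control is not None and control.reads_counted == 0:
        raise ContractError("control track has zero counted reads")
    contigs = set(sample.contigs) | (set(control.contigs) if control else set())
    out: Dict[str, SmoothedTrack] = {}
    for contig in sorted(contigs):
        s = _bin_track(sample, contig, bin_size) * (1e6 / sample.reads_counted)
        if control is not None:
            c = _bin_track(control, contig, bin_size) * (1e6 / control.reads_counted)
            n = max(len(s), len(c))
            s = np.pad(s, (0, n - len(s)))
            c = np.pad(c, (0, n - len(c)))
            s = np.maximum(s - c, 0.0)
        kname = "none"
        if kernel not in (None, "none"):
            kname, param = kernel
            if kname == "gaussian":
                s = gaussian_filter1d(s, sigma=float(param), mode="reflect")
            elif kname == "box":
                s = uniform_filter1d(s, size=int(param), mode="reflect")
            else:
                raise ContractError(f"unknown kernel {kname!r}")
            s = np.maximum(s, 0.0)
        out[contig] = SmoothedTrack(contig, bin_size, s, kname)
    return out


# ---------------------------------------------------------------------------
# 2. Dense Ricker transform
# ---------------------------------------------------------------------------


def ricker_kernel(scale_bins: float) -> np.ndarray:
    """Zero-mean Ricker kernel matched to a Gaussian bump of sigma
    ``scale_bins``; amplitude-normalized so the matched response is
    scale-independent."""
    if scale_bins <= 0:
        raise ContractError(f"scale must be positive, got {scale_bins}")
    b = math.sqrt(2.0) * scale_bins
    half = max(1, int(math.ceil(5.0 * b)))
    x = np.arange(-half, half + 1, dtype=float)
    u2 = (x / b) ** 2
    k = (1.0 - u2) * np.exp(-u2 / 2.0) / b
    k -= k.mean()  # exact zero response to constant signal despite truncation
    return k


def _convolve_reflect(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = (len(kernel) - 1) // 2
    padded = np.pad(values, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def cwt_scales(
    signal: SmoothedTrack,
    scales: Optional[Sequence[float]] = None,
) -> Dict[float, np.ndarray]:
    """Ricker coefficients at each scale (bases); output length equals the
    signal length at every scale (dense transform ⇒ translation invariance).

    Scales finer than one bin, or whose kernel exceeds the signal length, are
    skipped with a warning.
    """
    if scales is None:
        scales = DEFAULT_SCALES
    scales = sorted(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise ContractError("scales must be positive")
    n = len(signal.values)
    out: Dict[float, np.ndarray] = {}
    for scale in scales:
        sb = scale / signal.bin_size
        if sb < 1.0:
            log.warning(
                "%s: scale %g bases is below one bin (%d bases); skipped",
                signal.contig, scale, signal.bin_size,
            )
            continue
        kern = ricker_kernel(sb)
        if len(kern) // 2 >= n:
            log.warning(
                "%s: scale %g bases exceeds signal length %d bins; skipped",
                signal.contig, scale, n,
            )
            continue
        out[scale] = _convolve_reflect(signal.values, kern)
    return out


# ---------------------------------------------------------------------------
# 3. Per-scale local maxima
# ---------------------------------------------------------------------------


def windowed_maxima(
    values: np.ndarray, window: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Indices that strictly dominate a centered window of width ``window``.

    A position wins if it exceeds everything to its left in the window and is
    >= everything to its right (so a plateau resolves to its leftmost bin).
    Positions whose window is truncated by an array edge are excluded.
    """
    half = window // 2
    n = len(values)
    if n < 2 * half + 1:
        return np.array([], dtype=int), np.array([], dtype=float)
    sw = np.lib.stride_tricks.sliding_window_view(values, 2 * half + 1)
    centers = np.arange(half, n - half)
    center_vals = values[centers]
    left_max = sw[:, :half].max(axis=1) if half else np.full(len(sw), -np.inf)
    right_max = sw[:, half + 1:].max(axis=1) if half else np.full(len(sw), -np.inf)
    keep = (center_vals > left_max) & (center_vals >= right_max)
    return centers[keep], center_vals[keep]


def find_scale_maxima(
    coefficients: Dict[float, np.ndarray],
    min_separation_factor: float = 1.0,
    bin_size: int = 1,
) -> List[ScaleMaxima]:
    """Local maxima per scale, window width max(3, round(factor * scale_bins));
    returned ordered from largest to smallest scale (ready for linking)."""
    out: List[ScaleMaxima] = []
    for scale in sorted(coefficients, reverse=True):
        sb = scale / bin_size
        window = max(3, int(round(min_separation_factor * sb)))
        if window % 2 == 0:
            window += 1
        pos, val = windowed_maxima(coefficients[scale], window)
        out.append(ScaleMaxima(scale, pos, val))
    return out


# ---------------------------------------------------------------------------
# 4. Ridge linking
# ---------------------------------------------------------------------------


def link_ridges(
    maxima: Sequence[ScaleMaxima],
    gap_tolerance: int = 2,
    position_tolerance_factor: float = 0.5,
    bin_size: int = 1,
) -> List[RidgeLine]:
    """Greedy largest-to-smallest-scale linking of maxima into ridge lines.

    Every active ridge tries to extend to the nearest unclaimed maximum at
    the next scale within ``position_tolerance_factor * current_scale_bins``
    of its current position.  Ridges compete in priority order (larger
    current coefficient, then longer current length, then smaller position);
    a miss increments a consecutive-gap counter and the ridge dies once the
    counter exceeds ``gap_tolerance``.  Unclaimed maxima seed new ridges.
    Every maximum belongs to exactly one ridge.
    """
    ridges: List[dict] = []
    for level, sm in enumerate(maxima):
        claimed = np.zeros(len(sm.positions), dtype=bool)
        active = [r for r in ridges if r["alive"]]
        # priority: larger current coefficient, longer ridge, smaller position
        active.sort(
            key=lambda r: (-r["points"][-1].coefficient,
                           -len(r["points"]),
                           r["points"][-1].position)
        )
        positions = sm.positions  # ascending (windowed_maxima output order)
        for r in active:
            cur = r["points"][-1]
            tol = position_tolerance_factor * (cur.scale / bin_size)
            best_j = -1
            best_key: Tuple[float, int] = (math.inf, 0)
            if len(positions):
                # scan outward from the insertion point; stop each direction
                # at the first unclaimed candidate (positions are sorted, so
                # it is the nearest one on that side)
                k = int(np.searchsorted(positions, cur.position))
                for j in range(k, len(positions)):
                    d = int(positions[j]) - cur.position
                    if d > tol:
                        break
                    if not claimed[j]:
                        best_key = (d, int(positions[j]))
                        best_j = j
                        break
                for j in range(k - 1, -1, -1):
                    d = cur.position - int(positions[j])
                    if d > tol:
                        break
                    if not claimed[j]:
                        if (d, int(positions[j])) < best_key:
                            best_key = (d, int(positions[j]))
                            best_j = j
                        break
            if best_j >= 0:
                claimed[best_j] = True
                r["points"].append(
                    RidgePoint(
                        sm.scale,
                        int(sm.positions[best_j]),
                        float(sm.coefficients[best_j]),
                    )
                )
                r["gap"] = 0
            else:
                r["gap"] += 1
                if r["gap"] > gap_tolerance:
                    r["alive"] = False
        for j, p in enumerate(sm.positions):
            if not claimed[j]:
                ridges.append(
                    {
                        "points": [
                            RidgePoint(
                                sm.scale, int(p), float(sm.coefficients[j])
                            )
                        ],
                        "gap": 0,
                        "alive": True,
                    }
                )
    return [RidgeLine(r["points"]) for r in ridges]


# ---------------------------------------------------------------------------
# 5. Peak calling
# ---------------------------------------------------------------------------


def auto_min_signal(values: np.ndarray, n_sigma: float = 5.0) -> float:
    """Data-adaptive low-signal threshold: median + n_sigma * 1.4826 * MAD.

    Positively homogeneous (scaling the signal scales the threshold), so it
    preserves the amplitude-monotonicity invariant.  Falls back to the mean +
    n_sigma * SD when the MAD degenerates to zero.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad > 0:
        return med + n_sigma * 1.4826 * mad
    sd = float(values.std())
    return float(values.mean()) + n_sigma * sd


def _half_max_bounds(
    values: np.ndarray,
    summit: int,
    min_signal: float,
    cap_bins: int,
) -> Tuple[int, int]:
    """Nearest positions around the summit where the signal falls below half
    the summit height (or a local minimum below min_signal), capped."""
    height = values[summit]
    half = height / 2.0
    lo = max(0, summit - cap_bins)
    hi = min(len(values) - 1, summit + cap_bins)
    left = summit
    while left > lo:
        v = values[left - 1]
        if v < half:
            break
        if v < min_signal and left - 2 >= 0 and values[left - 2] >= v:
            break
        left -= 1
    right = summit
    while right < hi:
        v = values[right + 1]
        if v < half:
            break
        if v < min_signal and right + 2 < len(values) and values[right + 2] >= v:
            break
        right += 1
    return left, right


def _fwhm_bins(values: np.ndarray, summit: int) -> int:
    """Width at half maximum around the summit, in bins."""
    half = values[summit] / 2.0
    left = summit
    while left > 0 and values[left - 1] >= half:
        left -= 1
    right = summit
    while right < len(values) - 1 and values[right + 1] >= half:
        right += 1
    return right - left + 1


def call_peaks(
    signal: SmoothedTrack,
    ridges: Sequence[RidgeLine],
    min_ridge_length: int = 3,
    min_signal: Union[float, str] = "auto",
    max_spike_sharpness: Optional[float] = 2.0,
    keep_filtered: bool = False,
) -> List[Peak]:
    """Turn ridge lines into ranked peaks.

    Ridges shorter than ``min_ridge_length`` are discarded outright.  Each
    surviving ridge yields a candidate peak at its smallest-scale position;
    the low-signal filter drops candidates whose smoothed signal at the
    summit is below ``min_signal`` ('auto' = median + 5*1.4826*MAD), and the
    spike filter drops candidates whose full width at half maximum is below
    ``max_spike_sharpness`` bins (None disables it).  Overlapping candidates
    are non-maximum suppressed (a lower-ranked summit inside a kept peak's
    interval is dropped).  Output is sorted by descending score (ridge
    length, best-coefficient tiebreak) then position.
    """
    values = signal.values
    thr = (
        auto_min_signal(values) if isinstance(min_signal, str) else float(min_signal)
    )
    candidates: List[Peak] = []
    for ridge in ridges:
        if ridge.length < min_ridge_length:
            continue
        summit_bin = ridge.summit
        if not 0 <= summit_bin < len(values):
            continue
        height = float(values[summit_bin])
        best = ridge.best_point
        cap_bins = max(1, int(round(2.0 * best.scale / signal.bin_size)))
        reason = "none"
        if height < thr:
            reason = "low_signal"
        elif max_spike_sharpness is not None:
            if _fwhm_bins(values, summit_bin) < max_spike_sharpness:
                reason = "spike"
        left, right = _half_max_bounds(values, summit_bin, thr, cap_bins)
        interval = GenomicInterval(
            signal.contig,
            left * signal.bin_size,
            (right + 1) * signal.bin_size,
            ".",
        )
        candidates.append(
            Peak(
                interval=interval,
                summit=summit_bin * signal.bin_size + signal.bin_size // 2,
                score=ridge.score,
                ridge_length=ridge.length,
                best_scale=best.scale,
                max_height=height,
                filtered_reason=reason,
            )
        )
    candidates.sort(
        key=lambda p: (-p.score, -p.max_height, p.interval.start, p.summit)
    )
    kept: List[Peak] = []
    surviving: List[Peak] = []
    for p in candidates:
        if p.filtered_reason != "none":
            if keep_filtered:
                kept.append(p)
            continue
        if any(
            s.interval.start <= p.summit < s.interval.end for s in surviving
        ):
            continue  # suppressed duplicate call on the same bump
        surviving.append(p)
    out = surviving + kept if keep_filtered else surviving
    out.sort(key=lambda p: (-p.score, -p.max_height, p.summit))
    return out


def gaussian_smooth_peaks(
    signal: SmoothedTrack,
    bandwidth: float,
    min_signal: Union[float, str] = "auto",
) -> List[Peak]:
    """Single-scale alternative: Gaussian smoothing + strict local maxima.

    Provided for comparison with the multiscale method; same Peak contract
    (ridge_length 1, score = smoothed height).
    """
    if bandwidth <= 0:
        raise ContractError(f"bandwidth must be positive, got {bandwidth}")
    sm = gaussian_filter1d(signal.values, sigma=bandwidth, mode="reflect")
    thr = auto_min_signal(sm) if isinstance(min_signal, str) else float(min_signal)
    pos, _ = windowed_maxima(sm, 3)
    peaks: List[Peak] = []
    for p in pos:
        height = float(sm[p])
        if height < thr:
            continue
        cap = max(1, int(round(4 * bandwidth)))
        left, right = _half_max_bounds(sm, int(p), thr, cap)
        peaks.append(
            Peak(
                interval=GenomicInterval(
                    signal.contig,
                    left * signal.bin_size,
                    (right + 1) * signal.bin_size,
                    ".",
                ),
                summit=int(p) * signal.bin_size + signal.bin_size // 2,
                score=height,
                ridge_length=1,
                best_scale=bandwidth * signal.bin_size,
                max_height=height,
            )
        )
    peaks.sort(key=lambda pk: (-pk.score, pk.summit))
    return peaks


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def call_peaks_from_tracks(
    sample: CoverageTrack,
    control: Optional[CoverageTrack] = None,
    bin_size: int = 10,
    kernel: Union[str, Tuple[str, float]] = "none",
    scales: Optional[Sequence[float]] = None,
    min_separation_factor: float = 1.0,
    gap_tolerance: int = 2,
    position_tolerance_factor: float = 0.5,
    min_ridge_length: int = 3,
    min_signal: Union[float, str] = "auto",
    max_spike_sharpness: Optional[float] = 2.0,
    keep_filtered: bool = False,
) -> List[Peak]:
    """Run the full multiscale pipeline over every contig of a track pair."""
    signals = prepare_signal(sample, control, bin_size, kernel)
    peaks: List[Peak] = []
    for contig in sorted(signals):
        sig = signals[contig]
        coeffs = cwt_scales(sig, scales)
        if not coeffs:
            continue
        maxima = find_scale_maxima(coeffs, min_separation_factor, sig.bin_size)
        ridges = link_ridges(
            maxima, gap_tolerance, position_tolerance_factor, sig.bin_size
        )
        peaks.extend(
            call_peaks(
                sig,
                ridges,
                min_ridge_length,
                min_signal,
                max_spike_sharpness,
                keep_filtered,
            )
        )
    peaks.sort(key=lambda p: (-p.score, -p.max_height, p.interval.chrom, p.summit))
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path, comment_lines=None) -> None:
    """BED6: chrom, start, end, name, score (ridge length), strand '.'."""
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        for k, p in enumerate(peaks, start=1):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{k}\t"
                f"{int(p.score)}\t.\n"
            )


def write_peaks_detail(peaks: Sequence[Peak], path, comment_lines=None) -> None:
    """Detail TSV: summit, ridge length, best scale, height, filter reason."""
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        fh.write(
            "chrom\tstart\tend\tsummit\tridge_length\tbest_scale\t"
            "height\tfilter_reason\n"
        )
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.summit}\t"
                f"{p.ridge_length}\t{p.best_scale:g}\t{p.max_height:.6g}\t"
                f"{p.filtered_reason}\n"
            )
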