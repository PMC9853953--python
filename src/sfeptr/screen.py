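"""Ion classification from extracted ion profiles.

Sample-derived ions elute from the extraction vessel as a broad bell-shaped
pulse; reagent and instrumental background ions hold a steady level early
in the run and decay once the sample plug arrives. Classification therefore
reduces to: (1) does the XIC contain a bell (peak with adequate S/N that
falls below half height on both sides)? → sample; (2) otherwise, does the
trace start high and decay? → background; (3) otherwise unclassified.
Ions also present in a blank run (no cell on the frit) within a small m/z
tolerance are re-flagged blank_matched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import ExtractionProfile, IonRecord

__all__ = [
    "ElutionPeak",
    "IonRecord",
    "detect_elution_peak",
    "classify_ion",
    "match_blank",
]


@dataclass
class ElutionPeak:
    apex_time: float  # s
    apex_counts: float  # smoothed counts/scan at apex
    half_height_start: float  # s
    half_height_end: float  # s
    fwhm: float  # s
    area_counts: int  # raw counts summed inside the half-height window


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    window = max(1, int(window))
    kernel = np.ones(window) / window
    # reflect-pad so the ends are averaged over real data only
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")
    return sm[pad : pad + len(x)] if pad else sm


def detect_elution_peak(
    profile: ExtractionProfile,
    smoothing_window: int = 5,
    snr_min: float = 3.0,
) -> ElutionPeak | None:
    """Find a bell-shaped elution peak in an XIC, or None.

    The trace is smoothed by a moving average; the global maximum is the
    apex candidate. Baseline is the median of the smoothed trace. The peak
    is accepted iff (apex − baseline)/sqrt(baseline + 1) ≥ snr_min and the
    smoothed trace falls below half of (apex − baseline) on both sides of
    the apex within the run; half-height crossings are located by linear
    interpolation. The reported area sums the RAW counts between the two
    half-height times.
    """
    counts = np.asarray(profile.counts, dtype=float)
    times = np.asarray(profile.times, dtype=float)
    if len(counts) < 5:
        return None
    sm = _moving_average(counts, smoothing_window)
    apex_idx = int(np.argmax(sm))
    baseline = float(np.median(sm))
    # apex height from a local average around the argmax: the raw maximum of
    # a noisy trace overshoots, which would bias the half level up and the
    # half-height window narrow
    w = max(1, int(smoothing_window))
    lo, hi = max(0, apex_idx - w), min(len(sm), apex_idx + w + 1)
    apex_height = float(np.mean(sm[lo:hi]))
    height = apex_height - baseline
    if height <= 0 or height / np.sqrt(baseline + 1.0) < snr_min:
        return None
    half = baseline + height / 2.0

    def _cross(direction: int) -> float | None:
        i = apex_idx
        while 0 <= i + direction < len(sm):
            j = i + direction
            if sm[j] < half:
                # linear interpolation between scans i and j
                frac = (sm[i] - half) / (sm[i] - sm[j])
                return float(times[i] + frac * (times[j] - times[i]))
            i = j
        return None

    t_left = _cross(-1)
    t_right = _cross(+1)
    if t_left is None or t_right is None:
        return None
    # a bell returns to baseline outside its half-height window; a decaying
    # background trace (or a noise spike riding on one) stays elevated on
    # at least one side
    shoulder_max = baseline + height / 4.0
    for outside in (sm[times < t_left], sm[times > t_right]):
        if len(outside) and float(np.mean(outside)) >= shoulder_max:
            return None
    window = (times >= t_left) & (times <= t_right)
    return ElutionPeak(
        apex_time=float(times[apex_idx]),
        apex_counts=float(sm[apex_idx]),
        half_height_start=t_left,
        half_height_end=t_right,
        fwhm=t_right - t_left,
        area_counts=int(counts[window].sum()),
    )


def classify_ion(
    profile: ExtractionProfile,
    smoothing_window: int = 5,
    snr_min: float = 3.0,
    decay_ratio: float = 2.0,
) -> tuple[str, ElutionPeak | None]:
    """Classify an XIC as sample, background, or unclassified.

    sample: a qualifying elution peak exists. background: no peak, but the
    mean of the first decile of scans exceeds ``decay_ratio`` times the
    mean of the last decile (and is nonzero) — the start-high-then-decay
    signature of reagent/instrumental ions. Otherwise unclassified.
    """
    if len(profile.counts) == 0:
        raise ValueError("empty extraction profile")
    peak = detect_elution_peak(profile, smoothing_window, snr_min)
    if peak is not None:
        return "sample", peak
    n = len(profile.counts)
    k = max(1, n // 10)
    first = float(np.mean(profile.counts[:k]))
    last = float(np.mean(profile.counts[-k:]))
    if first > 0 and first > decay_ratio * last:
        return "background", None
    return "unclassified", None


def match_blank(
    sample_ions: list[IonRecord],
    blank_ions: list[IonRecord],
    tolerance_mda: float = 5.0,
) -> list[IonRecord]:
    """Flag sample-run ions that also appear in the blank run.

    Any ion with at least one blank ion within ±tolerance is reclassified
    ``blank_matched``; the nearest blank m/z (ties → lower m/z) is recorded
    for reporting. Other ions pass through untouched. Both input lists are
    expected sorted by m/z.
    """
    tol = tolerance_mda * 1e-3
    blank_mz = np.array(sorted(r.mz for r in blank_ions))
    out: list[IonRecord] = []
    for rec in sample_ions:
        if len(blank_mz) == 0:
            out.append(rec)
            continue
        idx = np.searchsorted(blank_mz, rec.mz)
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(blank_mz) and abs(blank_mz[j] - rec.mz) <= tol:
                d = abs(blank_mz[j] - rec.mz)
                # ties resolve to the lower m/z (j-1 checked first)
                if best is None or d < best[0]:
                    best = (d, float(blank_mz[j]))
        if best is not None:
            out.append(replace(rec, classification="blank_matched", matched_blank_mz=best[1]))
        else:
            out.append(rec)
    return out
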