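"""Spectrum-series container, co-addition, peak centroiding and XICs.

A run is a time-ordered list of centroided scans (one per TOF extraction
window, nominally every 0.15 s). Counts are integer ion counts; all
downstream statistics assume Poisson counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Scan:
    time: float  # s
    mz: np.ndarray  # Da, sorted ascending
    counts: np.ndarray  # nonnegative integers, same length


@dataclass
class SpectrumSeries:
    """Time series of centroided scans for one run, one polarity."""

    polarity: str  # "positive" | "negative"
    scan_interval: float  # s
    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("scan times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def total_counts(self) -> int:
        return int(sum(int(s.counts.sum()) for s in self.scans))


@dataclass
class CoaddedSpectrum:
    """Mass spectrum summed over a time range of a run."""

    mz: np.ndarray  # centroid m/z per bin, sorted
    counts: np.ndarray  # summed counts per bin
    t_start: float
    t_end: float
    bin_width_mda: float


@dataclass
class ExtractionProfile:
    """Extracted ion profile: counts vs time inside a narrow m/z window."""

    target_mz: float
    window_halfwidth_mda: float
    times: np.ndarray
    counts: np.ndarray

    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class IonRecord:
    """One observed ion from the co-added spectrum."""

    mz: float
    total_counts: int
    classification: str = "unclassified"  # sample | background | blank_matched | unclassified
    apex_time: float | None = None
    fwhm: float | None = None
    area_counts: int | None = None
    matched_blank_mz: float | None = None


def coadd(
    series: SpectrumSeries,
    t_start: float | None = None,
    t_end: float | None = None,
    bin_width_mda: float = 5.0,
) -> CoaddedSpectrum:
    """Co-add scans in [t_start, t_end] onto an m/z grid of bin_width_mda.

    Counts in each bin are summed; the bin's reported m/z is the
    counts-weighted centroid, so total counts are conserved exactly.
    An empty time range yields an empty spectrum.
    """
    times = series.times
    if t_start is None:
        t_start = float(times[0]) if len(times) else 0.0
    if t_end is None:
        t_end = float(times[-1]) if len(times) else 0.0
    if t_start > t_end:
        raise ValueError("t_start must be <= t_end")
    mzs, cts = [], []
    for scan in series.scans:
        if t_start <= scan.time <= t_end and len(scan.mz):
            mzs.append(scan.mz)
            cts.append(scan.counts)
    if not mzs:
        return CoaddedSpectrum(np.array([]), np.array([]), t_start, t_end, bin_width_mda)
    mz = np.concatenate(mzs)
    counts = np.concatenate(cts).astype(np.int64)
    bw = bin_width_mda * 1e-3
    bins = np.round(mz / bw).astype(np.int64)
    uniq, inv = np.unique(bins, return_inverse=True)
    csum = np.bincount(inv, weights=counts)
    wsum = np.bincount(inv, weights=counts * mz)
    nonzero = csum > 0
    centroid = np.where(nonzero, wsum / np.maximum(csum, 1), uniq * bw)
    order = np.argsort(centroid)
    return CoaddedSpectrum(
        mz=centroid[order],
        counts=csum[order].astype(np.int64),
        t_start=t_start,
        t_end=t_end,
        bin_width_mda=bin_width_mda,
    )


def detect_mass_peaks(spectrum: CoaddedSpectrum, min_counts: int = 100) -> list[IonRecord]:
    """Threshold + merge the co-added bins into a sorted ion list.

    Bins whose centroids sit closer than one bin width are merged by
    counts-weighted centroid (an ion whose jitter straddles a bin edge
    splits across two adjacent bins); merged peaks below ``min_counts``
    are dropped. Output is strictly sorted in m/z with no pair closer
    than one bin width.
    """
    if min_counts < 1:
        raise ValueError("min_counts must be >= 1")
    bw = spectrum.bin_width_mda * 1e-3
    records: list[IonRecord] = []
    cur_w = cur_c = 0.0
    for mz, c in zip(spectrum.mz, spectrum.counts):
        if cur_c and mz - (cur_w / cur_c) < bw:
            cur_w += mz * c
            cur_c += c
        else:
            if cur_c >= min_counts:
                records.append(IonRecord(mz=cur_w / cur_c, total_counts=int(cur_c)))
            cur_w, cur_c = mz * c, float(c)
    if cur_c >= min_counts:
        records.append(IonRecord(mz=cur_w / cur_c, total_counts=int(cur_c)))
    return records


def extract_ion_profile(
    series: SpectrumSeries,
    target_mz: float,
    window_halfwidth_mda: float = 5.0,
) -> ExtractionProfile:
    """Counts-vs-time trace for |mz − target| ≤ window_halfwidth.

    Two co-eluting ions inside the window sum; the profile is their total.
    """
    if window_halfwidth_mda <= 0:
        raise ValueError("window_halfwidth_mda must be > 0")
    hw = window_halfwidth_mda * 1e-3
    counts = np.zeros(series.n_scans, dtype=np.int64)
    for i, scan in enumerate(series.scans):
        if len(scan.mz):
            lo = np.searchsorted(scan.mz, target_mz - hw, side="left")
            hi = np.searchsorted(scan.mz, target_mz + hw, side="right")
            counts[i] = scan.counts[lo:hi].sum()
    return ExtractionProfile(
        target_mz=target_mz,
        window_halfwidth_mda=window_halfwidth_mda,
        times=series.times,
        counts=counts,
    )


def rescale_mz(series: SpectrumSeries, factor: float) -> SpectrumSeries:
    """New series with every m/z multiplied by ``factor`` (lock-mass use)."""
    scans = [Scan(s.time, s.mz * factor, s.counts.copy()) for s in series.scans]
    meta = dict(series.metadata)
    return SpectrumSeries(series.polarity, series.scan_interval, scans, meta)
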