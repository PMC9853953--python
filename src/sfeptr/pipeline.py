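"""End-to-end screening pipeline: simulate → screen → annotate → quantify.

The functions here are what the CLI wraps. Each takes paths plus a
PipelineConfig, runs the library stages in order (lock-mass correction,
co-addition, peak detection, per-ion XIC classification, blank matching,
formula annotation), and writes plain-text reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .annotate import enumerate_candidates, match_ions, normalize_structures
from .mass_axis import LOCKMASS_REFERENCES, LockMassReference, lock_mass_correct
from .quantify import estimate_amount, fit_response, replicate_summary
from .screen import classify_ion, match_blank
from .spectra import IonRecord, SpectrumSeries, coadd, detect_mass_peaks, extract_ion_profile
from .synthetic import SyntheticIonSpec, SyntheticRunConfig, generate_blank_run, generate_run


@dataclass
class PipelineConfig:
    """Tolerances and knobs for the screening pipeline.

    Defaults: blank match ±5 mDa, annotation ±3 mDa, LOQ at 100 counts.
    """

    polarity: str = "positive"
    blank_match_mda: float = 5.0
    annotate_mda: float = 3.0
    loq_counts: float = 100.0
    coadd_bin_mda: float = 5.0
    xic_halfwidth_mda: float = 5.0
    min_peak_counts: int = 100
    snr_min: float = 3.0
    smoothing_window: int = 5
    lockmass: str | None = None  # label in LOCKMASS_REFERENCES, or None to skip
    lockmass_window_mda: float = 20.0
    annotate_gate: str = "fixed"  # or "replicate_sd"
    include_ammonium: bool = False

    def __post_init__(self) -> None:
        for name in ("blank_match_mda", "annotate_mda", "loq_counts", "coadd_bin_mda", "xic_halfwidth_mda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(overrides)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def example_run_config(
    seed: int = 0,
    polarity: str = "positive",
    duration: float = 240.0,
) -> SyntheticRunConfig:
    """A study-like synthetic run: lock-mass + reagent background + lipid ions.

    Sample ions elute as ~10 s-sigma bells centered mid-run; background and
    lock-mass ions hold a steady level and decay once the extraction pulse
    arrives (~60 s). m/z values are typical screened lipid ions.
    """
    if polarity == "positive":
        lock = LOCKMASS_REFERENCES["P321"]
        sample_mz = [263.237, 282.279, 296.258, 298.274, 300.063, 593.574]
        background_mz = [199.150, 279.159, 355.070]
    else:
        lock = LOCKMASS_REFERENCES["tetracosenoic"]
        sample_mz = [239.202, 299.202, 301.217, 303.233, 381.374]
        background_mz = [255.233, 311.169]
    ions = [
        SyntheticIonSpec(
            mz_true=lock.exact_mz,
            kind="lockmass",
            background_level=40.0,
            decay_onset=60.0,
            decay_rate=0.01,
        )
    ]
    rng = np.random.default_rng(seed + 977)  # layout stream, separate from the run stream
    for mz in sample_mz:
        ions.append(
            SyntheticIonSpec(
                mz_true=mz,
                kind="sample",
                amplitude=float(rng.uniform(2_000, 40_000)),
                elution_center=float(rng.uniform(0.4, 0.6) * duration),
                elution_width_sigma=float(rng.uniform(8.0, 14.0)),
            )
        )
    for mz in background_mz:
        ions.append(
            SyntheticIonSpec(
                mz_true=mz,
                kind="background",
                background_level=float(rng.uniform(4.0, 12.0)),
                decay_onset=60.0,
                decay_rate=float(rng.uniform(0.01, 0.03)),
            )
        )
    return SyntheticRunConfig(
        duration=duration,
        ions=tuple(ions),
        polarity=polarity,
        mass_jitter_sigma_mda=1.0,
        seed=seed,
    )


def cmd_simulate(
    out_dir: str | Path,
    seed: int = 0,
    polarity: str = "positive",
    blank: bool = False,
    run_config: SyntheticRunConfig | None = None,
) -> tuple[Path, Path]:
    """Generate a synthetic run; write run + ground-truth files. Returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = run_config or example_run_config(seed=seed, polarity=polarity)
    series, truth = (generate_blank_run if blank else generate_run)(config)
    tag = "blank" if blank else "sample"
    run_path = out_dir / f"run_{tag}_{polarity}_{seed}.csv"
    truth_path = out_dir / f"truth_{tag}_{polarity}_{seed}.tsv"
    sfio.write_run(series, run_path)
    sfio.write_ground_truth(truth, truth_path)
    return run_path, truth_path


def screen_series(
    sample: SpectrumSeries,
    blank: SpectrumSeries,
    config: PipelineConfig,
) -> list[IonRecord]:
    """Screen one sample run against its blank; returns classified ions."""
    if sample.polarity != blank.polarity:
        raise ValueError(
            f"polarity mismatch: sample is {sample.polarity}, blank is {blank.polarity}"
        )
    if config.lockmass:
        ref = LOCKMASS_REFERENCES[config.lockmass]
        sample = lock_mass_correct(sample, ref, config.lockmass_window_mda)
        blank = lock_mass_correct(blank, ref, config.lockmass_window_mda)

    records: list[IonRecord] = []
    spec = coadd(sample, bin_width_mda=config.coadd_bin_mda)
    for rec in detect_mass_peaks(spec, min_counts=config.min_peak_counts):
        profile = extract_ion_profile(sample, rec.mz, config.xic_halfwidth_mda)
        label, peak = classify_ion(profile, config.smoothing_window, config.snr_min)
        rec = replace(
            rec,
            classification=label,
            apex_time=peak.apex_time if peak else None,
            fwhm=peak.fwhm if peak else None,
            area_counts=peak.area_counts if peak else None,
        )
        records.append(rec)

    blank_spec = coadd(blank, bin_width_mda=config.coadd_bin_mda)
    blank_records = detect_mass_peaks(blank_spec, min_counts=config.min_peak_counts)
    return match_blank(records, blank_records, config.blank_match_mda)


def cmd_screen(
    sample_path: str | Path,
    blank_path: str | Path,
    report_path: str | Path,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """File-level wrapper around screen_series; writes the screening report."""
    config = config or PipelineConfig()
    sample = sfio.read_run(sample_path)
    blank = sfio.read_run(blank_path)
    records = screen_series(sample, blank, config)
    sfio.write_screening_report(records, report_path)
    return sfio.screening_report_frame(records)


def cmd_annotate(
    report_path: str | Path,
    sdf_path: str | Path,
    out_path: str | Path,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Annotate sample-classified ions from a screening report against an SDF."""
    config = config or PipelineConfig()
    report = sfio.read_screening_report(report_path)
    norm = normalize_structures(sdf_path)
    candidates = enumerate_candidates(
        norm.formulas, config.polarity, include_ammonium=config.include_ammonium
    )
    sample_rows = report[report["classification"] == "sample"]
    observed = [(float(mz), 0.0, 1) for mz in sorted(sample_rows["mz"])]
    matches = match_ions(observed, candidates, config.annotate_mda, config.annotate_gate)
    frame = sfio.annotation_report_frame(matches)
    frame.to_csv(out_path, sep="\t", index=False, float_format="%.6f")
    return frame


def cmd_quantify(
    points_path: str | Path,
    counts: list[float],
    out_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    label: str = "",
) -> pd.DataFrame:
    """Fit a response curve from a delimited (amount, area) table; convert counts.

    The output row per requested count value carries the estimated amount and
    the Poisson relative error; a replicate mean/RSD row is appended when two
    or more counts are given.
    """
    config = config or PipelineConfig()
    pts = pd.read_csv(points_path, sep=None, engine="python", comment="#")
    cols = list(pts.columns[:2])
    curve = fit_response(
        list(zip(pts[cols[0]].astype(float), pts[cols[1]].astype(float))),
        label=label,
        loq_counts=config.loq_counts,
    )
    rows = []
    for c in counts:
        est = estimate_amount(c, curve)
        rows.append(
            {
                "counts": c,
                "amount": est.amount,
                "relative_error": est.relative_error,
                "slope": curve.slope,
                "loq": curve.loq,
            }
        )
    frame = pd.DataFrame(rows)
    if len(counts) >= 2:
        mean, rsd = replicate_summary(counts)
        frame.attrs["replicate_mean"] = mean
        frame.attrs["replicate_rsd"] = rsd
    if out_path is not None:
        frame.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return frame
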