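"""Plain-text file formats for runs, ground truth, and reports.

A run is stored as a single CSV table (scan_index, time_s, mz, counts) with
run-level metadata in leading ``# key=value`` comment lines. Reports are
tab-separated with one documented header line. Everything is inspectable
with standard text tools.
"""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Scan, SpectrumSeries
from .synthetic import GroundTruth, GroundTruthEntry

RUN_MAGIC = "# sfeptr-run v1"


def write_run(series: SpectrumSeries, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for i, scan in enumerate(series.scans):
        for mz, c in zip(scan.mz, scan.counts):
            rows.append((i, scan.time, mz, int(c)))
    df = pd.DataFrame(rows, columns=["scan_index", "time_s", "mz", "counts"])
    with path.open("w") as fh:
        fh.write(RUN_MAGIC + "\n")
        fh.write(f"# polarity={series.polarity}\n")
        fh.write(f"# scan_interval={series.scan_interval!r}\n")
        fh.write(f"# n_scans={series.n_scans}\n")
        for k, v in series.metadata.items():
            fh.write(f"# meta.{k}={v!r}\n")
        df.to_csv(fh, index=False, float_format="%.9f")


def read_run(path: str | Path) -> SpectrumSeries:
    path = Path(path)
    meta: dict = {}
    polarity, scan_interval, n_scans = None, None, None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, val = body.partition("=")
            key = key.strip()
            if key == "polarity":
                polarity = val.strip()
            elif key == "scan_interval":
                scan_interval = float(ast.literal_eval(val))
            elif key == "n_scans":
                n_scans = int(val)
            elif key.startswith("meta."):
                try:
                    meta[key[5:]] = ast.literal_eval(val)
                except (ValueError, SyntaxError):
                    meta[key[5:]] = val.strip()
    if polarity is None or scan_interval is None or n_scans is None:
        raise ValueError(f"{path} is not a valid run file (missing header)")
    df = pd.read_csv(path, comment="#")
    scans: list[Scan] = []
    grouped = dict(tuple(df.groupby("scan_index")))
    # scans whose peaks were all zero-count still exist on the time grid
    for i in range(n_scans):
        if i in grouped:
            g = grouped[i].sort_values("mz")
            scans.append(
                Scan(
                    time=float(g["time_s"].iloc[0]),
                    mz=g["mz"].to_numpy(),
                    counts=g["counts"].to_numpy(dtype=np.int64),
                )
            )
        else:
            scans.append(Scan(time=i * scan_interval, mz=np.array([]), counts=np.array([], dtype=np.int64)))
    return SpectrumSeries(polarity=polarity, scan_interval=scan_interval, scans=scans, metadata=meta)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "mz_true": e.mz_true,
                "kind": e.kind,
                "total_counts": e.total_counts,
                "fwhm_window_counts": e.fwhm_window_counts,
                "true_amount": e.true_amount,
            }
            for e in truth.entries
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    entries = [
        GroundTruthEntry(
            mz_true=float(r.mz_true),
            kind=str(r.kind),
            total_counts=int(r.total_counts),
            fwhm_window_counts=None if pd.isna(r.fwhm_window_counts) else int(r.fwhm_window_counts),
            true_amount=None if pd.isna(r.true_amount) else float(r.true_amount),
        )
        for r in df.itertuples()
    ]
    return GroundTruth(entries)


def read_calibration_references(path: str | Path) -> list[tuple[float, float]]:
    """Delimited text with columns flight_time, mz (header optional)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.columns.dtype == object and not set(df.columns) >= {"flight_time", "mz"}:
        # headerless file: first row was data
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None, names=["flight_time", "mz"])
    return [(float(t), float(m)) for t, m in zip(df["flight_time"], df["mz"])]


def write_screening_report(records, path: str | Path) -> None:
    """TSV: mz, total_counts, classification, apex_time, fwhm, area, blank m/z."""
    df = screening_report_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def screening_report_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mz": r.mz,
                "total_counts": r.total_counts,
                "classification": r.classification,
                "apex_time_s": r.apex_time,
                "fwhm_s": r.fwhm,
                "area_counts": r.area_counts,
                "matched_blank_mz": r.matched_blank_mz,
            }
            for r in records
        ],
        columns=[
            "mz",
            "total_counts",
            "classification",
            "apex_time_s",
            "fwhm_s",
            "area_counts",
            "matched_blank_mz",
        ],
    )


def read_screening_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def annotation_report_frame(matches) -> pd.DataFrame:
    """Columns mirror the screening tables: m/z, SD, formula, species, +isomers, exact m/z."""
    return pd.DataFrame(
        [
            {
                "observed_mz": m.observed_mz_mean,
                "sd_mda": m.observed_sd_mda,
                "n": m.n_replicates,
                "formula": m.formula,
                "species": m.species,
                "isomer_extra": m.isomer_extra,
                "exact_mz": round(m.theoretical_mz, 3),
                "delta_m_mda": m.delta_m_mda,
            }
            for m in matches
        ],
        columns=[
            "observed_mz",
            "sd_mda",
            "n",
            "formula",
            "species",
            "isomer_extra",
            "exact_mz",
            "delta_m_mda",
        ],
    )
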