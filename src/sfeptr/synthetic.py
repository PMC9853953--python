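"""Synthetic SFE-PTR MS run generator with ground truth.

Emulates the behavior downstream stages rely on, without any instrument
physics: sample-derived ions elute as a Gaussian bell whose integral over
the scan grid is the ion's amplitude (expected total counts); reagent and
instrumental background ions (and the lock-mass reference) hold a constant
per-scan level until a decay onset, then decay exponentially as the sample
plug displaces them. Per-scan counts are Poisson; observed m/z is the true
m/z plus Gaussian jitter, passed through an optional polynomial mass-axis
distortion. Scans are already centroided (m/z, counts) pairs.

Draw order (fixed, documented for reproducibility): ions are processed in
list order; for each ion, first the per-scan Poisson counts vector, then
the per-scan m/z jitter vector, from one numpy Generator seeded from the
run config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from io import StringIO

import numpy as np

from .spectra import Scan, SpectrumSeries

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class SyntheticIonSpec:
    """One ion in a synthetic run."""

    mz_true: float  # Da
    kind: str  # "sample" | "background" | "lockmass"
    amplitude: float = 0.0  # expected total counts (sample ions)
    elution_center: float = 0.0  # s
    elution_width_sigma: float = 1.0  # s
    background_level: float = 0.0  # expected counts per scan (background/lockmass)
    decay_onset: float = 0.0  # s
    decay_rate: float = 0.0  # 1/s
    true_amount: float | None = None  # mol, optional

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "background", "lockmass"):
            raise ValueError(f"unknown ion kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.kind == "sample" and self.elution_width_sigma <= 0:
            raise ValueError("elution_width_sigma must be > 0 for sample ions")


@dataclass(frozen=True)
class SyntheticRunConfig:
    duration: float  # s
    ions: tuple[SyntheticIonSpec, ...]
    scan_interval: float = 0.15  # s
    polarity: str = "positive"
    mass_jitter_sigma_mda: float = 1.0
    #: ascending-power cubic applied to the jittered m/z; identity by default
    calibration_distortion: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0 or self.duration <= self.scan_interval:
            raise ValueError("require duration > scan_interval > 0")
        if self.mass_jitter_sigma_mda < 0:
            raise ValueError("mass_jitter_sigma_mda must be >= 0")
        if not self.ions:
            raise ValueError("ion list must not be empty")


@dataclass
class GroundTruthEntry:
    mz_true: float
    kind: str
    total_counts: int  # realized counts summed over all scans
    fwhm_window_counts: int | None  # realized counts inside the FWHM time window (sample only)
    true_amount: float | None = None


@dataclass
class GroundTruth:
    entries: list[GroundTruthEntry]

    def sample_ions(self) -> list[GroundTruthEntry]:
        return [e for e in self.entries if e.kind == "sample"]

    def background_ions(self) -> list[GroundTruthEntry]:
        return [e for e in self.entries if e.kind != "sample"]


def _mean_profile(ion: SyntheticIonSpec, times: np.ndarray) -> np.ndarray:
    """Expected counts per scan on the scan grid."""
    if ion.kind == "sample":
        w = np.exp(-0.5 * ((times - ion.elution_center) / ion.elution_width_sigma) ** 2)
        total = w.sum()
        return ion.amplitude * w / total if total > 0 else np.zeros_like(times)
    mean = np.full_like(times, float(ion.background_level))
    after = times > ion.decay_onset
    mean[after] *= np.exp(-ion.decay_rate * (times[after] - ion.decay_onset))
    return mean


def generate_run(config: SyntheticRunConfig) -> tuple[SpectrumSeries, GroundTruth]:
    """Simulate one run; returns the scan series and its hidden ground truth."""
    rng = np.random.default_rng(config.seed)
    n_scans = int(np.floor(config.duration / config.scan_interval))
    times = np.arange(n_scans) * config.scan_interval
    c0, c1, c2, c3 = config.calibration_distortion

    per_ion_counts, per_ion_mz = [], []
    entries = []
    for ion in config.ions:
        mean = _mean_profile(ion, times)
        counts = rng.poisson(mean)
        jitter = rng.normal(0.0, config.mass_jitter_sigma_mda * 1e-3, size=n_scans)
        m = ion.mz_true + jitter
        m = c0 + c1 * m + c2 * m**2 + c3 * m**3
        per_ion_counts.append(counts)
        per_ion_mz.append(m)
        fwhm_counts = None
        if ion.kind == "sample":
            half = 0.5 * GAUSSIAN_FWHM_FACTOR * ion.elution_width_sigma
            window = np.abs(times - ion.elution_center) <= half
            fwhm_counts = int(counts[window].sum())
        entries.append(
            GroundTruthEntry(
                mz_true=ion.mz_true,
                kind=ion.kind,
                total_counts=int(counts.sum()),
                fwhm_window_counts=fwhm_counts,
                true_amount=ion.true_amount,
            )
        )

    scans = []
    for i in range(n_scans):
        mz = np.array([per_ion_mz[j][i] for j in range(len(config.ions))])
        cts = np.array([per_ion_counts[j][i] for j in range(len(config.ions))], dtype=np.int64)
        keep = cts > 0
        order = np.argsort(mz[keep])
        scans.append(Scan(time=float(times[i]), mz=mz[keep][order], counts=cts[keep][order]))
    series = SpectrumSeries(
        polarity=config.polarity,
        scan_interval=config.scan_interval,
        scans=scans,
        metadata={"seed": config.seed, "synthetic": True},
    )
    return series, GroundTruth(entries)


def generate_blank_run(config: SyntheticRunConfig) -> tuple[SpectrumSeries, GroundTruth]:
    """The same run with the sample removed: only background and lock-mass ions.

    A config with no sample ions yields, at the same seed, exactly the
    generate_run output.
    """
    blank_ions = tuple(i for i in config.ions if i.kind != "sample")
    if not blank_ions:
        raise ValueError("blank run would contain no ions (no background/lockmass specified)")
    return generate_run(replace(config, ions=blank_ions))


# --- structure-database fixture -------------------------------------------

#: (name, SMILES) pool of lipophilic molecules for the synthetic SDF fixture.
#: The first four entries exercise every normalization branch: a plain lipid,
#: a sodium-salt form (disconnected counter-ion), a deuterium-labeled
#: variant, and a duplicate structure of the first entry.
_FIXTURE_CORE: list[tuple[str, str]] = [
    ("oleic acid", r"CCCCCCCC/C=C\CCCCCCCC(=O)O"),
    ("sodium oleate", r"CCCCCCCC/C=C\CCCCCCCC(=O)[O-].[Na+]"),
    ("oleic acid-d2", r"CCCCCCCC/C=C\CCCCCCC([2H])([2H])C(=O)O"),
    ("oleic acid (dup)", r"OC(=O)CCCCCCC/C=C\CCCCCCCC"),
]

_FIXTURE_POOL: list[tuple[str, str]] = [
    ("arachidonic acid", r"CCCCC/C=C\C/C=C\C/C=C\C/C=C\CCCC(=O)O"),
    ("eicosapentaenoic acid", r"CC/C=C\C/C=C\C/C=C\C/C=C\C/C=C\CCCC(=O)O"),
    ("linoleic acid", r"CCCCC/C=C\C/C=C\CCCCCCCC(=O)O"),
    ("alpha-linolenic acid", r"CC/C=C\C/C=C\C/C=C\CCCCCCCC(=O)O"),
    ("stearic acid", "CCCCCCCCCCCCCCCCCC(=O)O"),
    ("palmitic acid", "CCCCCCCCCCCCCCCC(=O)O"),
    ("palmitoleic acid", r"CCCCCC/C=C\CCCCCCCC(=O)O"),
    ("myristic acid", "CCCCCCCCCCCCCC(=O)O"),
    ("lauric acid", "CCCCCCCCCCCC(=O)O"),
    ("capric acid", "CCCCCCCCCC(=O)O"),
    ("arachidic acid", "CCCCCCCCCCCCCCCCCCCC(=O)O"),
    ("nervonic acid", r"CCCCCCCC/C=C\CCCCCCCCCCCCCC(=O)O"),
    ("pentadecylic acid", "CCCCCCCCCCCCCCC(=O)O"),
    ("dihomo-gamma-linolenic acid", r"CCCCC/C=C\C/C=C\C/C=C\CCCCCCC(=O)O"),
    # a positional isomer of arachidonic acid (same C20H32O2 formula)
    ("eicosatetraenoic acid (isomer)", r"CCCCCCC/C=C\C/C=C\C/C=C\C/C=C\CC(=O)O"),
    ("oleamide", r"CCCCCCCC/C=C\CCCCCCCC(=O)N"),
    ("monoolein", r"CCCCCCCC/C=C\CCCCCCCC(=O)OCC(O)CO"),
    ("cholesterol", r"CC(C)CCC[C@@H](C)[C@H]1CC[C@@H]2[C@@]1(CC[C@H]3[C@H]2CC=C4[C@@]3(CC[C@@H](C4)O)C)C"),
    ("retinol", r"CC1=C(C(CCC1)(C)C)/C=C/C(=C/C=C/C(=C/CO)/C)/C"),
    ("eicosadienoic acid", r"CCCCC/C=C\C/C=C\CCCCCCCCCC(=O)O"),
]


def make_structure_fixture(n_structures: int, seed: int = 0) -> str:
    """Generate an SDF (V2000) text of ``n_structures`` lipid-like records.

    The fixture is synthetic: a small stand-in for a lipid structure
    database. It always starts with the four normalization edge cases
    (plain acid, salt, isotope-labeled, duplicate) when ``n_structures``
    allows; the remainder is drawn from a fixed pool with a seeded RNG,
    so the same (n, seed) yields byte-identical output.
    """
    from rdkit import Chem
    from rdkit.Chem import rdDepictor

    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    picks = list(_FIXTURE_CORE[:n_structures])
    remaining = n_structures - len(picks)
    if remaining > 0:
        idx = rng.choice(len(_FIXTURE_POOL), size=remaining, replace=remaining > len(_FIXTURE_POOL))
        picks.extend(_FIXTURE_POOL[i] for i in idx)
    buf = StringIO()
    writer = Chem.SDWriter(buf)
    try:
        for name, smiles in picks:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # pool entries are all valid; guard anyway
                raise ValueError(f"bad fixture SMILES for {name}")
            rdDepictor.Compute2DCoords(mol)
            mol.SetProp("_Name", name)
            mol.SetProp("COMMON_NAME", name)
            writer.write(mol)
    finally:
        writer.close()
    return buf.getvalue()
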