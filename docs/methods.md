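# Methods

## Scope and data model

The pipeline consumes a *spectrum series*: centroided scans — (m/z, integer
ion counts) pairs — stored every `scan_interval` seconds (default 0.15 s)
for one acquisition polarity. The instrument's waveform-level acquisition
channels are not modeled; everything downstream operates on centroided
counts, which is the level at which the screening procedure is defined.
Charge states above 1 are out of scope (PTR water chemical ionization
yields singly charged species), as are isotope patterns (monoisotopic
peaks only) and MS/MS.

## Synthetic run generator

`sfeptr.synthetic.generate_run` emulates the features of SFE-PTR runs the
analysis depends on:

- **Sample ions** elute as a Gaussian bell. "Bell-shaped" is the only
  constraint the physical process imposes; the Gaussian is the simplest
  bell and makes the FWHM closed-form (2.3548 σ). The per-scan mean is the
  bell normalized over the scan grid times the ion's `amplitude`, so the
  expected total count over the run equals `amplitude` exactly.
- **Background/reagent ions and the lock-mass reference** hold a constant
  per-scan level until `decay_onset`, then decay exponentially — the
  signature of reagent ions being displaced when the sample plug arrives.
- **Counts** are Poisson per scan; **observed m/z** is the true m/z plus
  per-scan Gaussian jitter (default σ = 1 mDa), optionally passed through a
  third-order polynomial mass-axis distortion to exercise calibration and
  lock-mass correction.
- **Determinism**: one numpy Generator per run; draw order is ions in list
  order, per ion first the Poisson vector then the jitter vector.

Default study conditions (`pipeline.example_run_config`): 240 s runs
(1600 scans), sample amplitudes 2 000–40 000 total counts with elution
centers at 40–60 % of the run and σ = 8–14 s, background levels 4–12
counts/scan with decay onset at 60 s and rates 0.01–0.03 s⁻¹, lock-mass at
40 counts/scan. These are realistic for a micro-scale SFE pulse feeding a
counting detector; run length and peak width are free parameters of the
technique and are configurable.

What the generator does **not** emulate: isotope envelopes, ion
suppression/matrix effects, detector dead time, restrictor-pressure
instability (the dominant real source of run-to-run RSD), co-eluting
isobars, and mass-resolution-limited peak shapes. Passing recovery tests
on synthetic runs therefore demonstrates the correctness of the
*algorithms* under Poisson counting statistics, not instrument-level
performance.

The structure-database stand-in (`make_structure_fixture`) is a synthetic
SDF of lipid-like molecules that deliberately includes a salt form
(disconnected counter-ion), a deuterium-labeled variant, duplicated
structures, and formula-sharing isomers, so every normalization branch is
exercised.

## Mass calibration and lock mass

TOF physics gives m/z ∝ t², so the default calibration form fits
√(m/z) = p₃(t) by least squares (`form="direct"` fits m/z = p₃(t)
instead). At least 4 references are required; the fitted polynomial must
be strictly increasing on the reference span, checked on a dense grid.
The calibration axis is treated as an abstract monotone variable — flight
time or digitizer index both work.

Lock-mass correction is single-point multiplicative: the reference
centroid is located as the counts-weighted centroid within ±20 mDa
(configurable) of its exact m/z in the co-added run, and all m/z values
are scaled by `exact/observed`. One reference per polarity per run is the
operating procedure, which rules out anything fancier; a multiplicative
factor is exact for the dominant drift mode of a TOF (extraction-voltage/
temperature scaling) and is idempotent to numerical precision. Built-in
references: P321 (C6H18N3O6P3 [M+H]⁺ 322.048), P621 (C12H18F12N3O6P3
[M+H]⁺ 622.029) for positive mode; tetracosenoic acid (C24H46O2 [M−H]⁻,
computed 365.343) for negative mode — its m/z is always recomputed from
the formula, never hard-coded.

## Co-addition, peaks, XICs

Co-addition bins all scan peaks in a time range on a fixed m/z grid
(default 5 mDa, the same scale as the blank-match tolerance); each bin
reports the counts-weighted centroid, so total counts are conserved
exactly — an invariant asserted on every synthetic fixture. Peak listing
merges adjacent bins closer than one bin width (an ion whose jitter
straddles a bin edge splits across two bins) and applies a minimum-count
threshold, default 100 counts — the quantitation floor, below which an
ion could not be quantified anyway. XICs sum counts within ±5 mDa of the
target per scan; two co-eluting ions inside one window sum by design.

## Elution-peak detection and classification

The XIC is smoothed by a moving average (default 5 scans ≈ 0.75 s).
Candidate apex = global maximum of the smoothed trace; baseline = median
of the smoothed trace; apex height is re-estimated as the local mean of
the smoothed trace within ± one smoothing window of the argmax (the raw
maximum of a noisy trace overshoots, which would bias the half level up
and the measured FWHM narrow). A peak qualifies when:

1. SNR = height/√(baseline+1) ≥ 3 (Poisson noise scale at the baseline);
2. the smoothed trace crosses below baseline + height/2 on **both** sides
   of the apex (crossings located by linear interpolation);
3. the mean smoothed trace outside the half-height window stays below
   baseline + height/4 on both sides — a bell returns to baseline; a
   decaying background trace, or a noise spike riding on its plateau,
   stays elevated on at least one side. Without this shape requirement,
   slowly decaying background XICs are misread as peaks at a ~13 % rate
   because the global-median baseline understates their plateau.

The reported area sums **raw** counts between the half-height crossings.
Classification: *sample* iff a peak qualifies; otherwise *background* iff
the mean of the first decile of scans is positive and exceeds twice the
mean of the last decile (start-high-then-decay); otherwise *unclassified*.
Blank matching reclassifies any ion with a blank-run ion within ±5 mDa as
*blank_matched* (nearest blank m/z reported; ties to the lower m/z).

Under the default study conditions this recovers 100 % of sample ions
with 0 background ions misread as sample over 100 seeded runs in either
polarity (the test suite asserts ≥ 95 % / ≤ 5 %).

## Structure normalization and annotation

SDF records are normalized with rdkit: keep the largest covalent fragment
(desalting; heavy-atom count, ties by exact mass), neutralize residual
formal charges, zero all isotope labels, drop structures above 1200 Da,
de-duplicate identical normalized structures (canonical SMILES), and
group by molecular formula, counting distinct structures per formula —
the "+isomers" column is that count minus one. Unparseable records are
skipped and counted, not fatal.

Monoisotopic masses use the most-abundant-isotope table from pyteomics
(C 12 exactly, H 1.0078250, O 15.9949146, …). Ion species carry explicit
electron bookkeeping: [M+H]⁺ = M + 1.0072765 (proton), [M]⁺ = M − m(e),
[M−OH]⁺ = M − 17.0032882 (hydroxide), and the exact negatives for the
negative-mode rules, so positive/negative deltas cancel exactly.
[M+NH4]⁺ exists as an opt-in rule (seen for some authentic standards) but
is off by default for cell screening.

Matching accepts |observed mean − theoretical| ≤ 3 mDa (default). The
alternative reading — gating on the per-ion replicate SD instead of a
fixed 3 mDa — is implemented behind `gate="replicate_sd"`; the fixed gate
is the default because a replicate SD is undefined for single runs and
the fixed tolerance is the stricter, more reproducible criterion.

## Quantitation

Relative counting error = 1/√N (Poisson). Response curves are fit through
the origin (slope = Σaᵢyᵢ/Σaᵢ², the least-squares solution with zero
intercept), consistent with a blank-corrected zero response at zero
amount; `through_origin=False` gives a free intercept. LOQ = 100/slope
(the amount yielding 100 counts, i.e. 10 % counting error), so
LOQ × slope = 100 holds exactly for every fitted curve. Replicate
summaries use the sample (n−1) standard deviation by default; a
population-SD switch exists (`ddof=0`).

## Numerical choices and degenerate inputs

- Empty co-add time range → empty spectrum, not an error; empty XIC
  window is rejected (halfwidth must be positive).
- Profiles shorter than 5 scans never qualify as peaks.
- Flat or all-zero XICs → no peak; all-zero → *unclassified*.
- Zero counts → amount 0 with undefined (None) relative error.
- Calibration with < 4 points, duplicate times, or a non-monotone fit is
  rejected with a specific error; a missing lock-mass reference names the
  reference and the search window.
- All tolerances are expressed in mDa at the interfaces and converted to
  Da internally.

## Known limitations

- One elution peak per XIC: co-eluting multi-peak deconvolution is out of
  scope; a window covering two ions reports their sum.
- No retention-time alignment across runs; replicate aggregation is by
  m/z only.
- The blank match is purely m/z-based, as in the original screening
  procedure; an ion genuinely present in both cell and blank at different
  elution times is still grayed out.
- Formula-level annotation only: isomers sharing a formula are counted,
  never resolved.
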