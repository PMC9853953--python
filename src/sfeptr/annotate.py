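"""Formula annotation of screened ions.

PTR (water chemical ionization) produces simple singly charged species —
protonated/deprotonated molecules, radical ions, and hydroxide gain/loss —
so annotation reduces to enumerating a handful of ion-species rules over a
normalized structure database and matching theoretical m/z against observed
centroids within a few mDa.

Electron mass is carried explicitly: the m/z of [M+H]+ is M + m(H+) where
m(H+) = m(H) − m(e), and [M]+ / [M]− differ from the neutral monoisotopic
mass by exactly one electron mass.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics.mass import nist_mass as _NIST_MASS

logger = logging.getLogger(__name__)

#: Monoisotopic atomic masses (Da), most abundant isotope per element.
MONOISOTOPIC: dict[str, float] = {el: data[0][0] for el, data in _NIST_MASS.items()}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990
#: Hydroxide anion mass: O + H + e.
HYDROXIDE_MASS = MONOISOTOPIC["O"] + MONOISOTOPIC["H"] + ELECTRON_MASS
#: Ammonium cation mass: N + 4H − e.
AMMONIUM_MASS = MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"] - ELECTRON_MASS


@dataclass(frozen=True)
class IonSpeciesRule:
    """An ion species: neutral molecule M plus a fixed mass delta, charge ±1."""

    label: str
    delta_mass: float
    polarity: str  # "positive" | "negative"


#: Core PTR species. [M+NH4]+ is seen only for a few authentic standards and
#: is disabled by default for cell screening.
ION_SPECIES: dict[str, IonSpeciesRule] = {
    "[M+H]+": IonSpeciesRule("[M+H]+", +PROTON_MASS, "positive"),
    "[M]+": IonSpeciesRule("[M]+", -ELECTRON_MASS, "positive"),
    "[M-OH]+": IonSpeciesRule("[M-OH]+", -HYDROXIDE_MASS, "positive"),
    "[M-H]-": IonSpeciesRule("[M-H]-", -PROTON_MASS, "negative"),
    "[M]-": IonSpeciesRule("[M]-", +ELECTRON_MASS, "negative"),
    "[M+OH]-": IonSpeciesRule("[M+OH]-", +HYDROXIDE_MASS, "negative"),
    "[M+NH4]+": IonSpeciesRule("[M+NH4]+", +AMMONIUM_MASS, "positive"),
}

DEFAULT_POSITIVE_RULES = ("[M+H]+", "[M]+", "[M-OH]+")
DEFAULT_NEGATIVE_RULES = ("[M-H]-", "[M]-", "[M+OH]-")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into an element→count map.

    Supports parenthesized groups with multipliers, e.g. ``Ca(OH)2``.
    Charge tokens are not accepted: formulas here are neutral molecules.
    """
    if not formula or not formula.strip():
        return {}
    pos = 0
    stack: list[dict[str, int]] = [{}]
    s = formula.strip()
    while pos < len(s):
        ch = s[pos]
        if ch == "(":
            stack.append({})
            pos += 1
        elif ch == ")":
            m = re.match(r"\)(\d*)", s[pos:])
            mult = int(m.group(1)) if m.group(1) else 1
            group = stack.pop()
            if not stack:
                raise ValueError(f"unbalanced parentheses in formula {formula!r}")
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
            pos += len(m.group(0))
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[pos:])
            if not m:
                raise ValueError(f"cannot parse formula {formula!r} at {s[pos:]!r}")
            el, cnt = m.group(1), int(m.group(2)) if m.group(2) else 1
            stack[-1][el] = stack[-1].get(el, 0) + cnt
            pos += len(m.group(0))
    if len(stack) != 1:
        raise ValueError(f"unbalanced parentheses in formula {formula!r}")
    return stack[0]


def hill_formula(composition: dict[str, int]) -> str:
    """Composition map → Hill-notation string (C, H, then alphabetical)."""
    comp = {el: n for el, n in composition.items() if n}
    parts = []
    for el in ("C", "H"):
        if el in comp:
            n = comp.pop(el)
            parts.append(el + (str(n) if n > 1 else ""))
    for el in sorted(comp):
        n = comp[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(composition: dict[str, int] | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral composition, Da."""
    if isinstance(composition, str):
        composition = parse_formula(composition)
    total = 0.0
    for element, count in composition.items():
        try:
            total += MONOISOTOPIC[element] * count
        except KeyError:
            raise ValueError(f"unknown element {element!r}") from None
    return total


def theoretical_mz(composition: dict[str, int] | str, rule: IonSpeciesRule | str) -> float:
    """Theoretical m/z of a singly charged ion of the given species."""
    if isinstance(rule, str):
        rule = ION_SPECIES[rule]
    mz = monoisotopic_mass(composition) + rule.delta_mass
    if mz <= 0:
        raise ValueError(f"non-positive m/z for {composition!r} with {rule.label}")
    return mz


@dataclass
class FormulaRecord:
    """One neutral molecular formula and the structures that reduce to it."""

    formula: str
    composition: dict[str, int]
    monoisotopic_mass: float
    n_structures: int


@dataclass
class NormalizationResult:
    formulas: list[FormulaRecord]
    n_input: int
    n_parsed: int
    n_skipped: int
    n_unique_structures: int


def normalize_structures(
    sdf: str | Path,
    max_mass: float = 1200.0,
) -> NormalizationResult:
    """Normalize an SDF structure database into formula records.

    Per record: keep only the principal (largest) covalent fragment
    (desalting), neutralize residual formal charges, replace any
    isotope-specified atom by the element's most abundant isotope, and
    compute the molecular formula. Records above ``max_mass`` Da are
    dropped. Identical normalized structures (canonical SMILES) are
    de-duplicated; distinct structures sharing a formula are counted.

    ``sdf`` may be a path to an SDF file or the SDF text itself.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdMolDescriptors
    from rdkit.Chem.MolStandardize import rdMolStandardize

    RDLogger.DisableLog("rdApp.*")
    text = sdf if (isinstance(sdf, str) and "\n" in sdf) else Path(sdf).read_text()
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True)
    uncharger = rdMolStandardize.Uncharger()

    n_input = n_skipped = 0
    seen_smiles: set[str] = set()
    by_formula: dict[str, FormulaRecord] = {}
    for mol in supplier:
        n_input += 1
        if mol is None:
            n_skipped += 1
            logger.warning("skipping unparseable SDF record #%d", n_input)
            continue
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = max(
            frags,
            key=lambda f: (f.GetNumHeavyAtoms(), rdMolDescriptors.CalcExactMolWt(f)),
        )
        mol = uncharger.uncharge(mol)
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)
        mol = Chem.RemoveHs(mol)  # ex-isotope hydrogens fold back to implicit
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen_smiles:
            continue
        seen_smiles.add(smiles)
        comp: dict[str, int] = {}
        for atom in mol.GetAtoms():
            comp[atom.GetSymbol()] = comp.get(atom.GetSymbol(), 0) + 1
            if atom.GetTotalNumHs():
                comp["H"] = comp.get("H", 0) + atom.GetTotalNumHs()
        mass = monoisotopic_mass(comp)
        if mass > max_mass:
            continue
        formula = hill_formula(comp)
        if formula in by_formula:
            by_formula[formula].n_structures += 1
        else:
            by_formula[formula] = FormulaRecord(formula, comp, mass, 1)
    if n_skipped:
        logger.warning("%d of %d SDF records skipped as unparseable", n_skipped, n_input)
    records = sorted(by_formula.values(), key=lambda r: r.monoisotopic_mass)
    return NormalizationResult(
        formulas=records,
        n_input=n_input,
        n_parsed=n_input - n_skipped,
        n_skipped=n_skipped,
        n_unique_structures=len(seen_smiles),
    )


@dataclass(frozen=True)
class IonCandidate:
    """A (formula, species) pair with precomputed theoretical m/z."""

    formula: str
    species: str
    theoretical_mz: float
    isomer_extra: int = 0


def enumerate_candidates(
    formulas: list[FormulaRecord],
    polarity: str,
    include_ammonium: bool = False,
) -> list[IonCandidate]:
    """All (formula, species) ion candidates for one polarity, sorted by m/z."""
    if polarity == "positive":
        labels = list(DEFAULT_POSITIVE_RULES) + (["[M+NH4]+"] if include_ammonium else [])
    elif polarity == "negative":
        labels = list(DEFAULT_NEGATIVE_RULES)
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    out = [
        IonCandidate(rec.formula, lab, theoretical_mz(rec.composition, lab), rec.n_structures - 1)
        for rec in formulas
        for lab in labels
    ]
    out.sort(key=lambda c: c.theoretical_mz)
    return out


@dataclass
class AnnotationMatch:
    observed_mz_mean: float
    observed_sd_mda: float
    n_replicates: int
    formula: str
    species: str
    theoretical_mz: float
    delta_m_mda: float
    isomer_extra: int


def match_ions(
    observed: list[tuple[float, float, int]],
    candidates: list[IonCandidate],
    tolerance_mda: float = 3.0,
    gate: str = "fixed",
) -> list[AnnotationMatch]:
    """Match observed ions (mz_mean, sd_mda, n) against candidate species.

    ``gate="fixed"``: accept |mean − theoretical| ≤ tolerance_mda (default
    3 mDa). ``gate="replicate_sd"``: the gate is the per-ion replicate SD
    instead of the fixed tolerance. Matches for each ion are sorted by
    |delta m|.
    """
    if gate not in ("fixed", "replicate_sd"):
        raise ValueError(f"unknown gate {gate!r}")
    cands = sorted(candidates, key=lambda c: c.theoretical_mz)
    theo = [c.theoretical_mz for c in cands]
    import bisect

    matches: list[AnnotationMatch] = []
    for mz_mean, sd_mda, n in observed:
        tol = (sd_mda if gate == "replicate_sd" else tolerance_mda) * 1e-3
        lo = bisect.bisect_left(theo, mz_mean - tol)
        hi = bisect.bisect_right(theo, mz_mean + tol)
        hits = sorted(cands[lo:hi], key=lambda c: abs(mz_mean - c.theoretical_mz))
        for c in hits:
            matches.append(
                AnnotationMatch(
                    observed_mz_mean=mz_mean,
                    observed_sd_mda=sd_mda,
                    n_replicates=n,
                    formula=c.formula,
                    species=c.species,
                    theoretical_mz=c.theoretical_mz,
                    delta_m_mda=(mz_mean - c.theoretical_mz) * 1e3,
                    isomer_extra=c.isomer_extra,
                )
            )
    return matches
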