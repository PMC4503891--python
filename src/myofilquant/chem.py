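"""Peptide sequence, tryptic digestion, modification and mass/m-over-z arithmetic.

All mass arithmetic is monoisotopic. A peptide's neutral mass is the sum of its
residue masses plus one water plus the deltas of any covalent modifications; an
ion's m/z is ``(M + z * m_proton) / z``. Phosphorylation (+79.966331 Da on S/T/Y)
and the two methionine oxidation states (sulfoxide +15.994915, sulfone
+31.989829 Da) are the only modifications the study's quantification needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Literal, Sequence

__all__ = [
    "ResidueMassTable",
    "Modification",
    "ModifiedPeptide",
    "IonSpecies",
    "DEFAULT_MASS_TABLE",
    "monoisotopic_mass",
    "mz",
    "printed_mz",
    "digest",
    "fragment_ions",
]

ModKind = Literal["phospho", "met_sulfoxide", "met_sulfone"]

#: Monoisotopic residue (amino-acid minus water) masses in Da.
_MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Residues a given modification may sit on.
_MOD_TARGETS = {
    "phospho": frozenset("STY"),
    "met_sulfoxide": frozenset("M"),
    "met_sulfone": frozenset("M"),
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic mass constants used by every mass computation."""

    residue_mass: dict = field(default_factory=lambda: dict(_MONO_RESIDUE_MASS))
    water_mass: float = 18.010565
    proton_mass: float = 1.007276
    mod_delta: dict = field(default_factory=lambda: {
        "phospho": 79.966331,
        "met_sulfoxide": 15.994915,
        "met_sulfone": 31.989829,
    })

    def __post_init__(self) -> None:
        missing = set(_MONO_RESIDUE_MASS) - set(self.residue_mass)
        if missing:
            raise ValueError(f"residue mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("all residue masses must be positive")
        if not (self.mod_delta["met_sulfone"] > self.mod_delta["met_sulfoxide"] > 0):
            raise ValueError("met_sulfone delta must exceed met_sulfoxide delta (> 0)")


DEFAULT_MASS_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A covalent modification at a 1-based position within a peptide."""

    position: int
    kind: ModKind


@dataclass(frozen=True)
class ModifiedPeptide:
    """A tryptic peptide with residue-numbered modifications.

    ``start_residue`` is the 1-based position of the peptide's first residue in
    the parent protein, so superscript numbering like 195..205 for the troponin-I
    C-terminal peptide is preserved.
    """

    sequence: str
    start_residue: int = 1
    mods: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in _MONO_RESIDUE_MASS:
                raise ValueError(f"unknown residue code {ch!r} in sequence {self.sequence!r}")
        if self.start_residue < 1:
            raise ValueError("start_residue is 1-based and must be >= 1")
        seen: set[int] = set()
        for mod in self.mods:
            if not 1 <= mod.position <= len(self.sequence):
                raise ValueError(
                    f"modification position {mod.position} outside peptide of length {len(self.sequence)}"
                )
            if mod.position in seen:
                raise ValueError(f"more than one modification at position {mod.position}")
            seen.add(mod.position)
            if mod.kind not in _MOD_TARGETS:
                raise ValueError(f"unknown modification kind {mod.kind!r}")
            residue = self.sequence[mod.position - 1]
            if residue not in _MOD_TARGETS[mod.kind]:
                raise ValueError(
                    f"{mod.kind} not allowed on residue {residue!r} at position {mod.position}"
                )

    def with_mods(self, *mods: Modification) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence, self.start_residue, self.mods + tuple(mods))


@dataclass(frozen=True)
class IonSpecies:
    """A protonated peptide ion as it appears in a chromatogram table."""

    peptide: ModifiedPeptide
    charge: int
    species_id: str

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


def monoisotopic_mass(peptide: ModifiedPeptide, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic mass in Da: residues + water + modification deltas."""
    mass = table.water_mass
    for ch in peptide.sequence:
        mass += table.residue_mass[ch]
    for mod in peptide.mods:
        mass += table.mod_delta[mod.kind]
    return mass


def mz(species: IonSpecies, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Full-precision m/z of a protonated peptide ion: (M + z·m_p) / z."""
    z = species.charge
    return (monoisotopic_mass(species.peptide, table) + z * table.proton_mass) / z


def printed_mz(value: float) -> float:
    """Round an m/z to 2 decimals (half-even), the precision used in reports."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def _cleavage_sites(sequence: str) -> list[int]:
    """Indices i such that trypsin cleaves between sequence[i-1] and sequence[i]."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            sites.append(i)
    return sites


def digest(protein_sequence: str, max_missed_cleavages: int = 0) -> list[ModifiedPeptide]:
    """In-silico tryptic digest: cleave C-terminal to K/R unless followed by P.

    Returns every peptide with 0..``max_missed_cleavages`` retained internal
    sites, each annotated with its 1-based start position in the protein. The
    zero-missed-cleavage products tile the protein exactly.
    """
    if not protein_sequence:
        raise ValueError("protein sequence must be non-empty")
    if protein_sequence != protein_sequence.upper():
        raise ValueError("protein sequence must be uppercase")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be non-negative")
    # Validate residues via the peptide constructor on the full sequence.
    ModifiedPeptide(protein_sequence)

    boundaries = [0] + _cleavage_sites(protein_sequence) + [len(protein_sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            peptides.append(ModifiedPeptide(protein_sequence[start:end], start_residue=start + 1))
    return peptides


def fragment_ions(
    peptide: ModifiedPeptide,
    series: Literal["b", "y"],
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[float]:
    """b- or y-ion m/z ladder; modifications travel with their residue.

    b_i = (sum of the first i residues (+ mods) + z·m_p) / z;
    y_i = (sum of the last i residues (+ mods) + water + z·m_p) / z.
    The ladder runs over i = 1..n-1 (i = 1 alone for a single-residue peptide).
    """
    if series not in ("b", "y"):
        raise ValueError(f"fragment series must be 'b' or 'y', got {series!r}")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    n = len(peptide.sequence)
    mod_at = {mod.position: table.mod_delta[mod.kind] for mod in peptide.mods}
    residue_plus_mod = [
        table.residue_mass[peptide.sequence[k]] + mod_at.get(k + 1, 0.0) for k in range(n)
    ]
    ladder = []
    for i in range(1, max(2, n)):
        if series == "b":
            neutral = sum(residue_plus_mod[:i])
        else:
            neutral = sum(residue_plus_mod[n - i:]) + table.water_mass
        ladder.append((neutral + charge * table.proton_mass) / charge)
    return ladder


def peptide_from_strings(
    sequence: str, start_residue: int = 1, mods_spec: str | Iterable[str] = ""
) -> ModifiedPeptide:
    """Build a peptide from a fixture-style mods string like ``"3:phospho;4:phospho"``."""
    if isinstance(mods_spec, str):
        parts: Sequence[str] = [p for p in mods_spec.split(";") if p and p != "-"]
    else:
        parts = list(mods_spec)
    mods = []
    for part in parts:
        pos, _, kind = part.partition(":")
        mods.append(Modification(int(pos), kind))  # type: ignore[arg-type]
    return ModifiedPeptide(sequence, start_residue, tuple(mods))
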