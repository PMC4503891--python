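"""The packaged peptide-species table and helpers built on it.

The table lists every ion species the quantification tracks: the TnI
serine-23/24 phosphopeptides and their properly cleaved non-phospho analog, the
alpha-Tm serine-283 phosphopeptides in all three methionine oxidation states
with their analogs, the TnI C-terminal peptide pair, and the five reference
peptides per protein used for loading normalization.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem import IonSpecies, peptide_from_strings

__all__ = [
    "load_fixture",
    "ion_species",
    "integration_window",
    "reference_ids",
    "analog_ids",
    "cterm_ids",
]

_FIXTURE_CACHE: pd.DataFrame | None = None


def load_fixture() -> pd.DataFrame:
    """Load the packaged species table (one row per ion species)."""
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        with resources.files("myofilquant.data").joinpath("peptide_fixture.tsv").open() as fh:
            _FIXTURE_CACHE = pd.read_csv(fh, sep="\t", comment="#")
    return _FIXTURE_CACHE.copy()


def ion_species(row: pd.Series) -> IonSpecies:
    """Build the IonSpecies for one fixture row."""
    peptide = peptide_from_strings(row["sequence"], int(row["start_residue"]), row["mods"])
    return IonSpecies(peptide=peptide, charge=int(row["charge"]), species_id=row["species_id"])


def integration_window(row: pd.Series, n_sigma: float = 5.0) -> tuple[float, float]:
    """Per-species XIC integration window: elution apex +/- n_sigma peak widths."""
    rt, sigma = float(row["rt_min"]), float(row["peak_sigma_min"])
    return rt - n_sigma * sigma, rt + n_sigma * sigma


def reference_ids(fixture: pd.DataFrame, protein: str) -> list[str]:
    """The five loading-normalization reference species for one protein."""
    mask = (fixture["protein"] == protein) & (fixture["role"] == "reference")
    return fixture.loc[mask, "species_id"].tolist()


def analog_ids(fixture: pd.DataFrame, family: str) -> list[str]:
    """Non-phospho analog species of a phospho-site family (summed for alpha-Tm)."""
    mask = (fixture["family"] == family) & (fixture["role"] == "analog")
    return fixture.loc[mask, "species_id"].tolist()


def cterm_ids(fixture: pd.DataFrame) -> list[str]:
    """The TnI C-terminal peptide species (unoxidized + sulfoxide), summed."""
    return fixture.loc[fixture["role"] == "cterm", "species_id"].tolist()
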