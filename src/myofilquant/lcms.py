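"""Synthetic LC-MS chromatogram generator with known ground truth.

Emulates paired untreated / alkaline-phosphatase-treated tryptic digests of
troponin I and alpha-tropomyosin. Each detectable ion species receives a molar
abundance from the group's ground-truth occupancies, a per-run loading factor
(lognormal), a fixed per-species response factor, and multiplicative lognormal
noise on the integrated abundance; the species then renders as a Gaussian
elution peak at its fixture retention time. Phosphatase treatment reassigns
phospho-species abundance to the corresponding dephosphorylated analog (for
TnI, both the mono- and bis-phosphopeptide collapse onto the properly cleaved
SSANYR peptide because dephosphorylation precedes digestion and restores
normal tryptic cleavage).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .species import load_fixture

__all__ = [
    "GroupTruth",
    "GroundTruth",
    "SampleRun",
    "ChromatogramSet",
    "default_ground_truth",
    "simulate_run",
    "simulate_design",
    "write_chromatograms",
    "read_chromatograms",
]

GROUPS = ("control", "IR2", "IDNR")

#: Shared retention-time grid (minutes). All traces use the same spacing.
RT_GRID_START = 0.0
RT_GRID_END = 30.0
RT_GRID_STEP = 0.02


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth molecular state of one experimental group.

    Occupancies are molar fractions of protein molecules: ``tni_mono_fraction``
    mono-phosphorylated at Ser24, ``tni_bis_fraction`` bis-phosphorylated at
    Ser23+24, ``tm_phospho_fraction`` phosphorylated at alpha-Tm Ser283,
    ``tni_truncated_fraction`` lacking the C-terminal 195-205 peptide.
    ``met_oxidation_probs`` is the (M, sulfoxide, sulfone) simplex for the
    alpha-Tm methionine; ``tni_cterm_oxidation`` the sulfoxide fraction of the
    C-terminal methionine.
    """

    tni_mono_fraction: float = 0.15
    tni_bis_fraction: float = 0.05
    tm_phospho_fraction: float = 0.10
    tni_truncated_fraction: float = 0.0
    met_oxidation_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)
    tni_cterm_oxidation: float = 0.10

    def validate(self) -> list[str]:
        v = []
        for name in ("tni_mono_fraction", "tni_bis_fraction", "tm_phospho_fraction",
                     "tni_truncated_fraction", "tni_cterm_oxidation"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{name}={x} outside [0, 1]")
        if self.tni_mono_fraction + self.tni_bis_fraction > 1.0 + 1e-12:
            v.append("tni_mono_fraction + tni_bis_fraction exceeds 1 (simplex rule)")
        if len(self.met_oxidation_probs) != 3 or any(p < 0 for p in self.met_oxidation_probs):
            v.append("met_oxidation_probs must be three non-negative values")
        elif abs(sum(self.met_oxidation_probs) - 1.0) > 1e-9:
            v.append(f"met_oxidation_probs sum to {sum(self.met_oxidation_probs)}, not 1")
        return v


@dataclass(frozen=True)
class GroundTruth:
    """Full simulator parameterization: per-group truths plus nuisance levels."""

    groups: dict = field(default_factory=lambda: {g: GroupTruth() for g in GROUPS})
    loading_sigma: float = 0.2
    noise_cv: float = 0.10
    phosphatase_completeness: float = 1.0
    protein_amount: float = 1.0

    def validate(self) -> list[str]:
        v = []
        for name, group in self.groups.items():
            v.extend(f"groups.{name}: {msg}" for msg in group.validate())
        if self.loading_sigma < 0:
            v.append("loading_sigma must be >= 0")
        if self.noise_cv < 0:
            v.append("noise_cv must be >= 0")
        if not 0.0 <= self.phosphatase_completeness <= 1.0:
            v.append("phosphatase_completeness outside [0, 1]")
        if self.protein_amount <= 0:
            v.append("protein_amount must be > 0")
        return v


@dataclass(frozen=True)
class SampleRun:
    """One LC-MS run: a group replicate, untreated or phosphatase-treated."""

    group: str
    treated: bool
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based and must be >= 1")


@dataclass
class ChromatogramSet:
    """XIC traces for every fixture species in one run."""

    run: SampleRun
    rt: np.ndarray
    traces: dict  # species_id -> intensity ndarray on the shared grid
    truth: GroundTruth | None = None


def default_ground_truth() -> GroundTruth:
    """Study-condition defaults.

    Control occupancies (mono 0.15, bis 0.05, Tm 0.10) are chosen so the
    reported mono/bis relative abundances (IR2 0.27/4.2, IDNR 0.19/2.8) imply
    a significantly higher total TnI + Tm phosphorylation in IR2 and an
    unchanged total in IDNR. Truncation is zero in every group, matching the
    observed absence of C-terminal proteolysis.
    """
    control = GroupTruth()
    return GroundTruth(groups={
        "control": control,
        "IR2": replace(control,
                       tni_mono_fraction=0.27 * control.tni_mono_fraction,
                       tni_bis_fraction=4.2 * control.tni_bis_fraction,
                       tm_phospho_fraction=0.20),
        "IDNR": replace(control,
                        tni_mono_fraction=0.19 * control.tni_mono_fraction,
                        tni_bis_fraction=2.8 * control.tni_bis_fraction),
    })


def _species_fractions(group: GroupTruth, treated: bool, completeness: float) -> dict:
    """Molar abundance (per mole of protein) of each fixture species."""
    mono, bis = group.tni_mono_fraction, group.tni_bis_fraction
    if treated:
        mono, bis = mono * (1 - completeness), bis * (1 - completeness)
    unphos = 1.0 - mono - bis

    p = group.tm_phospho_fraction
    if treated:
        p *= 1 - completeness
    pm, pox, pox2 = group.met_oxidation_probs

    intact = 1.0 - group.tni_truncated_fraction
    cterm_ox = group.tni_cterm_oxidation

    fractions = {
        "tni_analog_SSANYR": unphos,
        "tni_mono_RSSpANYR": mono,
        "tni_bis_RRSpSpANYR": bis,
        "tni_cterm_NIDALSGMEGR": intact * (1 - cterm_ox),
        "tni_cterm_NIDALSGmoxEGR": intact * cterm_ox,
        "tm_analog_M": (1 - p) * pm,
        "tm_analog_Mox": (1 - p) * pox,
        "tm_analog_Mox2": (1 - p) * pox2,
        "tm_phos_M": p * pm,
        "tm_phos_Mox": p * pox,
        "tm_phos_Mox2": p * pox2,
    }
    # Reference peptides come from every molecule regardless of state.
    for protein_refs in (
        ("tni_ref_YDVEAK", "tni_ref_KLQLK", "tni_ref_ETLDLR",
         "tni_ref_NITEIADLNQK", "tni_ref_IFDLR"),
        ("tm_ref_HIAEDADR", "tm_ref_SLEAQAEK", "tm_ref_IQLVEEELDR",
         "tm_ref_LVIIESDLER", "tm_ref_SIDDLEDELYAQK"),
    ):
        for sid in protein_refs:
            fractions[sid] = 1.0
    return fractions


def simulate_run(truth: GroundTruth, run: SampleRun,
                 fixture: pd.DataFrame | None = None) -> ChromatogramSet:
    """Render one run's XIC traces from the ground truth.

    Expected species area = protein_amount x species molar fraction x response
    factor x loading factor; realized area carries multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (mean-one, so areas are
    unbiased). The trace is a Gaussian elution peak whose integral equals the
    realized area.
    """
    violations = truth.validate()
    if violations:
        raise ValueError("invalid ground truth: " + "; ".join(violations))
    if run.group not in truth.groups:
        raise ValueError(f"run group {run.group!r} not in ground truth groups")
    if fixture is None:
        fixture = load_fixture()

    rng = np.random.default_rng(run.seed)
    loading = float(np.exp(rng.normal(0.0, truth.loading_sigma))) if truth.loading_sigma > 0 else 1.0
    fractions = _species_fractions(truth.groups[run.group], run.treated,
                                   truth.phosphatase_completeness)

    rt = np.arange(RT_GRID_START, RT_GRID_END + RT_GRID_STEP / 2, RT_GRID_STEP)
    cv = truth.noise_cv
    sigma_ln = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0

    traces = {}
    for row in fixture.itertuples(index=False):
        area = truth.protein_amount * fractions[row.species_id] * row.response_factor * loading
        if sigma_ln > 0:
            area *= float(np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)))
        peak_sigma = row.peak_sigma_min
        amplitude = area / (peak_sigma * np.sqrt(2.0 * np.pi))
        traces[row.species_id] = amplitude * np.exp(-0.5 * ((rt - row.rt_min) / peak_sigma) ** 2)
    return ChromatogramSet(run=run, rt=rt, traces=traces, truth=truth)


def simulate_design(truth: GroundTruth, master_seed: int, n_replicates: int = 3,
                    groups: tuple = GROUPS,
                    fixture: pd.DataFrame | None = None) -> list[ChromatogramSet]:
    """The study design: n replicates x {untreated, treated} per group.

    Per-run seeds are derived deterministically from the master seed so a
    design is reproducible from a single integer.
    """
    if fixture is None:
        fixture = load_fixture()
    runs = []
    counter = 0
    for group in groups:
        for replicate in range(1, n_replicates + 1):
            for treated in (False, True):
                seed = (master_seed * 100003 + counter) % (2**31)
                runs.append(simulate_run(
                    truth, SampleRun(group, treated, replicate, seed), fixture))
                counter += 1
    return runs


def write_chromatograms(cset: ChromatogramSet, path) -> None:
    """Write a chromatogram set as TSV: metadata comment header + one row per point."""
    buf = io.StringIO()
    buf.write(f"# group={cset.run.group}\n")
    buf.write(f"# treated={int(cset.run.treated)}\n")
    buf.write(f"# replicate={cset.run.replicate}\n")
    buf.write(f"# seed={cset.run.seed}\n")
    buf.write("species_id\trt_min\tintensity\n")
    for sid in cset.traces:
        intensity = cset.traces[sid]
        for t, y in zip(cset.rt, intensity):
            buf.write(f"{sid}\t{float(t)!r}\t{float(y)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_chromatograms(path) -> ChromatogramSet:
    """Read a chromatogram TSV back; lossless inverse of write_chromatograms."""
    meta: dict = {}
    by_species: dict = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.split("\t") != ["species_id", "rt_min", "intensity"]:
                    raise ValueError(f"{path}: line {lineno}: unexpected header {line!r}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            sid, rt_s, y_s = parts
            try:
                point = (float(rt_s), float(y_s))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
            by_species.setdefault(sid, []).append(point)

    for key in ("group", "treated", "replicate", "seed"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata line '# {key}=...'")
    run = SampleRun(group=meta["group"], treated=bool(int(meta["treated"])),
                    replicate=int(meta["replicate"]), seed=int(meta["seed"]))

    rt = None
    traces = {}
    for sid, points in by_species.items():
        arr = np.asarray(points)
        if rt is None:
            rt = arr[:, 0]
        elif arr.shape[0] == rt.shape[0] and not np.array_equal(arr[:, 0], rt):
            raise ValueError(f"{path}: species {sid} retention grid differs from the first trace")
        traces[sid] = arr[:, 1]
    if rt is None:
        rt = np.array([])
    return ChromatogramSet(run=run, rt=rt, traces=traces)
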