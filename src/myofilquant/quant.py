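"""Label-free mass-balance quantification from extracted-ion-current peak areas.

The estimand chain mirrors the study's strategy: integrate each species' XIC
peak, normalize target areas by each of the five reference peptides of the
same protein within the same run (cancelling loading), then

* fraction phosphorylated f = 1 - untreated/treated normalized analog
  abundance (the analog gains exactly the phosphorylated molar share upon
  complete dephosphorylation);
* relative abundance = experimental / control normalized phosphopeptide
  abundance;
* truncation ratio = relative abundance of the summed C-terminal peptide
  forms (unoxidized + methionine sulfoxide).

Per-reference ratios are the replicate unit for spread and Student's t-tests;
replicate runs add a second stratum pooled by simple aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lcms import ChromatogramSet
from .species import analog_ids, cterm_ids, integration_window, load_fixture, reference_ids

__all__ = [
    "XICPeakArea",
    "PhosphoQuantResult",
    "integrate_xic",
    "normalize",
    "run_areas",
    "normalized_abundance",
    "fraction_phosphorylated",
    "relative_abundance",
    "truncation_ratio",
    "two_sample_t",
    "quantify_study",
]


@dataclass(frozen=True)
class XICPeakArea:
    """Integrated ion current (arbitrary units x minutes) over an RT window."""

    species_id: str
    area: float
    rt_start: float
    rt_end: float


@dataclass
class PhosphoQuantResult:
    """Point estimate with per-reference(-and-replicate) values and spread."""

    kind: str  # fraction_phosphorylated | relative_abundance | truncation_ratio
    estimate: float
    sd: float
    sem: float
    values: np.ndarray = field(repr=False)
    n: int = 0
    p_value: float | None = None
    clamped: bool = False


def integrate_xic(rt: np.ndarray, intensity: np.ndarray,
                  window: tuple[float, float], species_id: str = "") -> XICPeakArea:
    """Trapezoidal peak area over [rt_start, rt_end]; no baseline subtraction."""
    rt_start, rt_end = window
    if rt_end <= rt_start:
        raise ValueError(f"empty integration window ({rt_start}, {rt_end})")
    if rt.size == 0 or rt_start < rt[0] - 1e-12 or rt_end > rt[-1] + 1e-12:
        raise ValueError(
            f"integration window ({rt_start}, {rt_end}) outside trace extent"
        )
    mask = (rt >= rt_start) & (rt <= rt_end)
    area = float(np.trapezoid(intensity[mask], rt[mask]))
    return XICPeakArea(species_id=species_id, area=area, rt_start=rt_start, rt_end=rt_end)


def normalize(target: XICPeakArea, references: list[XICPeakArea]) -> dict:
    """Per-reference ratios target_area / reference_area.

    References with zero area are dropped with a warning; an all-zero
    reference set makes the run unusable and raises.
    """
    ratios = {}
    for ref in references:
        if ref.area <= 0:
            warnings.warn(f"reference {ref.species_id} has zero area; dropped")
            continue
        ratios[ref.species_id] = target.area / ref.area
    if not ratios:
        raise ValueError(f"all reference peptides have zero area for {target.species_id}")
    return ratios


def run_areas(cset: ChromatogramSet, fixture: pd.DataFrame | None = None) -> dict:
    """Integrate every fixture species' XIC in one run: species_id -> XICPeakArea."""
    if fixture is None:
        fixture = load_fixture()
    areas = {}
    for _, row in fixture.iterrows():
        window = integration_window(row)
        trace = cset.traces.get(row["species_id"])
        if trace is None:
            areas[row["species_id"]] = XICPeakArea(row["species_id"], 0.0, *window)
        else:
            areas[row["species_id"]] = integrate_xic(cset.rt, trace, window, row["species_id"])
    return areas


def normalized_abundance(areas: dict, target_ids: list[str], ref_ids: list[str]) -> dict:
    """Summed target area normalized by each reference: ref_id -> ratio."""
    total = sum(areas[t].area for t in target_ids)
    target = XICPeakArea("+".join(target_ids), total, 0.0, 0.0)
    return normalize(target, [areas[r] for r in ref_ids])


def _paired_fraction(untreated: dict, treated: dict) -> list[float]:
    values = []
    for ref in untreated:
        if ref not in treated:
            continue
        if treated[ref] <= 0:
            warnings.warn(f"treated ratio for reference {ref} is zero; reference dropped")
            continue
        values.append(1.0 - untreated[ref] / treated[ref])
    if not values:
        raise ValueError("no usable reference peptides for mass balance")
    return values


def fraction_phosphorylated(untreated_runs: list[dict], treated_runs: list[dict]) -> PhosphoQuantResult:
    """Mass-balance fraction phosphorylated from paired untreated/treated runs.

    Each argument is a list (over replicates, paired by index) of per-reference
    normalized analog abundances as returned by :func:`normalized_abundance`.
    For the alpha-Tm site the analog abundance is the sum over the three
    methionine oxidation states, which the caller provides via ``target_ids``.
    """
    if len(untreated_runs) != len(treated_runs):
        raise ValueError("untreated and treated replicate lists must pair 1:1")
    values = []
    for u, t in zip(untreated_runs, treated_runs):
        values.extend(_paired_fraction(u, t))
    raw = np.asarray(values, dtype=float)
    clamped = bool((raw < 0).any() or (raw > 1).any())
    if clamped:
        warnings.warn("fraction phosphorylated clamped to [0, 1] for some references")
    vals = np.clip(raw, 0.0, 1.0)
    est = float(np.clip(raw.mean(), 0.0, 1.0))
    return PhosphoQuantResult(
        kind="fraction_phosphorylated", estimate=est,
        sd=float(raw.std(ddof=1)) if raw.size > 1 else 0.0,
        sem=float(raw.std(ddof=1) / np.sqrt(raw.size)) if raw.size > 1 else 0.0,
        values=vals, n=int(raw.size), clamped=clamped)


def relative_abundance(experimental_runs: list[dict], control_runs: list[dict],
                       kind: str = "relative_abundance") -> PhosphoQuantResult:
    """Normalized species abundance in experimental runs relative to control.

    The control level per reference is the mean over control replicates; each
    experimental replicate contributes one value per reference. The t-test
    compares the per-reference normalized abundances of the two groups.
    """
    refs = sorted(set().union(*experimental_runs) & set().union(*control_runs))
    control_mean = {}
    for ref in refs:
        vals = [run[ref] for run in control_runs if ref in run]
        m = float(np.mean(vals))
        if m <= 0:
            warnings.warn(f"control ratio for reference {ref} is zero; reference dropped")
            continue
        control_mean[ref] = m
    if not control_mean:
        raise ValueError("no usable reference peptides: all control ratios are zero")

    values = [run[ref] / control_mean[ref]
              for run in experimental_runs for ref in control_mean if ref in run]
    vals = np.asarray(values, dtype=float)

    exp_flat = [run[ref] for run in experimental_runs for ref in control_mean if ref in run]
    ctl_flat = [run[ref] for run in control_runs for ref in control_mean if ref in run]
    _, p = two_sample_t(exp_flat, ctl_flat)

    return PhosphoQuantResult(
        kind=kind, estimate=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        sem=float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        values=vals, n=int(vals.size), p_value=p)


def truncation_ratio(experimental_areas: list[dict], control_areas: list[dict],
                     cterm_species: list[str], ref_ids: list[str]) -> PhosphoQuantResult:
    """Relative abundance of the summed C-terminal TnI peptide forms.

    Arguments are per-run area dicts (species_id -> XICPeakArea); the summed
    C-terminal area is normalized by the TnI reference peptides, then compared
    between groups exactly as :func:`relative_abundance`.
    """
    if not cterm_species:
        raise ValueError("cterm_species must be non-empty")
    exp = [normalized_abundance(a, cterm_species, ref_ids) for a in experimental_areas]
    ctl = [normalized_abundance(a, cterm_species, ref_ids) for a in control_areas]
    return relative_abundance(exp, ctl, kind="truncation_ratio")


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Classical pooled-variance two-sample Student's t with two-sided p.

    Degenerate convention: zero pooled variance gives p = 1 when the means are
    equal and p = 0 when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def quantify_study(runs: list[ChromatogramSet],
                   fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full quantification table over a simulated or loaded design.

    Returns a tidy frame: group, quantity, estimate, sd, sem, n, p_vs_control.
    Quantities: TnI/Tm fraction phosphorylated, mono-/bis-phosphopeptide
    relative abundance vs control, and the C-terminal truncation ratio.
    """
    if fixture is None:
        fixture = load_fixture()
    tni_refs = reference_ids(fixture, "TnI")
    tm_refs = reference_ids(fixture, "Tm")
    tni_analogs = analog_ids(fixture, "tni_ser23_24")
    tm_analogs = analog_ids(fixture, "tm_ser283")
    cterm = cterm_ids(fixture)

    by_run: dict = {}
    for cset in runs:
        key = (cset.run.group, cset.run.treated)
        by_run.setdefault(key, []).append((cset.run.replicate, run_areas(cset, fixture)))
    areas = {k: [a for _, a in sorted(v)] for k, v in by_run.items()}
    groups = sorted({g for g, _ in areas}, key=lambda g: (g != "control", g))

    def norm(group, treated, targets, refs):
        return [normalized_abundance(a, targets, refs) for a in areas[(group, treated)]]

    rows = []

    def add(group, quantity, result):
        rows.append({"group": group, "quantity": quantity, "estimate": result.estimate,
                     "sd": result.sd, "sem": result.sem, "n": result.n,
                     "p_vs_control": result.p_value})

    for group in groups:
        if (group, True) in areas:
            add(group, "tni_fraction_phosphorylated", fraction_phosphorylated(
                norm(group, False, tni_analogs, tni_refs),
                norm(group, True, tni_analogs, tni_refs)))
            add(group, "tm_fraction_phosphorylated", fraction_phosphorylated(
                norm(group, False, tm_analogs, tm_refs),
                norm(group, True, tm_analogs, tm_refs)))
        if group == "control" or ("control", False) not in areas:
            continue
        add(group, "tni_mono_relative_abundance", relative_abundance(
            norm(group, False, ["tni_mono_RSSpANYR"], tni_refs),
            norm("control", False, ["tni_mono_RSSpANYR"], tni_refs)))
        add(group, "tni_bis_relative_abundance", relative_abundance(
            norm(group, False, ["tni_bis_RRSpSpANYR"], tni_refs),
            norm("control", False, ["tni_bis_RRSpSpANYR"], tni_refs)))
        add(group, "tni_cterm_truncation_ratio", truncation_ratio(
            areas[(group, False)], areas[("control", False)], cterm, tni_refs))
    return pd.DataFrame(rows)
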