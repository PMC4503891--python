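"""Configuration, orchestration and reporting for full reproducible runs.

A single master seed drives everything: per-stage seeds are derived by hashing
the stage name against the master seed and logged in the report's provenance
block, so identical config + seed gives byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lcms import (GroundTruth, GroupTruth, simulate_design, write_chromatograms)
from .motility import (TrackSimParams, fit_hill, hill_velocity, simulate_tracks,
                       summarize, write_tracks)
from .quant import quantify_study

__all__ = ["RunConfig", "load_config", "default_config", "validate_config",
           "derive_seed", "run_all"]


@dataclass
class RunConfig:
    """Parsed study configuration (see config/default.yaml for the schema)."""

    seed: int
    lcms: dict
    motility: dict
    raw: dict = field(repr=False, default_factory=dict)


def default_config() -> RunConfig:
    with resources.files("myofilquant.config").joinpath("default.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(seed=raw["seed"], lcms=raw["lcms"], motility=raw["motility"], raw=raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for block in ("seed", "lcms", "motility"):
        if block not in raw:
            raise ValueError(f"config missing required block {block!r}")
    return RunConfig(seed=raw["seed"], lcms=raw["lcms"], motility=raw["motility"], raw=raw)


def ground_truth_from_config(lcms: dict) -> GroundTruth:
    groups = {name: GroupTruth(
        tni_mono_fraction=g["tni_mono_fraction"],
        tni_bis_fraction=g["tni_bis_fraction"],
        tm_phospho_fraction=g["tm_phospho_fraction"],
        tni_truncated_fraction=g.get("tni_truncated_fraction", 0.0),
        met_oxidation_probs=tuple(g.get("met_oxidation_probs", (0.8, 0.15, 0.05))),
        tni_cterm_oxidation=g.get("tni_cterm_oxidation", 0.1),
    ) for name, g in lcms["groups"].items()}
    return GroundTruth(groups=groups,
                       loading_sigma=lcms.get("loading_sigma", 0.2),
                       noise_cv=lcms.get("noise_cv", 0.10),
                       phosphatase_completeness=lcms.get("phosphatase_completeness", 1.0))


def validate_config(config: RunConfig) -> list[str]:
    """Collect every invariant violation; an empty list means the config is valid."""
    violations: list[str] = []
    if not isinstance(config.seed, int) or config.seed < 0:
        violations.append("seed: must be a non-negative integer")
    try:
        truth = ground_truth_from_config(config.lcms)
        violations.extend(f"lcms.{msg}" for msg in truth.validate())
    except (KeyError, TypeError) as exc:
        violations.append(f"lcms: malformed block ({exc})")
    if config.lcms.get("n_replicates", 3) < 1:
        violations.append("lcms.n_replicates: must be >= 1")
    m = config.motility
    try:
        for cond, hill in m["conditions"].items():
            params = TrackSimParams(
                n_filaments=m.get("n_filaments", 50),
                fraction_moving=m.get("fraction_moving_max", 0.9),
                mean_speed=hill["vmax"],
                speed_cv=m.get("speed_cv", 0.10),
                noise_sd=m.get("noise_sd", 0.05),
                n_frames=m.get("n_frames", 300),
                frame_interval=m.get("frame_interval", 0.1))
            violations.extend(f"motility.{cond}: {msg}" for msg in params.validate())
            if hill["n"] <= 0 or hill["pca50"] <= 0:
                violations.append(f"motility.{cond}: Hill n and pCa50 must be positive")
        if not m.get("pca_grid"):
            violations.append("motility.pca_grid: must be non-empty")
    except (KeyError, TypeError) as exc:
        violations.append(f"motility: malformed block ({exc})")
    return violations


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic stage seed below 2^31, keyed by stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _simulate_motility(config: RunConfig, seed: int) -> list:
    m = config.motility
    tracksets = []
    for i, (cond, hill) in enumerate(sorted(m["conditions"].items())):
        for j, pca in enumerate(m["pca_grid"]):
            speed = float(hill_velocity(pca, hill["vmax"], hill["pca50"], hill["n"]))
            frac = m.get("fraction_moving_max", 0.9) * speed / hill["vmax"]
            params = TrackSimParams(
                n_filaments=m.get("n_filaments", 50),
                fraction_moving=frac,
                mean_speed=speed,
                speed_cv=m.get("speed_cv", 0.10),
                noise_sd=m.get("noise_sd", 0.05),
                n_frames=m.get("n_frames", 300),
                frame_interval=m.get("frame_interval", 0.1))
            tracksets.append(simulate_tracks(params, derive_seed(seed, f"{cond}:{pca}"),
                                             condition=cond, pca=pca))
    return tracksets


def analyze_motility(tracksets: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pCa summaries and per-condition Hill parameter tables."""
    rows = []
    for ts in tracksets:
        s = summarize(ts)
        rows.append({"condition": ts.condition, "pCa": ts.pca,
                     "mean_velocity": s.mean_velocity, "sem_velocity": s.sem_velocity,
                     "fraction_moving": s.fraction_moving,
                     "motility_index": s.motility_index,
                     "n_tracks": s.n_tracks, "n_moving": s.n_moving})
    summaries = pd.DataFrame(rows).sort_values(["condition", "pCa"]).reset_index(drop=True)

    hill_rows = []
    for cond, sub in summaries.groupby("condition"):
        sub = sub.dropna(subset=["mean_velocity"])
        sem = sub["sem_velocity"].to_numpy(dtype=float)
        fit = fit_hill(sub["pCa"].to_numpy(dtype=float),
                       sub["mean_velocity"].to_numpy(dtype=float),
                       sem if np.all(sem > 0) else None)
        hill_rows.append({"condition": cond, "vmax": fit.vmax, "pca50": fit.pca50,
                          "n": fit.n, "se_vmax": fit.se_vmax, "se_pca50": fit.se_pca50,
                          "se_n": fit.se_n, "converged": fit.converged})
    return summaries, pd.DataFrame(hill_rows)


def run_all(config: RunConfig, out_dir, write_stage_outputs: bool = True) -> dict:
    """Execute simulate-lcms -> quantify and simulate-motility -> analyze-motility.

    Writes the quantification and Hill tables as TSV plus a JSON study report
    with a provenance block (config hash, derived seeds, package version) and
    returns the report dict.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lcms_seed = derive_seed(config.seed, "lcms")
    motility_seed = derive_seed(config.seed, "motility")

    truth = ground_truth_from_config(config.lcms)
    runs = simulate_design(truth, lcms_seed,
                           n_replicates=config.lcms.get("n_replicates", 3),
                           groups=tuple(config.lcms["groups"]))
    if write_stage_outputs:
        lcms_dir = out / "chromatograms"
        lcms_dir.mkdir(exist_ok=True)
        for cset in runs:
            name = (f"{cset.run.group}_rep{cset.run.replicate}_"
                    f"{'treated' if cset.run.treated else 'untreated'}.tsv")
            write_chromatograms(cset, lcms_dir / name)
    quant_table = quantify_study(runs)

    tracksets = _simulate_motility(config, motility_seed)
    if write_stage_outputs:
        write_tracks(tracksets, out / "tracks.tsv")
    summaries, hill_table = analyze_motility(tracksets)

    quant_table.to_csv(out / "quantification.tsv", sep="\t", index=False)
    summaries.to_csv(out / "motility_summaries.tsv", sep="\t", index=False)
    hill_table.to_csv(out / "hill_parameters.tsv", sep="\t", index=False)

    config_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True).encode()).hexdigest()
    report = {
        "provenance": {
            "package_version": __version__,
            "master_seed": config.seed,
            "stage_seeds": {"lcms": lcms_seed, "motility": motility_seed},
            "config_sha256": config_hash,
        },
        "quantification": quant_table.to_dict(orient="records"),
        "motility_summaries": summaries.to_dict(orient="records"),
        "hill_parameters": hill_table.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report
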