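"""End-to-end orchestration: simulate → fit → normalize → curve.

Two surfaces are provided.  The in-memory functions (`simulate_condition`,
`analyze_population`, `condition_curve`, `run_condition`) stream molecules
through the chain without touching disk and are the natural entry points
from Python.  The file-based functions (`run_simulate`, `run_analyze`) read
and write TIFF stacks / CSV tables and back the command-line interface; a
run's effective configuration is echoed into its output directory so reruns
are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .extcurve import (
    BinnedCurve,
    ExtrapolationResult,
    bin_by_intensity,
    expected_extension_line,
    extrapolate_native_extension,
)
from .normalize import (
    NormalizationResult,
    estimate_saturation_intensity,
    intensity_histogram,
    relative_intensity,
)
from .profilefit import (
    align_kymograph,
    extract_kymograph,
    fit_kymograph,
    summarize_molecule,
)
from .simgen import (
    ImageStack,
    SimConfig,
    equilibrate_dye,
    make_molecule_truth,
    render_stack,
    sample_dye_loads,
)

__all__ = [
    "SampleSpec",
    "RunConfig",
    "ConditionResult",
    "simulate_condition",
    "analyze_population",
    "condition_curve",
    "run_condition",
    "run_simulate",
    "run_analyze",
]

log = logging.getLogger("nanostain")


@dataclass(frozen=True)
class SampleSpec:
    """One staining sample: a cohort mixed at a given dye:bp ratio.

    ``mean_dye_per_bp`` is the sample-average stoichiometry (e.g. 0.05 for
    1:20); ``heterogeneity`` the width of the initial load distribution;
    the relaxation rate/duration model optional heat equilibration.
    """

    n_molecules: int
    mean_dye_per_bp: float
    heterogeneity: float = 2.0
    relaxation_rate_per_h: float = 0.0
    equilibration_h: float = 0.0
    label: str = ""


@dataclass
class RunConfig:
    """Everything one reproducible run needs, serializable to YAML/JSON."""

    sim: SimConfig = field(default_factory=SimConfig)
    samples: list[SampleSpec] = field(default_factory=list)
    condition_label: str = ""
    master_seed: int = 0
    min_valid_fraction: float = 0.5
    normalization_percentile: float = 0.975
    bin_width: float = 0.04
    min_per_bin: int = 3
    n_bins_extrapolate: int = 8

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "samples" in d:
            d["samples"] = [
                s if isinstance(s, SampleSpec) else SampleSpec(**s)
                for s in d["samples"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ConditionResult:
    """Full-chain output for one buffer condition."""

    table: pd.DataFrame
    normalization: NormalizationResult
    curve: BinnedCurve
    extrapolation: ExtrapolationResult


# ---------------------------------------------------------------------------
# In-memory chain


def simulate_condition(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw the per-molecule dye saturations for every sample of a condition.

    Returns (saturations, sample_labels), concatenated over samples.  Each
    sample's loads are drawn fresh and then relaxed toward the sample mean
    according to its equilibration settings.
    """
    ss = np.random.SeedSequence(config.master_seed).spawn(len(config.samples))
    thetas, labels = [], []
    for spec, child in zip(config.samples, ss):
        rng = np.random.default_rng(child)
        loads = sample_dye_loads(
            spec.n_molecules,
            spec.mean_dye_per_bp,
            spec.heterogeneity,
            rng,
            dye_site_bp=config.sim.dye_site_bp,
        )
        if spec.relaxation_rate_per_h > 0 and spec.equilibration_h > 0:
            loads = equilibrate_dye(
                loads, spec.relaxation_rate_per_h, spec.equilibration_h, seed=rng
            )
        thetas.append(np.clip(loads, 0.0, 1.0))
        labels.append(np.full(spec.n_molecules, spec.label or "sample", dtype=object))
    if not thetas:
        return np.empty(0), np.empty(0, dtype=object)
    return np.concatenate(thetas), np.concatenate(labels)


def analyze_population(
    saturations: Sequence[float],
    config: RunConfig,
    sample_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate and measure every molecule; one row per simulated molecule.

    Streams molecule by molecule: render the stack, extract the kymograph,
    fit every row, align, summarize.  Columns include the simulator truth
    (``theta_true``, ``ext_true_um``) next to the measurements so detection
    bias and recovery can be audited; ``detected`` marks molecules whose
    summary passed the valid-frame threshold.
    """
    sim = config.sim
    children = np.random.SeedSequence(config.master_seed, spawn_key=(1,)).spawn(
        len(saturations)
    )
    rows = []
    for i, (theta, child) in enumerate(zip(saturations, children)):
        rng = np.random.default_rng(child)
        truth = make_molecule_truth(float(theta), sim, rng=rng)
        stack = render_stack(truth, sim, seed=rng)
        kymo = extract_kymograph(stack)
        fits = fit_kymograph(kymo)
        if any(f.valid for f in fits):
            align_kymograph(kymo, fits)
        summ = summarize_molecule(
            fits, min_valid_fraction=config.min_valid_fraction, molecule_id=i
        )
        rows.append(
            {
                "molecule_id": i,
                "sample": sample_labels[i] if sample_labels is not None else "",
                "theta_true": float(theta),
                "ext_true_um": truth.mean_extension_um,
                "detected": bool(summ.valid),
                "mean_extension_um": summ.mean_extension_um,
                "extension_sd_um": summ.extension_sd_um,
                "mean_intensity": summ.mean_intensity,
                "intensity_sd": summ.intensity_sd,
                "n_valid_frames": summ.n_valid_frames,
                "n_total_frames": summ.n_total_frames,
            }
        )
    return pd.DataFrame(rows)


def condition_curve(
    table: pd.DataFrame,
    config: RunConfig,
    saturation_intensity: float | None = None,
) -> tuple[NormalizationResult, BinnedCurve]:
    """Normalize detected molecules and bin extension vs relative intensity.

    The saturation limit is estimated from the detected cohort's intensities
    unless supplied (e.g. a pooled limit shared between samples).
    """
    det = table[table["detected"]]
    if det.empty:
        raise ValueError("no detected molecules to normalize")
    if saturation_intensity is None:
        saturation_intensity = estimate_saturation_intensity(
            det["mean_intensity"].to_numpy(), config.normalization_percentile
        )
    norm = relative_intensity(
        dict(zip(det["molecule_id"], det["mean_intensity"])),
        saturation_intensity,
        method_label=f"quantile[{config.normalization_percentile}]",
    )
    rel = det["mean_intensity"].to_numpy() / saturation_intensity
    records = np.column_stack([rel, det["mean_extension_um"].to_numpy()])
    curve = bin_by_intensity(
        records,
        bin_width=config.bin_width,
        min_per_bin=config.min_per_bin,
        condition_label=config.condition_label,
    )
    return norm, curve


def run_condition(config: RunConfig) -> ConditionResult:
    """Full in-memory chain for one condition: simulate, measure, normalize,
    bin, extrapolate the native extension."""
    thetas, labels = simulate_condition(config)
    table = analyze_population(thetas, config, sample_labels=labels)
    norm, curve = condition_curve(table, config)
    extrap = extrapolate_native_extension(curve, config.n_bins_extrapolate)
    return ConditionResult(table=table, normalization=norm, curve=curve, extrapolation=extrap)


# ---------------------------------------------------------------------------
# File-based pipeline (TIFF in, CSV/JSON out)


def run_simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate a condition to disk: one multi-page TIFF per molecule plus a
    ground-truth CSV, a manifest, and the effective configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    thetas, labels = simulate_condition(config)
    sim = config.sim
    children = np.random.SeedSequence(config.master_seed, spawn_key=(1,)).spawn(
        len(thetas)
    )
    manifest, truth_rows = [], []
    for i, (theta, child) in enumerate(zip(thetas, children)):
        rng = np.random.default_rng(child)
        truth = make_molecule_truth(float(theta), sim, rng=rng)
        stack = render_stack(truth, sim, seed=rng)
        path = outdir / f"molecule_{i:05d}.tif"
        tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
        manifest.append(path.name)
        truth_rows.append(
            {
                "molecule_id": i,
                "sample": labels[i],
                "saturation": truth.saturation,
                "mean_extension_um": truth.mean_extension_um,
                "plateau_amplitude": truth.plateau_amplitude,
            }
        )
    pd.DataFrame(
        truth_rows,
        columns=[
            "molecule_id",
            "sample",
            "saturation",
            "mean_extension_um",
            "plateau_amplitude",
        ],
    ).to_csv(outdir / "truth.csv", index=False)
    info = {
        "version": __version__,
        "n_molecules": len(manifest),
        "stacks": manifest,
        "truth": "truth.csv",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(info, fh, indent=2)
    if not manifest:
        log.warning("simulated an empty population: manifest is empty")
    return info


def run_analyze(config: RunConfig, stacks_dir: str | Path, outdir: str | Path) -> ConditionResult:
    """Analyze a directory of per-molecule TIFF stacks end to end.

    Corrupt or unreadable stacks are skipped with a logged reason and listed
    in ``skipped.csv``; the run fails only if nothing is analyzable.  Writes
    the per-molecule result table, the normalization report, the binned
    curve and the extrapolation, plus the effective config.
    """
    stacks_dir, outdir = Path(stacks_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    paths = sorted(stacks_dir.glob("*.tif")) + sorted(stacks_dir.glob("*.tiff"))
    if not paths:
        raise ValueError(f"no TIFF stacks found in {stacks_dir}")
    rows, skipped, frame_rows = [], [], []
    for path in paths:
        mol_id = path.stem
        try:
            frames = tifffile.imread(path)
            if frames.ndim == 2:
                frames = frames[None, :, :]
            stack = ImageStack(
                frames=np.asarray(frames, dtype=float),
                pixel_size_um=config.sim.pixel_size_um,
                exposure_s=config.sim.exposure_s,
            )
            kymo = extract_kymograph(stack)
            fits = fit_kymograph(kymo)
            if any(f.valid for f in fits):
                align_kymograph(kymo, fits)
            summ = summarize_molecule(
                fits, min_valid_fraction=config.min_valid_fraction, molecule_id=mol_id
            )
        except Exception as exc:  # corrupt file or degenerate stack
            log.warning("skipping %s: %s", path.name, exc)
            skipped.append({"molecule_id": mol_id, "reason": str(exc)})
            continue
        for t, f in enumerate(fits):
            frame_rows.append(
                {
                    "molecule_id": mol_id,
                    "frame": t,
                    "center_um": f.center_um,
                    "extension_um": f.extension_um,
                    "plateau": f.plateau,
                    "background": f.background,
                    "sigma_px": f.blur_sigma_px,
                    "integrated_intensity": f.integrated_intensity,
                    "valid": f.valid,
                }
            )
        rows.append(
            {
                "molecule_id": mol_id,
                "sample": "",
                "theta_true": np.nan,
                "ext_true_um": np.nan,
                "detected": bool(summ.valid),
                "mean_extension_um": summ.mean_extension_um,
                "extension_sd_um": summ.extension_sd_um,
                "mean_intensity": summ.mean_intensity,
                "intensity_sd": summ.intensity_sd,
                "n_valid_frames": summ.n_valid_frames,
                "n_total_frames": summ.n_total_frames,
            }
        )
    pd.DataFrame(skipped, columns=["molecule_id", "reason"]).to_csv(
        outdir / "skipped.csv", index=False
    )
    if not rows:
        raise ValueError("all stacks were skipped; nothing to analyze")
    pd.DataFrame(frame_rows).to_csv(outdir / "frame_fits.csv", index=False)
    table = pd.DataFrame(rows)
    norm, curve = condition_curve(table, config)
    rel = table["molecule_id"].map(norm.relative_intensities)
    table = table.assign(relative_intensity=rel)
    table.to_csv(outdir / "molecules.csv", index=False)
    hist = intensity_histogram(
        [v for v in norm.relative_intensities.values()], config.bin_width
    )
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(outdir / "intensity_histogram.csv", index=False)
    with open(outdir / "normalization.json", "w") as fh:
        json.dump(
            {
                "saturation_intensity": norm.saturation_intensity,
                "method": norm.method_label,
                "n": len(norm.relative_intensities),
                "n_clipped": norm.n_clipped,
            },
            fh,
            indent=2,
        )
    pd.DataFrame(
        {
            "bin_center": curve.bin_centers,
            "mean_extension_um": curve.mean_extension_um,
            "extension_sem_um": curve.extension_sem_um,
            "n_molecules": curve.n_molecules,
        }
    ).to_csv(outdir / "curve.csv", index=False)
    extrap = extrapolate_native_extension(curve, config.n_bins_extrapolate)
    with open(outdir / "extrapolation.json", "w") as fh:
        json.dump(
            {
                "native_extension_um": extrap.native_extension_um,
                "slope_um_per_unit": extrap.slope_um_per_unit,
                "intercept_se": extrap.intercept_se,
                "slope_se": extrap.slope_se,
                "n_bins_used": extrap.n_bins_used,
            },
            fh,
            indent=2,
        )
    return ConditionResult(table=table, normalization=norm, curve=curve, extrapolation=extrap)
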