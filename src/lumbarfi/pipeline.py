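"""Reproducible end-to-end runs: phantom -> measurement -> cohort -> statistics.

A :class:`RunConfig` captures everything a run depends on (seed, stage list,
sizes, measurement knobs); it serializes to JSON and back losslessly, and its
hash plus the seed are stamped into every output so a report can be traced to
the exact configuration that produced it. All randomness derives from the
single top-level seed, split deterministically per stage, so rerunning the
same config reproduces the same bytes for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import phantom as phantom_mod
from . import stats as stats_mod
from .composition import MeasureConfig, measure_all

logger = logging.getLogger("lumbarfi")

STAGES = ("phantom", "measure", "simulate-cohort", "analyze")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (JSON round-trip safe)."""

    seed: int = 0
    out_dir: str = "lumbarfi_run"
    stages: tuple[str, ...] = STAGES
    cohort_n: int = 190
    phantom_size_px: int = 128
    phantom_noise_sd: float = 0.0
    phantom_bias: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    bias_correction: bool = True
    max_iterations: int = 25
    threshold_tolerance: float = 1e-6
    fi_group_boundaries: tuple[float, float] = (10.0, 50.0)
    significance_level: float = 0.05
    image_format: str = "nifti"  # or "csv"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        coerced = {}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        import hashlib

        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            bias_correction=self.bias_correction,
            max_iterations=self.max_iterations,
            threshold_tolerance=self.threshold_tolerance,
        )


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the artifact paths by stage.

    Stage failures abort the run but leave earlier outputs in place; the log
    records every statistical test choice made by the analysis stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    seeds = stage_seeds(config.seed)
    digest = config.digest()
    artifacts: dict[str, Path] = {}

    phantom_slice = None
    if "phantom" in config.stages:
        logger.info("stage phantom (seed %d)", seeds["phantom"])
        spec = phantom_mod.default_spec(
            image_height_px=config.phantom_size_px,
            image_width_px=config.phantom_size_px,
            noise_sd=config.phantom_noise_sd,
            bias_coefficients=tuple(config.phantom_bias),
            seed=seeds["phantom"],
        )
        phantom_slice = phantom_mod.generate_phantom(spec)
        paths = phantom_mod.write_phantom(
            phantom_slice, out / "phantom", fmt=config.image_format
        )
        artifacts["phantom"] = paths["image"].parent

    if "measure" in config.stages:
        if phantom_slice is None:
            raise ValueError("measure stage needs the phantom stage in this run")
        logger.info("stage measure")
        measured = measure_all(
            phantom_slice.image, phantom_slice.masks, config=config.measure_config()
        )
        rows = []
        # per-side truth folded into a bilateral (area-weighted) truth FI
        truth_bilateral: dict[str, tuple[float, float]] = {}
        for (muscle, side), frac in phantom_slice.truth_fat_fraction.items():
            region = phantom_slice.masks.labels == phantom_slice.masks.find(muscle, side)
            n = int(region.sum())
            fat, tot = truth_bilateral.get(muscle, (0.0, 0.0))
            truth_bilateral[muscle] = (fat + frac * n, tot + n)
        for muscle, comp in measured.items():
            fat, tot = truth_bilateral[muscle]
            rows.append(
                {
                    "config_digest": digest,
                    "seed": config.seed,
                    "muscle": muscle,
                    "CSA": comp.CSA,
                    "fCSA": comp.fCSA,
                    "FAT": comp.FAT,
                    "FI_measured": comp.FI,
                    "FI_truth": 100.0 * fat / tot,
                    "FI_error": comp.FI - 100.0 * fat / tot,
                }
            )
        path = out / "measurement_vs_truth.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        artifacts["measure"] = path

    table = None
    if "simulate-cohort" in config.stages:
        logger.info("stage simulate-cohort (n=%d, seed %d)", config.cohort_n, seeds["simulate-cohort"])
        spec = dataclasses.replace(
            cohort_mod.calibrate_defaults(), n=config.cohort_n
        )
        table = cohort_mod.generate_cohort(spec, seed=seeds["simulate-cohort"])
        path = out / "cohort.csv"
        cohort_mod.write_cohort(table, path, spec=spec)
        artifacts["simulate-cohort"] = path

    if "analyze" in config.stages:
        if table is None:
            raise ValueError("analyze stage needs the simulate-cohort stage in this run")
        logger.info("stage analyze")
        reports = stats_mod.analyze_cohort(table.df, alpha=config.significance_level)
        for _, row in reports["test_log"].iterrows():
            logger.info(
                "test choice: %s/%s -> %s (Shapiro p %.3g / %.3g)",
                row["sex"], row["variable"], row["test"],
                row["shapiro_p_low"], row["shapiro_p_high"],
            )
        report_dir = out / "reports"
        stats_mod.write_reports(reports, report_dir)
        with open(report_dir / "provenance.json", "w") as fh:
            json.dump({"config_digest": digest, "seed": config.seed}, fh, indent=2)
        artifacts["analyze"] = report_dir

    return artifacts
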