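"""Persistence: policy/summary tables as CSV, run manifests as JSON."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import pandas as pd

from .dp import Policy
from .experiments import SweepResult, summarize_headline_stats
from .simulate import TraitSummary

__all__ = ["RunManifest", "write_policy", "write_summary", "write_sweep",
           "write_headline_stats"]


@dataclass
class RunManifest:
    """Reproducibility record written next to every command's outputs."""

    command: str
    config: dict
    seed: int | None = None
    outputs: list[str] = dataclass_field(default_factory=list)
    counters: dict = dataclass_field(default_factory=dict)
    started: str = dataclass_field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    package_version: str = ""

    def add_output(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, outdir: Path) -> Path:
        from . import __version__
        self.package_version = self.package_version or __version__
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def write_policy(policy: Policy, outdir: str | Path, stem: str = "policy",
                 manifest: RunManifest | None = None) -> Path:
    """Policy/value grids as a long CSV plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    policy.to_frame().to_csv(csv_path, index=False)
    meta = {
        "scenario": policy.scenario.to_dict(),
        "params_hash": policy.params_hash,
        "clamp_count": policy.clamp_count,
        "n_grid_escapes": policy.n_grid_escapes,
    }
    (outdir / f"{stem}.meta.json").write_text(json.dumps(meta, indent=2))
    if manifest is not None:
        manifest.add_output(csv_path)
        manifest.add_output(outdir / f"{stem}.meta.json")
        manifest.counters.update({"clamp_count": policy.clamp_count,
                                  "n_grid_escapes": policy.n_grid_escapes})
    return csv_path


def write_summary(summary: TraitSummary, outdir: str | Path,
                  stem: str = "traits",
                  manifest: RunManifest | None = None) -> Path:
    """Tidy per-age trait table plus the age-at-maturity distribution."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    summary.by_age.to_csv(csv_path, index=False)
    mat = summary.maturity_counts.rename_axis("age").reset_index(name="count")
    mat_path = outdir / f"{stem}.maturity.csv"
    mat.to_csv(mat_path, index=False)
    if manifest is not None:
        manifest.add_output(csv_path)
        manifest.add_output(mat_path)
        manifest.counters.update({
            "starved_fraction": summary.starved_fraction,
            "mean_E_node_distance": summary.mean_E_node_distance,
        })
    return csv_path


def write_sweep(sweep: SweepResult, outdir: str | Path, stem: str,
                manifest: RunManifest | None = None) -> dict[str, Path]:
    """Reference-age table, percent changes (γ sweeps), and per-age curves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["reference"] = outdir / f"{stem}.reference_age.csv"
    sweep.reference_table().to_csv(paths["reference"], index=False)
    paths["by_age"] = outdir / f"{stem}.by_age.csv"
    sweep.by_age_table().to_csv(paths["by_age"], index=False)
    if sweep.axis == "gamma":
        paths["percent_change"] = outdir / f"{stem}.percent_change.csv"
        sweep.percent_change_table().to_csv(paths["percent_change"], index=False)
    if manifest is not None:
        for p in paths.values():
            manifest.add_output(p)
    return paths


def write_headline_stats(sweep: SweepResult, outdir: str | Path,
                         stem: str = "headline",
                         manifest: RunManifest | None = None) -> Path:
    path = Path(outdir) / f"{stem}.json"
    path.write_text(json.dumps(summarize_headline_stats(sweep), indent=2))
    if manifest is not None:
        manifest.add_output(path)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
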