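"""Assemble run outputs into tables, figures and a single JSON summary.

The report layer never recomputes science: every number in the JSON summary
traces to an upstream CSV written by another module.  The one sanctioned
derivation is percent cover, which is recomputed from the hectare columns
and each year's total area rather than trusting any input percent column
(printed percent columns can contradict their own hectares).

``build_report`` is idempotent: rerunning on the same directory produces a
byte-identical JSON (sorted keys, stable float formatting).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .change import TransitionMatrix
from .intensity import category_level, interval_level, transition_level

__all__ = ["RunManifest", "build_report"]


@dataclass(frozen=True)
class RunManifest:
    """Machine-readable record of a pipeline run."""

    inputs: dict[str, str] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        """Stable hash of the configuration, invariant to field order."""
        canonical = json.dumps(self.config, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "inputs": self.inputs,
            "config": self.config,
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "outputs": sorted(self.outputs),
        }
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path


def _round(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    return obj


def build_report(run_dir: str | Path, out_dir: str | Path | None = None) -> dict:
    """Collect stage outputs from ``run_dir`` into a report bundle.

    Looks for ``areas.csv`` (year, class, area_ha), per-interval transition
    matrices ``transitions_<interval>.csv`` (+ JSON sidecars) and
    ``accuracy.json``; whatever is present is summarized, whatever is missing
    is listed under ``gaps``.  Writes ``report.json`` and derived CSV tables
    into ``out_dir`` (defaults to ``run_dir``), and returns the summary dict.
    """
    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir is not None else run_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"inventory": [], "gaps": []}

    areas_path = run_dir / "areas.csv"
    if areas_path.exists():
        areas = pd.read_csv(areas_path)
        table = areas.pivot(index="year", columns="class", values="area_ha")
        cover = table.div(table.sum(axis=1), axis=0) * 100.0
        cover_out = out_dir / "percent_cover.csv"
        cover.to_csv(cover_out)
        summary["inventory"].append(areas_path.name)
        summary["percent_cover"] = {
            str(year): {cls: cover.loc[year, cls] for cls in sorted(cover.columns)}
            for year in cover.index
        }
        first, last = table.index[0], table.index[-1]
        total = float(table.loc[first].sum())
        summary["net_change_ha"] = {
            cls: float(table.loc[last, cls] - table.loc[first, cls]) for cls in sorted(table.columns)
        }
        summary["net_change_pct_of_area"] = {
            cls: v / total * 100.0 for cls, v in summary["net_change_ha"].items()
        }
    else:
        summary["gaps"].append("areas.csv")

    matrix_paths = sorted(run_dir.glob("transitions_*.csv"))
    if matrix_paths:
        matrices: dict[str, TransitionMatrix] = {}
        for p in matrix_paths:
            interval = p.stem.replace("transitions_", "")
            matrices[interval] = TransitionMatrix.read_csv(p)
            summary["inventory"].append(p.name)
        labels = list(matrices)
        # explicit mean total: matrices completed from rounded published tables
        # may disagree on total area, and the report must still assemble
        mean_total = float(sum(m.total_area for m in matrices.values()) / len(matrices))
        ii = interval_level(list(matrices.values()), total_area=mean_total, labels=labels)
        summary["interval_intensity"] = {
            "S_t_pct_per_yr": {k: float(v) for k, v in ii.s_t.items()},
            "U_pct_per_yr": float(ii.u),
        }
        category = {}
        for label, m in matrices.items():
            ci = category_level(m, ii.u)
            category[label] = {
                "gain_pct_per_yr": {k: None if pd.isna(v) else float(v) for k, v in ci.gain_intensity.items()},
                "loss_pct_per_yr": {k: None if pd.isna(v) else float(v) for k, v in ci.loss_intensity.items()},
            }
        summary["category_intensity"] = category
        rows = []
        for label, m in matrices.items():
            for name in m.scheme.names:
                ti = transition_level(m, name)
                for src, r in ti.intensity.items():
                    rows.append(
                        {
                            "interval": label,
                            "gaining": name,
                            "from": src,
                            "R_pct_per_yr": r,
                            "W_pct_per_yr": ti.uniform,
                        }
                    )
        pd.DataFrame(rows).to_csv(out_dir / "transition_intensity.csv", index=False)
    else:
        summary["gaps"].append("transitions_*.csv")

    accuracy_path = run_dir / "accuracy.json"
    if accuracy_path.exists():
        with open(accuracy_path) as fh:
            summary["accuracy"] = json.load(fh)
        summary["inventory"].append(accuracy_path.name)
    else:
        summary["gaps"].append("accuracy.json")

    summary["inventory"] = sorted(summary["inventory"])
    summary["gaps"] = sorted(summary["gaps"])
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_round(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
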