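"""File-format plumbing: 16-bit TIFF scans, CSV tables with provenance
headers, JSON/YAML configuration, and truth sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ArrayGeometry
from .panel import PanelDefinition, PanelEntry
from .simulate import SimulationTruth

__all__ = [
    "load_config",
    "config_hash",
    "geometry_from_config",
    "panel_from_config",
    "read_scan",
    "write_scan",
    "write_table",
    "read_table",
    "write_truth_sidecar",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a config for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def geometry_from_config(cfg: dict | None) -> ArrayGeometry:
    cfg = dict(cfg or {})
    if "post_offsets_um" in cfg:
        cfg["post_offsets_um"] = tuple(tuple(p) for p in cfg["post_offsets_um"])
    return ArrayGeometry(**cfg)


def panel_from_config(entries: list[dict] | None) -> PanelDefinition:
    if entries is None:
        from .panel import default_panel

        return default_panel()
    return PanelDefinition(
        entries=tuple(
            PanelEntry(int(e["post_index"]), str(e["target"]), str(e["role"]))
            for e in entries
        )
    )


def read_scan(path: str | Path) -> np.ndarray:
    image = tifffile.imread(path)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale scan, got shape {image.shape}")
    return image


def write_scan(path: str | Path, image: np.ndarray, description: str = "") -> None:
    tifffile.imwrite(path, image.astype(np.uint16), description=description)


def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    """CSV with a leading provenance comment line (config hash + seed)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_truth_sidecar(truth: SimulationTruth, out_dir: str | Path, provenance: str = "") -> None:
    """Ground truth as JSON (scalars) + CSV (one row per post)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {
        "background": truth.background,
        "noise_model": truth.noise_model,
        "noise_sigma": truth.noise_sigma,
        "seed": truth.seed,
        "grid_anchor": list(truth.grid_anchor),
        "label_counts": truth.label_counts(),
        "provenance": provenance,
    }
    (out_dir / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    n_rows, n_cols, n_posts = truth.intensities.shape
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            for p in range(n_posts):
                rows.append(
                    {
                        "well_row": r,
                        "well_col": c,
                        "post_index": p,
                        "true_intensity": truth.intensities[r, c, p],
                        "label": truth.labels[r, c, p],
                        "tissue_fraction": (
                            truth.tissue_fraction[r, c]
                            if truth.tissue_fraction is not None
                            else np.nan
                        ),
                    }
                )
    write_table(pd.DataFrame(rows), out_dir / "truth.csv", provenance)
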