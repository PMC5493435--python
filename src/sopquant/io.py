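"""File formats and run configuration.

Tabular data is CSV throughout (diffable, test-friendly); nested reports are
JSON; images are single-channel TIFF (16-bit grey values, 8-bit masks).

Schemas:

* outline CSV — header ``x,y``; 0-based subpixel vertex coordinates, y down.
* profiles CSV — header ``cell_id,k,arc_position,grey_value``; one block of
  rows per cell, k = 1..N.
* divisions CSV — header ``cell_id,i_a,i_b,ax_dx,ax_dy,ap_dx,ap_dy``.
* contingency CSV — first column = row labels (genotypes), remaining column
  headers = defect categories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .divisions import DivisionRecord
from .group_stats import ContingencyTable
from .profiles import CellOutline, IntensityProfile

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "write_mask",
    "read_outline_csv",
    "write_outline_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_divisions_csv",
    "write_divisions_csv",
    "read_contingency_csv",
    "write_contingency_csv",
    "write_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide settings shared by the CLI commands."""

    n_profile_samples: int = 100
    line_width: float = 3.0
    background_mode: str = "auto"  # auto | fixed | none
    background_value: float = 0.0  # used when background_mode == "fixed"
    min_n: int = 8
    seed: int = 0
    pixel_scale: float | None = None  # um/px; arc positions in px when None
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.min_n < 3:
            raise ValueError("min_n must be >= 3")
        if self.n_profile_samples < self.min_n:
            raise ValueError("n_profile_samples must be >= min_n")
        if self.background_mode not in ("auto", "fixed", "none"):
            raise ValueError("background_mode must be auto, fixed or none")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return d


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return img.astype(float)


def write_image(path, image: np.ndarray) -> None:
    """Write grey values as 16-bit TIFF (clipped to the representable range)."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_outline_csv(path) -> CellOutline:
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: outline CSV needs columns x,y")
    return CellOutline(df[["x", "y"]].to_numpy(float))


def write_outline_csv(path, outline: CellOutline) -> None:
    pd.DataFrame(outline.vertices, columns=["x", "y"]).to_csv(path, index=False)


def read_profiles_csv(path) -> dict[str, IntensityProfile]:
    df = pd.read_csv(path)
    if df.empty:
        return {}
    need = {"cell_id", "k", "arc_position", "grey_value"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: profiles CSV needs columns {sorted(need)}")
    out: dict[str, IntensityProfile] = {}
    for cell_id, block in df.groupby("cell_id", sort=False):
        block = block.sort_values("k")
        out[str(cell_id)] = IntensityProfile(
            values=block["grey_value"].to_numpy(float),
            arc_positions=block["arc_position"].to_numpy(float),
            normalized=False,
        )
    return out


def write_profiles_csv(path, profiles: dict[str, IntensityProfile]) -> None:
    frames = []
    for cell_id, prof in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "k": np.arange(1, prof.n + 1),
                    "arc_position": prof.arc_positions,
                    "grey_value": prof.values,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "k", "arc_position", "grey_value"]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_divisions_csv(path) -> list[DivisionRecord]:
    df = pd.read_csv(path)
    need = {"cell_id", "i_a", "i_b", "ax_dx", "ax_dy", "ap_dx", "ap_dy"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: divisions CSV needs columns {sorted(need)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DivisionRecord(
                cell_id=str(row.cell_id),
                intensity_a=float(row.i_a),
                intensity_b=float(row.i_b),
                daughter_axis=(float(row.ax_dx), float(row.ax_dy)),
                ap_axis=(float(row.ap_dx), float(row.ap_dy)),
            )
        )
    return records


def write_divisions_csv(path, records: list[DivisionRecord]) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "i_a": [r.intensity_a for r in records],
            "i_b": [r.intensity_b for r in records],
            "ax_dx": [r.daughter_axis[0] for r in records],
            "ax_dy": [r.daughter_axis[1] for r in records],
            "ap_dx": [r.ap_axis[0] for r in records],
            "ap_dy": [r.ap_axis[1] for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_contingency_csv(path) -> ContingencyTable:
    df = pd.read_csv(path, index_col=0)
    return ContingencyTable(
        counts=df.to_numpy(int),
        row_labels=[str(x) for x in df.index],
        col_labels=[str(x) for x in df.columns],
    )


def write_contingency_csv(path, table: ContingencyTable) -> None:
    pd.DataFrame(table.counts, index=table.row_labels, columns=table.col_labels).to_csv(path)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
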