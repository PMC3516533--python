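"""Co-registered gridded layers, occurrence maps and their readers/writers.

Every object in the package lives on a shared rectangular :class:`Grid`
whose cells are ordered row-major with 0-based ``(row, col)`` indices.
Cells are equal-weight: range sizes are cell counts, never areas.  Two
on-disk formats are supported: a wide CSV (one row per cell, columns
``cell_id, row, col`` then one column per layer) and a multi-band TIFF
("geotiff" format label) with a JSON description tag carrying names,
period, threshold and the optional affine geo-transform.

Missing climate propagates: a cell that is missing any variable is
excluded from model fitting and projected as missing (NaN).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "Grid",
    "ClimateLayerSet",
    "OccurrenceMap",
    "SuitabilityMap",
    "BinaryRangeMap",
    "GridAlignmentError",
    "GridStructureError",
    "assert_aligned",
    "read_layers",
    "read_suitability",
    "read_binary",
    "read_occurrence",
    "write_layers",
]

#: occurrence status codes
PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1


class GridStructureError(ValueError):
    """Raised for ragged/duplicated cell structure in a file or object."""


class GridAlignmentError(ValueError):
    """Raised when two gridded objects do not share the same grid."""


@dataclass(frozen=True)
class Grid:
    """A rectangular grid of ``n_rows x n_cols`` cells in row-major order."""

    n_rows: int
    n_cols: int
    cell_ids: tuple
    geo_transform: tuple | None = None

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridStructureError("grid dimensions must be positive")
        if len(self.cell_ids) != self.n_rows * self.n_cols:
            raise GridStructureError(
                f"expected {self.n_rows * self.n_cols} cell ids, got {len(self.cell_ids)}"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise GridStructureError("cell_ids are not unique")

    @classmethod
    def regular(cls, n_rows: int, n_cols: int, geo_transform: tuple | None = None) -> "Grid":
        """Grid with integer cell ids ``row * n_cols + col``."""
        return cls(n_rows, n_cols, tuple(range(n_rows * n_cols)), geo_transform)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def rows(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_rows), self.n_cols)

    def cols(self) -> np.ndarray:
        return np.tile(np.arange(self.n_cols), self.n_rows)

    def to_array(self, values: np.ndarray) -> np.ndarray:
        """Reshape a row-major cell vector into an ``(n_rows, n_cols)`` array."""
        return np.asarray(values).reshape(self.n_rows, self.n_cols)


def assert_aligned(a, b) -> None:
    """Raise :class:`GridAlignmentError` unless ``a`` and ``b`` share a grid.

    Shared means identical dimensions and identical cell-id order; the
    error names the first discrepancy found.
    """
    ga, gb = a.grid if hasattr(a, "grid") else a, b.grid if hasattr(b, "grid") else b
    if (ga.n_rows, ga.n_cols) != (gb.n_rows, gb.n_cols):
        raise GridAlignmentError(
            f"grid shape mismatch: {ga.n_rows}x{ga.n_cols} vs {gb.n_rows}x{gb.n_cols}"
        )
    if ga.cell_ids != gb.cell_ids:
        for i, (x, y) in enumerate(zip(ga.cell_ids, gb.cell_ids)):
            if x != y:
                raise GridAlignmentError(f"cell_ids differ first at index {i}: {x!r} vs {y!r}")
        raise GridAlignmentError("cell_ids differ")  # pragma: no cover


@dataclass
class ClimateLayerSet:
    """Named climate variables on a common grid, tagged with a period label.

    All variables share one missing mask: a cell missing any variable is
    set to NaN in every variable on construction.
    """

    grid: Grid
    period: str
    variables: dict

    def __post_init__(self):
        clean = {}
        for name, vals in self.variables.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (self.grid.n_cells,):
                raise GridStructureError(
                    f"variable {name!r}: expected {self.grid.n_cells} values, got {arr.shape}"
                )
            clean[name] = arr.copy()
        if not clean:
            raise GridStructureError("a ClimateLayerSet needs at least one variable")
        missing = np.zeros(self.grid.n_cells, dtype=bool)
        for arr in clean.values():
            missing |= ~np.isfinite(arr)
        for arr in clean.values():
            arr[missing] = np.nan
        self.variables = clean

    @property
    def names(self) -> list:
        return list(self.variables)

    @property
    def missing(self) -> np.ndarray:
        first = next(iter(self.variables.values()))
        return ~np.isfinite(first)

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack variables into an ``(n_cells, n_vars)`` design block."""
        names = list(self.variables) if names is None else list(names)
        for n in names:
            if n not in self.variables:
                raise KeyError(f"unknown climate variable {n!r}")
        return np.column_stack([self.variables[n] for n in names])

    def with_variable(self, name: str, values: np.ndarray) -> "ClimateLayerSet":
        new = dict(self.variables)
        new[name] = np.asarray(values, dtype=float)
        return ClimateLayerSet(self.grid, self.period, new)


@dataclass
class OccurrenceMap:
    """Per-cell presence/absence/unknown status for one species."""

    grid: Grid
    species: str
    status: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.status)
        if arr.shape != (self.grid.n_cells,):
            raise GridStructureError(
                f"status: expected {self.grid.n_cells} values, got {arr.shape}"
            )
        arr = arr.astype(np.int8)
        bad = ~np.isin(arr, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            raise ValueError(f"invalid occurrence status values: {np.unique(arr[bad])}")
        self.status = arr

    @property
    def surveyed(self) -> np.ndarray:
        return self.status != UNKNOWN

    @property
    def presence(self) -> np.ndarray:
        return self.status == PRESENT

    def prevalence(self, cells: np.ndarray | None = None) -> float:
        """#present / (#present + #absent), optionally restricted to ``cells``."""
        status = self.status if cells is None else self.status[np.asarray(cells)]
        n_pres = int((status == PRESENT).sum())
        n_abs = int((status == ABSENT).sum())
        if n_pres + n_abs == 0:
            raise ValueError("prevalence undefined: no surveyed cells")
        return n_pres / (n_pres + n_abs)


@dataclass
class SuitabilityMap:
    """Occurrence probability per cell from one model, an ensemble or truth."""

    grid: Grid
    species: str
    period: str
    probability: np.ndarray
    source: str = "unknown"

    def __post_init__(self):
        arr = np.asarray(self.probability, dtype=float)
        if arr.shape != (self.grid.n_cells,):
            raise GridStructureError(
                f"probability: expected {self.grid.n_cells} values, got {arr.shape}"
            )
        finite = np.isfinite(arr)
        if finite.any() and ((arr[finite] < -1e-9) | (arr[finite] > 1 + 1e-9)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        self.probability = np.clip(arr, 0.0, 1.0, where=finite, out=arr)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.probability)


@dataclass
class BinaryRangeMap:
    """Thresholded presence/absence projection with the cutoff it used."""

    grid: Grid
    species: str
    period: str
    presence: np.ndarray
    threshold: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = np.asarray(self.presence, dtype=bool)
        if arr.shape != (self.grid.n_cells,):
            raise GridStructureError(
                f"presence: expected {self.grid.n_cells} values, got {arr.shape}"
            )
        self.presence = arr
        if self.missing is None:
            self.missing = np.zeros(self.grid.n_cells, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        self.presence = self.presence & ~self.missing


# ---------------------------------------------------------------------------
# I/O


def _base_frame(grid: Grid) -> pd.DataFrame:
    return pd.DataFrame(
        {"cell_id": list(grid.cell_ids), "row": grid.rows(), "col": grid.cols()}
    )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _meta_for(obj) -> dict:
    if isinstance(obj, ClimateLayerSet):
        return {"kind": "climate", "period": obj.period, "names": obj.names}
    if isinstance(obj, SuitabilityMap):
        return {
            "kind": "suitability",
            "species": obj.species,
            "period": obj.period,
            "source": obj.source,
            "names": ["probability"],
        }
    if isinstance(obj, BinaryRangeMap):
        return {
            "kind": "binary",
            "species": obj.species,
            "period": obj.period,
            "threshold": obj.threshold,
            "names": ["presence"],
        }
    if isinstance(obj, OccurrenceMap):
        return {"kind": "occurrence", "species": obj.species, "names": ["status"]}
    raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def _layer_stack(obj) -> np.ndarray:
    if isinstance(obj, ClimateLayerSet):
        return np.stack([obj.variables[n] for n in obj.names])
    if isinstance(obj, SuitabilityMap):
        return obj.probability[None, :]
    if isinstance(obj, BinaryRangeMap):
        vals = obj.presence.astype(float)
        vals[obj.missing] = np.nan
        return vals[None, :]
    if isinstance(obj, OccurrenceMap):
        return obj.status.astype(float)[None, :]
    raise TypeError(type(obj).__name__)


def write_layers(obj, path, format: str = "csv") -> None:
    """Write a gridded object to ``path`` in ``"csv"`` or ``"geotiff"`` format.

    CSV files get a JSON sidecar (``<name>.meta.json``) with species,
    period and threshold metadata; the TIFF flavour embeds the same JSON
    in the image description tag.  Binary maps are written as 0/1 with
    the threshold recorded in the metadata.
    """
    path = Path(path)
    meta = _meta_for(obj)
    if obj.grid.geo_transform is not None:
        meta["geo_transform"] = list(obj.grid.geo_transform)
    if format == "csv":
        frame = _base_frame(obj.grid)
        for name, vals in zip(meta["names"], _layer_stack(obj)):
            frame[name] = obj.status if meta["kind"] == "occurrence" else vals
        frame.to_csv(path, index=False, float_format="%.17g")
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    elif format in ("geotiff", "tiff"):
        import tifffile

        stack = _layer_stack(obj)
        data = stack.reshape(len(stack), obj.grid.n_rows, obj.grid.n_cols)
        meta["cell_ids"] = list(obj.grid.cell_ids)
        if meta["kind"] == "occurrence":
            meta["status_codes"] = {"present": PRESENT, "absent": ABSENT, "unknown": UNKNOWN}
        tifffile.imwrite(
            path,
            data.astype(np.float64),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        raise ValueError(f"unsupported format {format!r}; use 'csv' or 'geotiff'")


def _read_table(path: Path, format: str):
    """Return (grid, meta, {name: values}) for either on-disk format."""
    if format == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        for col in ("cell_id", "row", "col"):
            if col not in frame.columns:
                raise GridStructureError(f"CSV is missing required column {col!r}")
        if frame["cell_id"].duplicated().any():
            dups = frame.loc[frame["cell_id"].duplicated(), "cell_id"].tolist()
            raise GridStructureError(f"duplicate cell_id(s): {dups[:5]}")
        n_rows = int(frame["row"].max()) + 1
        n_cols = int(frame["col"].max()) + 1
        if len(frame) != n_rows * n_cols:
            have = set(zip(frame["row"], frame["col"]))
            missing = [
                r * n_cols + c
                for r in range(n_rows)
                for c in range(n_cols)
                if (r, c) not in have
            ]
            raise GridStructureError(
                f"ragged grid: {len(missing)} missing cell(s), first ids {missing[:5]}"
            )
        frame = frame.sort_values(["row", "col"], kind="stable")
        meta = {}
        sidecar = _sidecar(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        gt = tuple(meta["geo_transform"]) if "geo_transform" in meta else None
        grid = Grid(n_rows, n_cols, tuple(frame["cell_id"].tolist()), gt)
        names = meta.get(
            "names", [c for c in frame.columns if c not in ("cell_id", "row", "col")]
        )
        return grid, meta, {n: frame[n].to_numpy(dtype=float) for n in names}
    if format in ("geotiff", "tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        if data.ndim == 2:
            data = data[None, :, :]
        n_rows, n_cols = data.shape[-2:]
        gt = tuple(meta["geo_transform"]) if "geo_transform" in meta else None
        ids = tuple(meta["cell_ids"]) if "cell_ids" in meta else tuple(range(n_rows * n_cols))
        grid = Grid(n_rows, n_cols, ids, gt)
        values = {n: data[i].reshape(-1) for i, n in enumerate(meta["names"])}
        return grid, meta, values
    raise ValueError(f"unsupported format {format!r}; use 'csv' or 'geotiff'")


def read_layers(path, format: str = "csv") -> ClimateLayerSet:
    """Read a :class:`ClimateLayerSet`; see :func:`write_layers` for layout."""
    grid, meta, values = _read_table(Path(path), format)
    return ClimateLayerSet(grid, meta.get("period", "current"), values)


def read_suitability(path, format: str = "csv") -> SuitabilityMap:
    grid, meta, values = _read_table(Path(path), format)
    return SuitabilityMap(
        grid,
        meta.get("species", "unknown"),
        meta.get("period", "current"),
        values["probability"],
        meta.get("source", "unknown"),
    )


def read_binary(path, format: str = "csv") -> BinaryRangeMap:
    grid, meta, values = _read_table(Path(path), format)
    vals = values["presence"]
    missing = ~np.isfinite(vals)
    return BinaryRangeMap(
        grid,
        meta.get("species", "unknown"),
        meta.get("period", "current"),
        np.where(missing, False, vals > 0.5),
        float(meta.get("threshold", np.nan)),
        missing,
    )


def read_occurrence(path, format: str = "csv") -> OccurrenceMap:
    grid, meta, values = _read_table(Path(path), format)
    vals = values["status"]
    status = np.where(np.isfinite(vals), vals, UNKNOWN).astype(np.int8)
    return OccurrenceMap(grid, meta.get("species", "unknown"), status)
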