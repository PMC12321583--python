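"""Tabular data model: cell and plaque centroid tables and image metadata.

Conventions shared by the whole package:

* coordinates are micrometres, continuous, 0-based, local to one image
  (origin at the image corner); there is no global registration,
* the hierarchy is ``group`` -> ``replicate_id`` (animal) -> ``image_id``,
* ``confetti_color`` comes from the closed vocabulary
  ``{none, nGFP, YFP, RFP, mCFP}``,
* CSV with a comma delimiter is canonical (TSV accepted via ``sep``);
  floats are written with pandas' shortest round-trip representation so
  that ``read(write(T)) == T`` exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import COLOR_NONE, CONFETTI_COLORS

COLOR_VOCAB = (COLOR_NONE,) + CONFETTI_COLORS

CELL_REQUIRED = [
    "group", "replicate_id", "image_id", "cell_id",
    "x_um", "y_um", "z_um", "confetti_color", "pu1",
]
CELL_OPTIONAL = [
    "cd11c", "tmem119", "iba1", "plaque_contact",
    "dist_to_plaque_um", "state", "founder_id",
]
PLAQUE_REQUIRED = [
    "group", "replicate_id", "image_id", "plaque_id",
    "x_um", "y_um", "z_um", "volume_um3",
]


class TableValidationError(ValueError):
    """A table violated the schema; the message lists offending rows."""


@dataclass(frozen=True)
class ImageMeta:
    """Physical extent of one image in micrometres."""

    image_id: str
    lx_um: float
    ly_um: float
    lz_um: float

    def __post_init__(self) -> None:
        if min(self.lx_um, self.ly_um, self.lz_um) <= 0:
            raise TableValidationError(
                f"image {self.image_id!r}: extents must be > 0")

    @property
    def extent(self) -> tuple[float, float, float]:
        return (self.lx_um, self.ly_um, self.lz_um)


def _rows(mask: pd.Series, limit: int = 10) -> str:
    idx = [int(i) for i in np.flatnonzero(np.asarray(mask))[:limit]]
    more = "" if int(mask.sum()) <= limit else f" (+{int(mask.sum()) - limit} more)"
    return f"rows {idx}{more}"


def _check_extent(df: pd.DataFrame, metas: Mapping[str, ImageMeta],
                  allow_outside: bool, what: str) -> pd.DataFrame:
    missing = set(df["image_id"].unique()) - set(metas)
    if missing:
        raise TableValidationError(
            f"{what}: no ImageMeta for images {sorted(missing)}")
    lx = df["image_id"].map(lambda i: metas[i].lx_um)
    ly = df["image_id"].map(lambda i: metas[i].ly_um)
    lz = df["image_id"].map(lambda i: metas[i].lz_um)
    outside = ((df["x_um"] < 0) | (df["x_um"] > lx)
               | (df["y_um"] < 0) | (df["y_um"] > ly)
               | (df["z_um"] < 0) | (df["z_um"] > lz))
    if outside.any():
        if not allow_outside:
            raise TableValidationError(
                f"{what}: coordinates outside the image extent at "
                f"{_rows(outside)}; pass allow_outside=True to keep them flagged")
        df = df.copy()
        df["outside_extent"] = outside.to_numpy()
    return df


def validate_cells(df: pd.DataFrame, metas: Mapping[str, ImageMeta] | None = None,
                   allow_outside: bool = False) -> pd.DataFrame:
    missing = [c for c in CELL_REQUIRED if c not in df.columns]
    if missing:
        raise TableValidationError(f"cell table missing columns {missing}")
    df = df.reset_index(drop=True)
    bad = ~df["confetti_color"].isin(COLOR_VOCAB)
    if bad.any():
        offenders = sorted(df.loc[bad, "confetti_color"].unique())
        raise TableValidationError(
            f"unknown confetti_color token(s) {offenders} at {_rows(bad)}; "
            f"allowed vocabulary: {list(COLOR_VOCAB)}")
    dup = df.duplicated(subset=["image_id", "cell_id"], keep=False)
    if dup.any():
        raise TableValidationError(
            f"cell_id not unique within image at {_rows(dup)}")
    for col in ("x_um", "y_um", "z_um"):
        df[col] = pd.to_numeric(df[col])
    df["pu1"] = df["pu1"].astype(bool)
    if metas is not None:
        df = _check_extent(df, metas, allow_outside, "cell table")
    return df


def validate_plaques(df: pd.DataFrame, metas: Mapping[str, ImageMeta] | None = None,
                     allow_outside: bool = False) -> pd.DataFrame:
    missing = [c for c in PLAQUE_REQUIRED if c not in df.columns]
    if missing:
        raise TableValidationError(f"plaque table missing columns {missing}")
    df = df.reset_index(drop=True)
    for col in ("x_um", "y_um", "z_um", "volume_um3"):
        df[col] = pd.to_numeric(df[col])
    nonpos = df["volume_um3"] <= 0
    if nonpos.any():
        raise TableValidationError(
            f"plaque volume_um3 must be > 0; violated at {_rows(nonpos)}")
    dup = df.duplicated(subset=["image_id", "plaque_id"], keep=False)
    if dup.any():
        raise TableValidationError(
            f"plaque_id not unique within image at {_rows(dup)}")
    if metas is not None:
        df = _check_extent(df, metas, allow_outside, "plaque table")
    return df


def _ordered(df: pd.DataFrame, required: list[str], optional: list[str]) -> list[str]:
    cols = list(required)
    cols += [c for c in optional if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return cols


def _float_repr(x: float) -> str:
    # shortest representation that round-trips exactly
    return repr(float(x))


def read_cells(path: str | Path, metas: Mapping[str, ImageMeta] | None = None,
               sep: str = ",", allow_outside: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_cells(df, metas, allow_outside)


def read_plaques(path: str | Path, metas: Mapping[str, ImageMeta] | None = None,
                 sep: str = ",", allow_outside: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_plaques(df, metas, allow_outside)


def write_cells(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=_float_repr,
              columns=_ordered(df, CELL_REQUIRED, CELL_OPTIONAL),
              lineterminator="\n")


def write_plaques(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=_float_repr,
              columns=_ordered(df, PLAQUE_REQUIRED, []),
              lineterminator="\n")


def read_image_meta(path: str | Path, sep: str = ",") -> dict[str, ImageMeta]:
    df = pd.read_csv(path, sep=sep)
    need = ["image_id", "lx_um", "ly_um", "lz_um"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise TableValidationError(f"image meta table missing columns {missing}")
    return {
        str(r.image_id): ImageMeta(str(r.image_id), float(r.lx_um),
                                   float(r.ly_um), float(r.lz_um))
        for r in df.itertuples()
    }


def write_image_meta(metas: Mapping[str, ImageMeta], path: str | Path,
                     sep: str = ",") -> None:
    df = pd.DataFrame(
        [{"image_id": m.image_id, "lx_um": m.lx_um, "ly_um": m.ly_um,
          "lz_um": m.lz_um} for m in metas.values()]
    ).sort_values("image_id")
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_results(obj, path: str | Path) -> None:
    """Write an analysis result (nested dicts/arrays) as deterministic JSON."""
    Path(path).write_text(
        json.dumps(obj, cls=_NumpyEncoder, indent=2, sort_keys=True) + "\n")
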