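"""Plaque-proximity cell-state classification (PAM vs non-PAM).

A cell is plaque-associated (PAM) when its body lies within a contact
radius — 30 um by default — of an amyloid deposit, or when an upstream,
mask-based ``plaque_contact`` flag is present and set.  Only centroid and
volume survive tabulation, so plaques are modeled as spheres of equivalent
volume; distances are measured to the sphere surface by default (centroid
optionally, via ``StateRule.to_surface=False``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import COLOR_NONE

STATE_PAM = "PAM"
STATE_NONPAM = "nonPAM"


@dataclass(frozen=True)
class StateRule:
    """Classification rule.  ``contact_radius_um`` is inclusive (<=)."""

    contact_radius_um: float = 30.0
    to_surface: bool = True  # measure to the equivalent-sphere surface
    use_contact_column: bool = True  # honor an upstream plaque_contact flag

    def __post_init__(self) -> None:
        if self.contact_radius_um <= 0:
            raise ValueError("contact_radius_um must be > 0")


def equivalent_radius(volume_um3) -> np.ndarray:
    """Radius of the sphere with the given volume."""
    return (3.0 * np.asarray(volume_um3, dtype=float) / (4.0 * np.pi)) ** (1.0 / 3.0)


def distance_to_nearest_plaque(cells: pd.DataFrame, plaques: pd.DataFrame,
                               rule: StateRule = StateRule()) -> pd.Series:
    """Per-cell distance (um) to the nearest plaque in the same image.

    Surface distance is ``max(0, |centroid distance| - r_p)``; cells in
    images without plaques get ``+inf``.
    """
    out = np.full(len(cells), np.inf)
    pl_by_img = dict(tuple(plaques.groupby("image_id", sort=False))) if len(plaques) else {}
    for img, idx in cells.groupby("image_id", sort=False).indices.items():
        pl = pl_by_img.get(img)
        if pl is None or not len(pl):
            continue
        cxyz = cells.iloc[idx][["x_um", "y_um", "z_um"]].to_numpy(float)
        pxyz = pl[["x_um", "y_um", "z_um"]].to_numpy(float)
        d = np.linalg.norm(cxyz[:, None, :] - pxyz[None, :, :], axis=2)
        if rule.to_surface:
            d = np.maximum(d - equivalent_radius(pl["volume_um3"])[None, :], 0.0)
        out[idx] = d.min(axis=1)
    return pd.Series(out, index=cells.index, name="dist_to_plaque_um")


def classify_cells(cells: pd.DataFrame, plaques: pd.DataFrame,
                   rule: StateRule = StateRule()) -> pd.DataFrame:
    """Add ``state`` (PAM / nonPAM) and ``dist_to_plaque_um`` columns.

    PAM iff the upstream ``plaque_contact`` flag is set (when present and
    honored) or the plaque distance is <= the contact radius.  Images
    without plaques yield 100% non-PAM.
    """
    cells = cells.copy()
    dist = distance_to_nearest_plaque(cells, plaques, rule)
    pam = dist.to_numpy() <= rule.contact_radius_um
    if rule.use_contact_column and "plaque_contact" in cells.columns:
        pam |= cells["plaque_contact"].fillna(False).astype(bool).to_numpy()
    cells["dist_to_plaque_um"] = dist.to_numpy()
    cells["state"] = np.where(pam, STATE_PAM, STATE_NONPAM)
    return cells


def plaques_with_pam_fraction(cells: pd.DataFrame, plaques: pd.DataFrame,
                              rule: StateRule = StateRule(),
                              marker: str | None = None) -> pd.DataFrame:
    """Per-image fraction of plaques decorated by at least one PAM.

    A plaque counts as decorated when >= 1 cell (optionally restricted to
    ``marker``-positive cells, e.g. ``cd11c``) lies within the contact
    radius of *that* plaque under the sphere model.  Images with zero
    plaques report a missing fraction (NaN), not 0.
    """
    sel = cells
    if marker is not None:
        if marker not in cells.columns:
            raise KeyError(f"marker column {marker!r} not in cell table")
        sel = cells[cells[marker].astype(bool)]
    rows = []
    cells_by_img = dict(tuple(sel.groupby("image_id", sort=False))) if len(sel) else {}
    for (grp, rep, img), pl in plaques.groupby(
            ["group", "replicate_id", "image_id"], sort=True):
        cc = cells_by_img.get(img)
        n_pl = len(pl)
        if cc is None or not len(cc):
            n_with = 0
        else:
            cxyz = cc[["x_um", "y_um", "z_um"]].to_numpy(float)
            pxyz = pl[["x_um", "y_um", "z_um"]].to_numpy(float)
            d = np.linalg.norm(cxyz[:, None, :] - pxyz[None, :, :], axis=2)
            if rule.to_surface:
                d = np.maximum(d - equivalent_radius(pl["volume_um3"])[None, :], 0.0)
            n_with = int((d <= rule.contact_radius_um).any(axis=0).sum())
        rows.append({"group": grp, "replicate_id": rep, "image_id": img,
                     "n_plaques": n_pl, "n_with_pam": n_with,
                     "fraction": n_with / n_pl if n_pl else np.nan})
    # images present in the cell table but without any plaque rows
    seen = {r["image_id"] for r in rows}
    for (grp, rep, img), _ in cells.groupby(
            ["group", "replicate_id", "image_id"], sort=True):
        if img not in seen:
            rows.append({"group": grp, "replicate_id": rep, "image_id": img,
                         "n_plaques": 0, "n_with_pam": 0, "fraction": np.nan})
    return pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True)


def confetti_cells_near_plaques(cells: pd.DataFrame, plaques: pd.DataFrame,
                                radius_um: float = 30.0,
                                rule: StateRule = StateRule()) -> pd.DataFrame:
    """Per-replicate count of Confetti+ cells within ``radius_um`` of a plaque.

    The per-animal summary behind ring-distance bar plots: labeled cells
    whose plaque surface distance is <= the radius, tabulated by group and
    replicate (replicates with no such cells report 0).
    """
    cells = cells.copy()
    cells["_near"] = (
        (distance_to_nearest_plaque(cells, plaques, rule).to_numpy() <= radius_um)
        & (cells["confetti_color"] != COLOR_NONE).to_numpy())
    out = (cells.groupby(["group", "replicate_id"], sort=True)["_near"]
           .sum().astype(int).rename("n_cells").reset_index())
    return out
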