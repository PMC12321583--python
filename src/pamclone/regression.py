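"""Clone-size / plaque-size regression and clone summary statistics.

Each data point is one (clone, contacted plaque) pair: a clone touching k
plaques contributes k points, a plaque touched by m clones contributes m —
contacts are the unit, never averaged within a clone.  Fits are ordinary
least squares with Pearson R and a two-sided t test on n-2 degrees of
freedom, optionally stratified by plaque volume at a 1,000 um^3 cutoff
(ties at the cutoff go to the small stratum).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .config import COLOR_NONE
from .proximity import STATE_NONPAM, STATE_PAM
from .voronoi import CloneSet, Tessellation, clone_plaque_contacts

STRATA = ("all", "small", "large")
DEFAULT_CUTOFF_UM3 = 1000.0


@dataclass(frozen=True)
class RegressionSummary:
    stratum: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    slope_se: float
    p_defined: bool

    def to_dict(self) -> dict:
        return {"stratum": self.stratum, "n": self.n, "r": self.r,
                "p": self.p, "slope": self.slope,
                "intercept": self.intercept, "slope_se": self.slope_se,
                "p_defined": self.p_defined}


def make_contact_pairs(clone_sets: list[tuple[CloneSet, Tessellation]],
                       plaques: pd.DataFrame) -> pd.DataFrame:
    """Pair table for regression: one row per clone-to-plaque contact.

    Columns: image_id, clone_id, plaque_id, volume_um3 (x) and clone_size
    (y, member cell count).
    """
    vol = {(str(r.image_id), str(r.plaque_id)): float(r.volume_um3)
           for r in plaques.itertuples()}
    rows = []
    for cs, tess in clone_sets:
        pairs, _ = clone_plaque_contacts(cs, tess)
        size = {c.clone_id: c.n_cells for c in cs.clones}
        terr = {c.clone_id: c.territory_um2 for c in cs.clones}
        for r in pairs.itertuples():
            rows.append({
                "image_id": cs.image_id, "clone_id": r.clone_id,
                "plaque_id": r.plaque_id,
                "volume_um3": vol[(cs.image_id, str(r.plaque_id))],
                "clone_size": size[r.clone_id],
                "clone_territory_um2": terr[r.clone_id]})
    return pd.DataFrame(rows, columns=[
        "image_id", "clone_id", "plaque_id", "volume_um3", "clone_size",
        "clone_territory_um2"])


def stratum_mask(volume_um3: np.ndarray, stratum: str,
                 cutoff: float = DEFAULT_CUTOFF_UM3) -> np.ndarray:
    v = np.asarray(volume_um3, dtype=float)
    if stratum == "all":
        return np.ones(len(v), dtype=bool)
    if stratum == "small":
        return v <= cutoff
    if stratum == "large":
        return v > cutoff
    raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")


def regress_clone_vs_plaque(pairs: pd.DataFrame, stratum: str = "all",
                            cutoff: float = DEFAULT_CUTOFF_UM3,
                            y: str = "clone_size") -> RegressionSummary:
    """Least-squares fit of clone size on plaque volume within a stratum.

    With fewer than 3 pairs the correlation test is undefined and the
    summary is flagged (``p_defined=False``).
    """
    mask = stratum_mask(pairs["volume_um3"].to_numpy(), stratum, cutoff)
    x = pairs.loc[mask, "volume_um3"].to_numpy(float)
    yv = pairs.loc[mask, y].to_numpy(float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        if n >= 2 and np.ptp(x) > 0:
            fit = linregress(x, yv)
            return RegressionSummary(stratum, n, float(fit.rvalue), np.nan,
                                     float(fit.slope), float(fit.intercept),
                                     float(fit.stderr), False)
        return RegressionSummary(stratum, n, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, False)
    fit = linregress(x, yv)
    return RegressionSummary(stratum, n, float(fit.rvalue), float(fit.pvalue),
                             float(fit.slope), float(fit.intercept),
                             float(fit.stderr), True)


def stratified_regressions(pairs: pd.DataFrame,
                           cutoff: float = DEFAULT_CUTOFF_UM3) -> dict:
    """All three strata at once, keyed by stratum name."""
    return {s: regress_clone_vs_plaque(pairs, s, cutoff).to_dict()
            for s in STRATA}


def clone_summaries(clone_frames: pd.DataFrame) -> pd.DataFrame:
    """Group-level distributions of cells/plaques/territory per clone.

    Input is a concatenation of :func:`pamclone.voronoi.clones_to_frame`
    outputs; returns per-group mean/median/count for each quantity.
    """
    g = clone_frames.groupby("group")
    out = g.agg(
        n_clones=("clone_id", "size"),
        cells_per_clone_mean=("n_cells", "mean"),
        cells_per_clone_median=("n_cells", "median"),
        plaques_per_clone_mean=("n_plaques_contacted", "mean"),
        territory_um2_mean=("territory_um2", "mean"),
    ).reset_index()
    return out


def pam_clone_nonpam_association(tess: Tessellation, cells: pd.DataFrame) -> dict:
    """Fraction of PAM clones with an adjacent same-colored non-PAM cell.

    Clones are connected components among Confetti+ PAM cells; a clone is
    'associated' when any member is tessellation-adjacent to a Confetti+
    non-PAM cell of the clone's color.
    """
    from .voronoi import call_clones

    cc = cells[cells["image_id"] == tess.image_id]
    if "state" not in cc.columns:
        raise ValueError("requires classified cells (state column)")
    clone_set = call_clones(tess, cells, subset=STATE_PAM)
    color_of = dict(zip(cc["cell_id"].astype(str), cc["confetti_color"]))
    state_of = dict(zip(cc["cell_id"].astype(str), cc["state"]))
    neigh: dict[int, set[int]] = {}
    for a, b in tess.adjacency:
        neigh.setdefault(a, set()).add(b)
        neigh.setdefault(b, set()).add(a)
    idx_of = tess.cell_index
    n_assoc = 0
    for clone in clone_set.clones:
        found = False
        for cid in clone.member_ids:
            for j in neigh.get(idx_of[cid], ()):
                jid = tess.ids[j]
                if (tess.kinds[j] == "cell"
                        and color_of.get(jid) == clone.color
                        and state_of.get(jid) == STATE_NONPAM):
                    found = True
                    break
            if found:
                break
        n_assoc += found
    n = len(clone_set.clones)
    return {"n_pam_clones": n, "n_associated": n_assoc,
            "fraction_associated": n_assoc / n if n else float("nan")}
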