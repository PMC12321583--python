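"""Monte Carlo ring-density clonality test.

For every Confetti+ origin cell, same-colored Confetti+ neighbors are
counted in concentric annuli of xy-distance — a first ring of 10 um radius,
then 20-um-wide rings out to ``r_max`` (290 um by default).  z is ignored:
each annulus is a cylindrical shell spanning the full image depth, so the
counted volume is ``pi (r2^2 - r1^2) * Lz`` and the reported quantity is a
same-color neighbor density per um^3.  Profiles are averaged per image, then
per replicate, then per experimental group.

The null model permutes Confetti labels uniformly over the positions of all
Pu.1+ cells of the chosen subset, image by image; the two-stage group
average is recomputed for every shuffle and an empirical confidence envelope
(98% by default) is taken per annulus across shuffles.  Where the
experimental confidence interval (Student-t across replicate means) and the
null envelope do not overlap, the hypothesis of random recombination is
rejected (P < 1 - ci), as clonal excess or deficit.

No edge correction is applied to annuli truncated by image borders: the
null is computed in the same geometry, so border effects cancel in the
comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import t as student_t

from .config import COLOR_NONE, CONFETTI_COLORS
from .proximity import STATE_NONPAM, STATE_PAM
from .tables import ImageMeta

SUBSETS = ("all", STATE_PAM, STATE_NONPAM)


@dataclass(frozen=True)
class RingBins:
    """Annulus edges: (0,10], (10,30], ..., (r_max-20, r_max]."""

    edges: np.ndarray

    @property
    def n(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"({e[i]:g},{e[i + 1]:g}]" for i in range(self.n)]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def make_ring_bins(r_max: float = 290.0) -> RingBins:
    if r_max < 10 or (r_max - 10) % 20 != 0:
        raise ValueError(
            f"r_max must be 10 plus a multiple of 20 um, got {r_max!r}")
    edges = np.concatenate([[0.0, 10.0], np.arange(30.0, r_max + 1e-9, 20.0)])
    return RingBins(edges=edges)


def ring_volumes(bins: RingBins, lz_um: float) -> np.ndarray:
    """Volume of each cylindrical annulus (um^3) for image depth ``lz_um``."""
    e = bins.edges
    return np.pi * (e[1:] ** 2 - e[:-1] ** 2) * lz_um


def _subset_mask(cells: pd.DataFrame, subset: str) -> np.ndarray:
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}, got {subset!r}")
    mask = cells["pu1"].astype(bool).to_numpy() if "pu1" in cells.columns \
        else np.ones(len(cells), bool)
    if subset != "all":
        if "state" not in cells.columns:
            raise ValueError("PAM/nonPAM subsets require a 'state' column "
                             "(run classify_cells first)")
        mask &= (cells["state"] == subset).to_numpy()
    return mask


def _bin_indices(dist: np.ndarray, bins: RingBins) -> np.ndarray:
    """Annulus index for each distance; -1 outside all (0, r_max] annuli."""
    b = np.searchsorted(bins.edges, dist, side="left") - 1
    b[(b < 0) | (b >= bins.n)] = -1
    return b


def same_color_counts(cells: pd.DataFrame, bins: RingBins,
                      subset: str = "all"):
    """Per-origin-cell, per-annulus counts of same-colored neighbors.

    Origins and neighbors are both restricted to Confetti+ Pu.1+ cells of
    ``subset`` within one image; the origin itself is excluded.  Returns
    ``(origin_cell_ids, counts)`` with ``counts`` of shape
    ``(n_origins, bins.n)``.
    """
    if cells["image_id"].nunique() > 1:
        raise ValueError("same_color_counts operates on a single image")
    sub = cells[_subset_mask(cells, subset)]
    lab = sub[sub["confetti_color"] != COLOR_NONE]
    n = len(lab)
    counts = np.zeros((n, bins.n), dtype=np.int64)
    if n == 0:
        return lab["cell_id"].tolist(), counts
    xy = lab[["x_um", "y_um"]].to_numpy(float)
    b = _bin_indices(cdist(xy, xy), bins)
    np.fill_diagonal(b, -1)
    colors = lab["confetti_color"].to_numpy()
    same = colors[:, None] == colors[None, :]
    valid = same & (b >= 0)
    rows = np.nonzero(valid)[0]
    np.add.at(counts, (rows, b[valid]), 1)
    return lab["cell_id"].tolist(), counts


@dataclass
class RingProfile:
    """Ring statistics for one image and subset."""

    group: str
    replicate_id: str
    image_id: str
    subset: str
    bins: RingBins
    n_origin_cells: int
    mean_counts: np.ndarray  # per annulus, mean over origin cells
    density: np.ndarray      # mean_counts / annulus volume, um^-3


def ring_density_profile(cells: pd.DataFrame, bins: RingBins, meta: ImageMeta,
                         subset: str = "all") -> RingProfile:
    """Ring-density profile of one image; missing (NaN) with zero origins."""
    ids, counts = same_color_counts(cells, bins, subset)
    n = len(ids)
    if n:
        mean_counts = counts.mean(axis=0)
        density = mean_counts / ring_volumes(bins, meta.lz_um)
    else:
        mean_counts = np.full(bins.n, np.nan)
        density = np.full(bins.n, np.nan)
    first = cells.iloc[0] if len(cells) else None
    return RingProfile(
        group=str(first["group"]) if first is not None else "",
        replicate_id=str(first["replicate_id"]) if first is not None else "",
        image_id=meta.image_id, subset=subset, bins=bins,
        n_origin_cells=n, mean_counts=mean_counts, density=density)


@dataclass
class GroupProfile:
    """Two-stage (image -> replicate -> group) averaged density profile."""

    group: str
    subset: str
    bins: RingBins
    ci: float
    replicate_ids: list[str]
    replicate_means: np.ndarray  # (n_replicates, n_bins)
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    single_replicate: bool = False


def average_profiles(profiles: list[RingProfile], ci: float = 0.98) -> GroupProfile:
    """Average image profiles per replicate, then across replicates.

    The experimental confidence interval is a Student-t interval at level
    ``ci`` on the replicate means.  With a single replicate the interval is
    undefined and flagged.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    bins = profiles[0].bins
    subset = profiles[0].subset
    group = profiles[0].group
    for p in profiles:
        if p.bins.n != bins.n or not np.allclose(p.bins.edges, bins.edges):
            raise ValueError("profiles use different ring bins")
        if p.subset != subset:
            raise ValueError("profiles mix subsets")
    reps: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        reps.setdefault(p.replicate_id, []).append(p.density)
    rep_ids = sorted(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN image sets
        rep_means = np.array([np.nanmean(np.array(reps[r]), axis=0)
                              for r in rep_ids])
        mean = np.nanmean(rep_means, axis=0)
    n_rep = len(rep_ids)
    if n_rep >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(rep_means, axis=0, ddof=1)
            n_eff = np.sum(~np.isnan(rep_means), axis=0)
        n_eff = np.maximum(n_eff, 1)
        tq = student_t.ppf(1 - (1 - ci) / 2, df=np.maximum(n_eff - 1, 1))
        half = np.where(n_eff >= 2, tq * sd / np.sqrt(n_eff), np.nan)
        lower, upper = mean - half, mean + half
        single = False
    else:
        lower = np.full(bins.n, np.nan)
        upper = np.full(bins.n, np.nan)
        single = True
    return GroupProfile(group=group, subset=subset, bins=bins, ci=ci,
                        replicate_ids=rep_ids, replicate_means=rep_means,
                        mean=mean, ci_lower=lower, ci_upper=upper,
                        single_replicate=single)


def group_profile(cells: pd.DataFrame, metas: dict[str, ImageMeta],
                  bins: RingBins, subset: str = "all",
                  ci: float = 0.98) -> GroupProfile:
    """Observed group profile from a multi-image table of one group."""
    profiles = [
        ring_density_profile(cells[cells["image_id"] == img], bins,
                             metas[img], subset)
        for img in sorted(cells["image_id"].unique())
    ]
    return average_profiles(profiles, ci=ci)


def shuffle_labels(cells: pd.DataFrame, rng: np.random.Generator,
                   subset: str = "all") -> pd.DataFrame:
    """One label-shuffle of a single image.

    Confetti colors are reassigned by a uniform permutation over the
    positions of the subset's Pu.1+ cells: the position multiset and the
    per-color counts are unchanged, only the pairing is randomized.
    """
    if cells["image_id"].nunique() > 1:
        raise ValueError("shuffle_labels operates on a single image")
    out = cells.copy()
    mask = _subset_mask(cells, subset)
    idx = np.flatnonzero(mask)
    colors = out["confetti_color"].to_numpy().copy()
    colors[idx] = colors[idx][rng.permutation(len(idx))]
    out["confetti_color"] = colors
    return out


@dataclass
class NullEnvelope:
    """Empirical per-annulus bounds of the shuffled-label null."""

    bins: RingBins
    subset: str
    ci: float
    n_shuffles: int
    seed: int
    lower: np.ndarray
    upper: np.ndarray
    # estimator metadata recorded with every run
    quantile_method: str = "linear (type 7)"


class _RingEngine:
    """Precomputed pairwise annulus indices of one image, for fast shuffles."""

    def __init__(self, xy: np.ndarray, color_codes: np.ndarray,
                 lz_um: float, bins: RingBins):
        self.n = len(xy)
        self.codes = color_codes
        self.nbins = bins.n
        self.ring_vols = ring_volumes(bins, lz_um)
        b = _bin_indices(cdist(xy, xy), bins) if self.n else \
            np.zeros((0, 0), dtype=np.int64)
        if self.n:
            np.fill_diagonal(b, -1)
        self.b = b.astype(np.int8)  # bin count is small; -1 marks "no annulus"
        # The shuffle only moves the fixed color multiset to new positions,
        # so the same-color pair pattern of a sorted color vector is constant
        # and can be precomputed as a block mask.
        self.n_labeled = int((color_codes > 0).sum())
        c0 = np.sort(color_codes[color_codes > 0])
        self._block = c0[:, None] == c0[None, :]

    def density(self, codes: np.ndarray) -> np.ndarray:
        """Ring density for an explicit per-position color assignment."""
        idx = np.flatnonzero(codes)
        if idx.size == 0:
            return np.full(self.nbins, np.nan)
        cnt = np.zeros(self.nbins, dtype=np.int64)
        c = codes[idx]
        for col in np.unique(c):
            ic = idx[c == col]
            sub = self.b[np.ix_(ic, ic)]
            cnt += np.bincount(sub[sub >= 0], minlength=self.nbins)
        return cnt / (idx.size * self.ring_vols)

    def shuffled_density(self, rng: np.random.Generator) -> np.ndarray:
        """One label shuffle: the color multiset lands on random positions.

        Equivalent in distribution to ``density(codes[rng.permutation(n)])``
        but exploits the precomputed same-color block mask.
        """
        if self.n_labeled == 0:
            return np.full(self.nbins, np.nan)
        pos = rng.permutation(self.n)[:self.n_labeled]
        sub = self.b[pos[:, None], pos]
        sel = sub[self._block]
        cnt = np.bincount(sel[sel >= 0], minlength=self.nbins)
        return cnt / (self.n_labeled * self.ring_vols)


def _build_engines(cells: pd.DataFrame, metas: dict[str, ImageMeta],
                   bins: RingBins, subset: str):
    """One engine per image (sorted by image_id) plus the replicate map."""
    engines, rep_of = [], []
    for img in sorted(cells["image_id"].unique()):
        cc = cells[cells["image_id"] == img]
        sub = cc[_subset_mask(cc, subset)]
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        colors = sub["confetti_color"].to_numpy()
        codes = np.zeros(len(sub), dtype=np.int8)
        for k, col in enumerate(CONFETTI_COLORS, start=1):
            codes[colors == col] = k
        engines.append(_RingEngine(xy, codes, metas[img].lz_um, bins))
        rep_of.append(str(sub["replicate_id"].iloc[0]) if len(sub)
                      else str(cc["replicate_id"].iloc[0]))
    return engines, rep_of


def _two_stage(img_densities: np.ndarray, rep_of: list[str]) -> np.ndarray:
    """Image -> replicate -> group mean, NaN-aware."""
    reps = sorted(set(rep_of))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_means = np.array([
            np.nanmean(img_densities[[i for i, r in enumerate(rep_of) if r == rr]],
                       axis=0)
            for rr in reps])
        return np.nanmean(rep_means, axis=0)


def mc_null_envelope(cells: pd.DataFrame, metas: dict[str, ImageMeta],
                     bins: RingBins, n_shuffles: int = 10_000,
                     ci: float = 0.98, seed: int = 0,
                     subset: str = "all") -> NullEnvelope:
    """Shuffled-label null envelope for one group.

    Every shuffle permutes labels independently within each image
    (substream ``(seed, image_index, shuffle)``), recomputes the full
    two-stage group density profile, and the envelope is the pair of
    empirical ``(1-ci)/2`` and ``1-(1-ci)/2`` quantiles per annulus.
    """
    if not 0 < ci < 1:
        raise ValueError("ci must lie in (0, 1)")
    if n_shuffles < 100:
        warnings.warn(
            f"n_shuffles={n_shuffles} < 100: envelope quantiles are poorly "
            "resolved at this level", UserWarning, stacklevel=2)
    engines, rep_of = _build_engines(cells, metas, bins, subset)
    n_img = len(engines)
    img_stats = np.empty((n_shuffles, n_img, bins.n))
    for i in range(n_shuffles):
        for k, eng in enumerate(engines):
            rng = np.random.default_rng([seed, k, i])
            img_stats[i, k] = eng.shuffled_density(rng)
    reps = sorted(set(rep_of))
    groups = [[k for k, r in enumerate(rep_of) if r == rr] for rr in reps]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_means = np.stack(
            [np.nanmean(img_stats[:, g, :], axis=1) for g in groups], axis=1)
        stats = np.nanmean(rep_means, axis=1)
        lower, upper = np.nanquantile(
            stats, [(1 - ci) / 2, 1 - (1 - ci) / 2], axis=0)
    return NullEnvelope(bins=bins, subset=subset, ci=ci,
                        n_shuffles=n_shuffles, seed=seed,
                        lower=lower, upper=upper)


CALL_EXCESS = "excess"
CALL_DEFICIT = "deficit"
CALL_NONE = "none"


@dataclass
class ClonalityCall:
    """Per-annulus decision with both intervals retained."""

    bins: RingBins
    subset: str
    calls: list[str]
    observed: GroupProfile
    null: NullEnvelope


def clonality_decision(observed: GroupProfile,
                       null: NullEnvelope) -> ClonalityCall:
    """Reject randomness per annulus where the two intervals do not overlap.

    ``excess``: the experimental lower bound exceeds the null upper bound;
    ``deficit``: the experimental upper bound is below the null lower bound;
    otherwise ``none`` (including wherever either interval is undefined).
    """
    if observed.bins.n != null.bins.n or \
            not np.allclose(observed.bins.edges, null.bins.edges):
        raise ValueError("observed profile and null envelope bins differ")
    calls = []
    for b in range(null.bins.n):
        lo, hi = observed.ci_lower[b], observed.ci_upper[b]
        nlo, nhi = null.lower[b], null.upper[b]
        if np.isnan(lo) or np.isnan(nhi):
            calls.append(CALL_NONE)
        elif lo > nhi:
            calls.append(CALL_EXCESS)
        elif hi < nlo:
            calls.append(CALL_DEFICIT)
        else:
            calls.append(CALL_NONE)
    return ClonalityCall(bins=null.bins, subset=null.subset, calls=calls,
                         observed=observed, null=null)


def ring_test(cells: pd.DataFrame, metas: dict[str, ImageMeta],
              bins: RingBins, n_shuffles: int = 10_000, ci: float = 0.98,
              seed: int = 0, subset: str = "all") -> ClonalityCall:
    """Observed profile, null envelope and decision for one group/subset."""
    obs = group_profile(cells, metas, bins, subset=subset, ci=ci)
    null = mc_null_envelope(cells, metas, bins, n_shuffles=n_shuffles,
                            ci=ci, seed=seed, subset=subset)
    return clonality_decision(obs, null)
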