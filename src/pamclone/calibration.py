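"""Operating characteristics of the ring clonality test on synthetic tissue.

Two studies used for validation and reporting:

* scrambled-label simulations (null generator) measure the per-annulus
  false-positive rate of the envelope non-overlap decision and the
  empirical coverage of the null envelope at its nominal level;
* planted-clone simulations measure the power to call clonality in the
  innermost annuli while staying silent in the outermost one, and the
  recovery of the generator's clone-size/plaque-volume slope by the
  contact regression.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import COLOR_NONE, SimConfig
from .regression import RegressionSummary, regress_clone_vs_plaque
from .rings import (RingBins, clonality_decision, group_profile,
                    make_ring_bins, mc_null_envelope, CALL_NONE)
from .simulate import simulate_group

_MOD31 = 2 ** 31


def _derive_seed(seed: int, *parts: int) -> int:
    """Deterministic child seed, kept below 2^31."""
    out = seed % _MOD31
    for p in parts:
        out = (out * 1_000_003 + p + 1) % _MOD31
    return out


@dataclass
class ScrambledOps:
    """Null-calibration results over repeated scrambled-label groups."""

    n_groups: int
    n_bins: int
    n_shuffles: int
    ci: float
    calls: np.ndarray        # (n_groups, n_bins) str
    inside: np.ndarray       # (n_groups, n_bins) bool: observed mean in envelope

    @property
    def call_rate(self) -> float:
        return float((self.calls != CALL_NONE).mean())

    @property
    def call_rate_se(self) -> float:
        n = self.calls.size
        p = self.call_rate
        return float(np.sqrt(max(p * (1 - p), 1e-12) / n))

    @property
    def coverage_pct(self) -> float:
        return float(self.inside.mean() * 100.0)

    @property
    def n_draws(self) -> int:
        return int(self.calls.size)


def scrambled_operating_characteristics(
        config: SimConfig | None = None, *, n_groups: int = 300,
        n_shuffles: int = 1000, ci: float = 0.98,
        bins: RingBins | None = None, seed: int = 0,
        n_replicates: int = 3, n_images: int = 3) -> ScrambledOps:
    """Run the full ring test on ``n_groups`` scrambled-label groups.

    Each group is 3 replicates x 3 images (overridable) at the generator's
    default intensities with colors scrambled independently per cell; the
    observed two-stage profile, the shuffled-null envelope and the
    non-overlap decision are recomputed per group.
    """
    base = config if config is not None else SimConfig()
    base = replace(base, n_replicates_per_group=n_replicates,
                   n_images_per_replicate=n_images)
    bins = bins if bins is not None else make_ring_bins()
    calls = np.empty((n_groups, bins.n), dtype=object)
    inside = np.zeros((n_groups, bins.n), dtype=bool)
    for g in range(n_groups):
        cfg = replace(base, seed=_derive_seed(seed, 1, g))
        cells, _, metas = simulate_group(cfg, group=f"g{g}", scramble=True)
        obs = group_profile(cells, metas, bins, subset="all", ci=ci)
        null = mc_null_envelope(cells, metas, bins, n_shuffles=n_shuffles,
                                ci=ci, seed=_derive_seed(seed, 2, g),
                                subset="all")
        calls[g] = clonality_decision(obs, null).calls
        inside[g] = (obs.mean >= null.lower) & (obs.mean <= null.upper)
    return ScrambledOps(n_groups=n_groups, n_bins=bins.n,
                        n_shuffles=n_shuffles, ci=ci, calls=calls,
                        inside=inside)


@dataclass
class PowerStudy:
    n_runs: int
    calls: np.ndarray  # (n_runs, n_bins)

    def rate_in_bin(self, b: int) -> float:
        return float((self.calls[:, b] != CALL_NONE).mean())

    @property
    def success_rate(self) -> float:
        """Fraction of runs calling the innermost annuli and not the outermost.

        Success: clonality called in annulus (0,10] or (10,30] and no call
        in the outermost annulus.
        """
        near = (self.calls[:, 0] != CALL_NONE) | (self.calls[:, 1] != CALL_NONE)
        far_quiet = self.calls[:, -1] == CALL_NONE
        return float((near & far_quiet).mean())


def planted_clone_power(config: SimConfig | None = None, *,
                        n_runs: int = 100, n_shuffles: int = 1000,
                        ci: float = 0.98, bins: RingBins | None = None,
                        seed: int = 0) -> PowerStudy:
    """Ring-test calls over repeated clonally-labeled groups (defaults)."""
    base = config if config is not None else SimConfig()
    bins = bins if bins is not None else make_ring_bins()
    calls = np.empty((n_runs, bins.n), dtype=object)
    for g in range(n_runs):
        cfg = replace(base, seed=_derive_seed(seed, 3, g))
        cells, _, metas = simulate_group(cfg, group=f"g{g}", scramble=False)
        obs = group_profile(cells, metas, bins, subset="all", ci=ci)
        null = mc_null_envelope(cells, metas, bins, n_shuffles=n_shuffles,
                                ci=ci, seed=_derive_seed(seed, 4, g),
                                subset="all")
        calls[g] = clonality_decision(obs, null).calls
    return PowerStudy(n_runs=n_runs, calls=calls)


def lineage_size_pairs(cells: pd.DataFrame,
                       plaques: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth pairs from generator founders, one per plaque.

    x is the plaque volume and y the full lineage cell count (zero when the
    plaque seeded no cells) — the generator's linear link whose slope the
    regression should recover.  Conditioning on observed (labeled, non-empty)
    clones would zero-truncate the Poisson sizes and bias the slope, so the
    founder column, which exists for exactly this purpose, is used instead.
    """
    counts = cells.groupby(["image_id", "founder_id"]).size()
    rows = []
    for p in plaques.itertuples():
        key = (p.image_id, f"p:{p.plaque_id}")
        n = int(counts.loc[key]) if key in counts.index else 0
        rows.append({"image_id": p.image_id, "plaque_id": p.plaque_id,
                     "volume_um3": float(p.volume_um3), "clone_size": n})
    return pd.DataFrame(rows, columns=["image_id", "plaque_id",
                                       "volume_um3", "clone_size"])


def slope_recovery(config: SimConfig | None = None, *, n_images: int = 200,
                   seed: int = 0) -> tuple[RegressionSummary, float]:
    """Fit lineage size on plaque volume over ``n_images`` synthetic images.

    Returns the regression summary and the generator's true slope.
    """
    base = config if config is not None else SimConfig()
    cfg = replace(base, n_replicates_per_group=1,
                  n_images_per_replicate=n_images,
                  seed=_derive_seed(seed, 5))
    cells, plaques, _ = simulate_group(cfg, group="recovery", scramble=False)
    pairs = lineage_size_pairs(cells, plaques)
    fit = regress_clone_vs_plaque(pairs, stratum="all")
    return fit, cfg.clone_cells_per_um3_plaque
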