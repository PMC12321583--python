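"""Synthetic tissue generator.

Produces cell and plaque centroid tables with the statistical structure the
downstream analyses assume: homogeneous background microglia, plaque-centred
clonal clusters whose expected size scales with plaque volume, and sparse
stochastic four-color Confetti labeling inherited clonally from founder
lineages.  A ``scramble`` mode assigns colors to cells independently and is
the null generator for calibrating the ring clonality test.

Randomness: one base seed (``SimConfig.seed``) with deterministic per-image
substreams ``(seed, stream, image_index)``, so changing the number of images
never reshuffles earlier images.  Founder identities are kept in the output
(``founder_id``) purely to let tests score clone recovery; real data will not
carry this column and no downstream operation reads it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COLOR_NONE, CONFETTI_COLORS, SimConfig, UM3_PER_MM3
from .tables import ImageMeta

# substream tags so plaques / cell positions / labels are independent
_PLAQUE_STREAM, _CELL_STREAM, _LABEL_STREAM = 0, 1, 2


def image_keys(config: SimConfig, group: str = "sim"):
    """Yield (replicate_id, image_id, global_image_index) for one group."""
    k = 0
    for r in range(config.n_replicates_per_group):
        rep = f"{group}-r{r}"
        for i in range(config.n_images_per_replicate):
            yield rep, f"{rep}-i{i}", k
            k += 1


def image_metas(config: SimConfig, group: str = "sim") -> dict[str, ImageMeta]:
    lx, ly, lz = config.image_extent
    return {img: ImageMeta(img, lx, ly, lz)
            for _, img, _ in image_keys(config, group)}


def generate_plaques(config: SimConfig, group: str = "sim") -> pd.DataFrame:
    """Poisson-distributed plaques per image, uniform centroids, lognormal volumes."""
    lam = config.plaque_intensity * config.image_volume_mm3
    ext = np.array(config.image_extent)
    rows = []
    for rep, img, k in image_keys(config, group):
        rng = np.random.default_rng([config.seed, _PLAQUE_STREAM, k])
        n = rng.poisson(lam)
        xyz = rng.uniform(0.0, 1.0, size=(n, 3)) * ext
        vols = rng.lognormal(config.plaque_volume_log_mean,
                             config.plaque_volume_log_sd, size=n)
        for j in range(n):
            rows.append((group, rep, img, f"p{j}",
                         xyz[j, 0], xyz[j, 1], xyz[j, 2], vols[j]))
    return pd.DataFrame(rows, columns=[
        "group", "replicate_id", "image_id", "plaque_id",
        "x_um", "y_um", "z_um", "volume_um3"])


def _clone_offsets(rng: np.random.Generator, n: int, radius: float):
    """Isotropic displacement from the plaque surface, distance <= radius.

    Radial distance is |N(0, radius/2)| truncated at ``radius`` (resampled,
    not clamped), direction uniform on the sphere.  Returns (d, u).
    """
    d = np.abs(rng.normal(0.0, radius / 2.0, size=n))
    while True:
        bad = d > radius
        if not bad.any():
            break
        d[bad] = np.abs(rng.normal(0.0, radius / 2.0, size=int(bad.sum())))
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return d, u


def generate_cells(config: SimConfig, plaques: pd.DataFrame,
                   group: str = "sim") -> pd.DataFrame:
    """Background Poisson cells plus one clonal cluster per plaque.

    Clone cells sit at ``centroid + (r_p + d) * u`` where ``r_p`` is the
    equivalent-sphere radius of the plaque and ``d <= clone_radius``; all
    positions receive Gaussian jitter (``noise_sd``) and are clipped into the
    image box.  Every cell records its founder: background cells are their
    own founders (``b<j>``), clone cells inherit the plaque founder
    (``p:<plaque_id>``).
    """
    ext = np.array(config.image_extent)
    lam_bg = config.background_cell_intensity * config.image_volume_mm3
    by_img = dict(tuple(plaques.groupby("image_id", sort=False))) if len(plaques) else {}
    frames = []
    for rep, img, k in image_keys(config, group):
        rng = np.random.default_rng([config.seed, _CELL_STREAM, k])
        n_bg = rng.poisson(lam_bg)
        pos = [rng.uniform(0.0, 1.0, size=(n_bg, 3)) * ext]
        founders = [np.array([f"b{j}" for j in range(n_bg)], dtype=object)]
        pl = by_img.get(img)
        if pl is not None:
            for p in pl.itertuples():
                n_c = rng.poisson(config.clone_cells_per_um3_plaque * p.volume_um3)
                if n_c == 0:
                    continue
                r_p = (3.0 * p.volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
                centre = np.array([p.x_um, p.y_um, p.z_um])
                d, u = _clone_offsets(rng, n_c, config.clone_radius)
                pos.append(centre + (r_p + d)[:, None] * u)
                founders.append(np.full(n_c, f"p:{p.plaque_id}", dtype=object))
        xyz = np.vstack(pos)
        if config.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, config.noise_sd, size=xyz.shape)
        xyz = np.clip(xyz, 0.0, ext)  # projection into the box, non-expansive
        n = len(xyz)
        frames.append(pd.DataFrame({
            "group": group, "replicate_id": rep, "image_id": img,
            "cell_id": [f"c{j}" for j in range(n)],
            "x_um": xyz[:, 0], "y_um": xyz[:, 1], "z_um": xyz[:, 2],
            "confetti_color": COLOR_NONE, "pu1": True,
            "founder_id": np.concatenate(founders) if n else np.array([], dtype=object),
        }))
    return pd.concat(frames, ignore_index=True)


def assign_confetti(cells: pd.DataFrame, config: SimConfig,
                    scramble: bool = False) -> pd.DataFrame:
    """Label lineages (or, with ``scramble``, individual cells) with Confetti colors.

    Clonal mode: each founder lineage is independently Confetti+ with
    probability ``label_prob`` and, if labeled, draws one color from
    ``color_weights``; all members inherit it.  Scramble mode ignores
    founders and labels each cell independently — the per-cell marginal
    distribution is identical, but colors carry no spatial information.
    """
    cells = cells.copy()
    colors = np.array(CONFETTI_COLORS, dtype=object)
    out = np.full(len(cells), COLOR_NONE, dtype=object)
    img_of = {img: k for _, img, k in image_keys(
        config, cells["group"].iloc[0] if len(cells) else "sim")}
    for img, idx in cells.groupby("image_id", sort=False).indices.items():
        rng = np.random.default_rng([config.seed, _LABEL_STREAM, img_of.get(img, 0)])
        if scramble:
            n = len(idx)
            labeled = rng.random(n) < config.label_prob
            draw = colors[rng.choice(len(colors), size=n, p=config.color_weights)]
            out[idx] = np.where(labeled, draw, COLOR_NONE)
        else:
            founders = np.sort(cells["founder_id"].to_numpy()[idx].astype(str))
            founders = np.unique(founders)
            labeled = rng.random(len(founders)) < config.label_prob
            draw = colors[rng.choice(len(colors), size=len(founders),
                                     p=config.color_weights)]
            lut = {f: (draw[j] if labeled[j] else COLOR_NONE)
                   for j, f in enumerate(founders)}
            out[idx] = [lut[f] for f in cells["founder_id"].to_numpy()[idx].astype(str)]
    cells["confetti_color"] = out
    return cells


def simulate_group(config: SimConfig, group: str = "sim", scramble: bool = False):
    """Generate one experimental group: (cells, plaques, image metadata)."""
    plaques = generate_plaques(config, group)
    cells = generate_cells(config, plaques, group)
    cells = assign_confetti(cells, config, scramble=scramble)
    return cells, plaques, image_metas(config, group)
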