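"""Configuration for the synthetic Confetti-tissue generator.

The generator emulates confocal image stacks of amyloid-bearing cortex that
have been reduced to centroid tables: a homogeneous Poisson background of
Pu.1+ microglia, plaques scattered uniformly with lognormal volumes, and a
clonal cluster of plaque-associated cells seeded at each plaque whose
expected size grows linearly with plaque volume.  Confetti labeling is
applied per founder lineage (clonal mode) or per cell (scramble mode, the
null generator).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

#: The four Confetti recombination outcomes, in canonical order.
CONFETTI_COLORS = ("nGFP", "YFP", "RFP", "mCFP")

#: Color token for unlabeled (Confetti-negative) cells.
COLOR_NONE = "none"

UM3_PER_MM3 = 1.0e9


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experimental group.

    Units: lengths in micrometres, intensities per cubic millimetre.
    Defaults describe an aged amyloid-model frontal cortex: roughly
    15,000 Pu.1+ microglia and 800 plaques per mm^3, plaque volumes
    lognormal with median ~330 um^3, and plaque-associated clones of
    ~0.01 cells per um^3 of plaque spread within 25 um of the plaque
    surface.  Labeling is sparse (10% of founder lineages).
    """

    image_extent: tuple[float, float, float] = (600.0, 600.0, 100.0)
    n_images_per_replicate: int = 3
    n_replicates_per_group: int = 8
    plaque_intensity: float = 800.0  # plaques per mm^3
    plaque_volume_log_mean: float = 5.8  # ln(um^3)
    plaque_volume_log_sd: float = 0.5
    background_cell_intensity: float = 15000.0  # cells per mm^3
    clone_cells_per_um3_plaque: float = 0.01  # expected clone cells per um^3 plaque
    clone_radius: float = 25.0  # um, spread of a clone around its plaque surface
    label_prob: float = 0.1  # probability a founder lineage is Confetti+
    color_weights: tuple[float, float, float, float] = (0.15, 0.35, 0.35, 0.15)
    noise_sd: float = 1.0  # um positional jitter
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_extent", tuple(float(v) for v in self.image_extent))
        object.__setattr__(self, "color_weights", tuple(float(v) for v in self.color_weights))
        ext = self.image_extent
        if len(ext) != 3 or any(v <= 0 for v in ext):
            raise ConfigError(f"image_extent must be 3 positive lengths, got {ext!r}")
        if self.n_images_per_replicate < 1 or self.n_replicates_per_group < 1:
            raise ConfigError("image and replicate counts must be >= 1")
        for name in ("plaque_intensity", "background_cell_intensity",
                     "clone_cells_per_um3_plaque", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.plaque_volume_log_sd < 0:
            raise ConfigError("plaque_volume_log_sd must be >= 0")
        if self.clone_radius <= 0:
            raise ConfigError("clone_radius must be > 0")
        if not 0.0 <= self.label_prob <= 1.0:
            raise ConfigError("label_prob must lie in [0, 1]")
        w = self.color_weights
        if len(w) != len(CONFETTI_COLORS) or any(v < 0 for v in w):
            raise ConfigError("color_weights must be 4 non-negative probabilities")
        if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
            raise ConfigError(f"color_weights must sum to 1 (got {sum(w)!r})")
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    @property
    def image_volume_um3(self) -> float:
        lx, ly, lz = self.image_extent
        return lx * ly * lz

    @property
    def image_volume_mm3(self) -> float:
        return self.image_volume_um3 / UM3_PER_MM3

    @property
    def n_images_per_group(self) -> int:
        return self.n_images_per_replicate * self.n_replicates_per_group

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["image_extent"] = list(self.image_extent)
        d["color_weights"] = list(self.color_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a configuration from a JSON or YAML file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)
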