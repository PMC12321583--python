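import numpy as np
import pandas as pd
import pytest

from pamclone import ImageMeta, SimConfig


@pytest.fixture
def tiny_config():
    """Small, fast group: 2 replicates x 2 images of 300x300x60 um."""
    return SimConfig(image_extent=(300.0, 300.0, 60.0),
                     n_images_per_replicate=2, n_replicates_per_group=2,
                     seed=11)


@pytest.fixture
def meta100():
    return ImageMeta("img0", 100.0, 100.0, 50.0)


@pytest.fixture
def make_cells():
    """Build a hand-specified single-image cell table.

    ``rows`` is a list of (x, y, z, color) or (x, y, z, color, extra-dict).
    """
    def _make(rows, group="g", rep="r0", image="img0"):
        recs = []
        for i, row in enumerate(rows):
            x, y, z, color = row[:4]
            rec = {"group": group, "replicate_id": rep, "image_id": image,
                   "cell_id": f"c{i}", "x_um": float(x), "y_um": float(y),
                   "z_um": float(z), "confetti_color": color, "pu1": True}
            if len(row) > 4:
                rec.update(row[4])
            recs.append(rec)
        cols = ["group", "replicate_id", "image_id", "cell_id", "x_um",
                "y_um", "z_um", "confetti_color", "pu1"]
        return pd.DataFrame(recs, columns=None if recs else cols)
    return _make


@pytest.fixture
def make_plaques():
    def _make(rows, group="g", rep="r0", image="img0"):
        recs = []
        for i, (x, y, z, vol) in enumerate(rows):
            recs.append({"group": group, "replicate_id": rep,
                         "image_id": image, "plaque_id": f"p{i}",
                         "x_um": float(x), "y_um": float(y), "z_um": float(z),
                         "volume_um3": float(vol)})
        cols = ["group", "replicate_id", "image_id", "plaque_id", "x_um",
                "y_um", "z_um", "volume_um3"]
        return pd.DataFrame(recs, columns=None if recs else cols)
    return _make
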