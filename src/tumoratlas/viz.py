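"""Basic overlay export for statistical maps (single-slice PNG)."""

from __future__ import annotations

import numpy as np

from .image_io import MapLabel, VoxelMap


def save_overlay(
    vmap: VoxelMap,
    path,
    background: VoxelMap | None = None,
    axis: int = 2,
    index: int | None = None,
    cmap: str = "RdYlGn",
) -> None:
    """Save one axial/coronal/sagittal slice of a map as a PNG.

    ``background`` (typically the cohort COUNT map) is drawn in grayscale
    under the map; NaN voxels of ``vmap`` are transparent, which together
    with significance masking reproduces the usual "significant log-OR on
    tumor distribution" overlay.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if index is None:
        index = vmap.grid.shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = index
    fig, ax = plt.subplots(figsize=(4, 4))
    if background is not None:
        ax.imshow(np.asarray(background.values, float)[tuple(sl)].T, cmap="gray", origin="lower")
    data = np.asarray(vmap.values, float)[tuple(sl)].T
    if vmap.label in (MapLabel.SIGNIFICANCE, MapLabel.COUNT):
        data = np.where(data == 0, np.nan, data)
    im = ax.imshow(data, cmap=cmap, origin="lower", alpha=0.9)
    fig.colorbar(im, ax=ax, shrink=0.8, label=vmap.label.value)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
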