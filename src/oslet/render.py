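"""Slice rendering of dose and LET_D maps with the standard display cutoffs
(doses below 0.2 Gy(RBE) and LET_D below 0.5 keV/um are transparent).
Cutoffs are presentation-only; scored maps are never thresholded."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phantom import VoxelPhantom
from .scoring import CombinedMaps

DOSE_RBE_CUTOFF_GY = 0.2
LET_CUTOFF_KEV_UM = 0.5


def render_delivery(maps: CombinedMaps, phantom: VoxelPhantom, path: str | Path,
                    rbe_factor: float = 1.1) -> None:
    lay = phantom.osld_layout
    k = lay.slice_index if lay is not None else phantom.shape[2] // 2
    i_mid = phantom.shape[0] // 2
    rbe_dose = np.nan_to_num(maps.dose) * rbe_factor
    let = np.nan_to_num(maps.let_d)
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [
        (rbe_dose[:, :, k].T, phantom.density[:, :, k].T, DOSE_RBE_CUTOFF_GY, "dose Gy(RBE), axial"),
        (rbe_dose[i_mid, :, :].T, phantom.density[i_mid, :, :].T, DOSE_RBE_CUTOFF_GY, "dose Gy(RBE), sagittal"),
        (let[:, :, k].T, phantom.density[:, :, k].T, LET_CUTOFF_KEV_UM, "LET_D keV/um, axial"),
        (let[i_mid, :, :].T, phantom.density[i_mid, :, :].T, LET_CUTOFF_KEV_UM, "LET_D keV/um, sagittal"),
    ]
    for ax, (img, bg, cutoff, title) in zip(axes.ravel(), panels):
        ax.imshow(bg, cmap="gray", origin="lower")
        masked = np.ma.masked_less(img, cutoff)
        im = ax.imshow(masked, cmap="jet", origin="lower", alpha=0.7)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(title, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
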