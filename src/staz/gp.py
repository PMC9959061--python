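"""Generalized polarization (GP) membrane-order mapping.

The environment-sensitive probe di-4-ANEPPDHQ red-shifts its emission in
disordered membranes, so the ratiometric quantity

    GP = (I_ordered - I_disordered) / (I_ordered + I_disordered)

computed per pixel from the ordered (500–580 nm) and disordered
(620–750 nm) emission images lies in [-1, 1] and increases with membrane
lipid order. Pixels outside the liver mask, or whose summed intensity
falls below a floor (background/dim pixels where the ratio is dominated
by noise), are left undefined.

Per-larva GP is the unweighted mean of defined pixels; to absorb
batch-to-batch staining variability, results are reported as ΔGP — the
larva's mean GP minus the mean GP of control (DMSO) larvae of the same
batch/experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    EmptyGPError,
    MissingControlError,
    ShapeMismatchError,
)
from .images import ChannelImage, LiverMask


@dataclass(frozen=True)
class GPMap:
    """Per-pixel GP values; ``gp`` is NaN where undefined."""

    gp: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_defined(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class LarvaGP:
    larva_id: str
    batch_id: str
    treatment: str
    mean_gp: float
    n_defined_px: int = 0


@dataclass(frozen=True)
class GPResult(LarvaGP):
    delta_gp: float = float("nan")


def auto_intensity_floor(
    ordered: ChannelImage, disordered: ChannelImage, mask: LiverMask
) -> float:
    """Default floor: 2% of the 99th percentile of the in-mask summed
    intensity. Masks dim/background pixels whose GP is noise-dominated;
    scale-equivariant, so GP maps are invariant to overall gain."""
    s = (ordered.pixels + disordered.pixels)[mask.mask]
    return 0.02 * float(np.percentile(s, 99))


def gp_map(
    ordered: ChannelImage,
    disordered: ChannelImage,
    mask: LiverMask,
    intensity_floor: float | None = None,
) -> GPMap:
    """Per-pixel GP within the liver mask.

    ``intensity_floor`` of ``None`` selects the automatic floor; pass 0 to
    keep every in-mask pixel with positive summed intensity.
    """
    if ordered.role != "gp_ordered" or disordered.role != "gp_disordered":
        raise ConfigurationError(
            f"expected gp_ordered/gp_disordered pair, got "
            f"{ordered.role!r}/{disordered.role!r}"
        )
    if ordered.shape != disordered.shape or ordered.shape != mask.shape:
        raise ShapeMismatchError("channel/mask dimensions differ")
    if intensity_floor is None:
        intensity_floor = auto_intensity_floor(ordered, disordered, mask)
    if intensity_floor < 0:
        raise ConfigurationError("intensity_floor must be >= 0")
    total = ordered.pixels + disordered.pixels
    valid = mask.mask & (total >= intensity_floor) & (total > 0)
    if not valid.any():
        raise EmptyGPError("no defined GP pixels (all below floor or outside mask)")
    gp = np.full(ordered.shape, np.nan)
    gp[valid] = (ordered.pixels[valid] - disordered.pixels[valid]) / total[valid]
    return GPMap(gp=gp, valid_mask=valid)


def larva_gp(gpmap: GPMap) -> float:
    """Unweighted mean GP over defined pixels."""
    if gpmap.n_defined == 0:
        raise EmptyGPError("GP map has no defined pixels")
    return float(gpmap.gp[gpmap.valid_mask].mean())


def delta_gp(
    results: Sequence[LarvaGP], control_label: str = "DMSO"
) -> list[GPResult]:
    """Anchor per-larva mean GP to the batch control mean.

    Every batch must contain at least one control larva; control larvae
    have mean ΔGP of zero per batch by construction.
    """
    batches = sorted({r.batch_id for r in results})
    control_mean: dict[str, float] = {}
    for b in batches:
        ctrl = [r.mean_gp for r in results if r.batch_id == b and r.treatment == control_label]
        if not ctrl:
            raise MissingControlError(
                f"no {control_label!r} control larvae in batch {b}"
            )
        control_mean[b] = float(np.mean(ctrl))
    return [
        GPResult(
            larva_id=r.larva_id,
            batch_id=r.batch_id,
            treatment=r.treatment,
            mean_gp=r.mean_gp,
            n_defined_px=r.n_defined_px,
            delta_gp=r.mean_gp - control_mean[r.batch_id],
        )
        for r in results
    ]


def save_gp_image(gpmap: GPMap, path) -> None:
    """Write a pseudocolor rendering of a GP map (undefined pixels dark)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    im = ax.imshow(gpmap.gp, cmap="RdYlBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="GP")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
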