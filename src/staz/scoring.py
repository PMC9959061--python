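"""Composite steatosis score: corrected fluorescence ratio + droplet terms.

Per slice, three parameters describe hepatic lipid accumulation:

* ``Ratio`` — total green (Nile red) over total blue (normalization)
  fluorescence within the liver, expressed relative to the mean ratio of
  DMSO control larvae: ``(raw - mean_DMSO) / mean_DMSO``;
* ``LD_dens`` — lipid droplets per liver pixel;
* ``LD_area`` — fraction of the liver covered by droplets.

The slice score is the published linear combination

    score = 400 * Ratio + 10000 * LD_dens + 100 * LD_area

and a larva's score is the arithmetic mean of its (up to three) slice
scores. The coefficients were set empirically by the assay's authors to
weight the three parameters homogeneously; they are configurable, but the
defaults are the published values. Scores are comparable only across data
quantified with one consistent segmentation configuration and density
unit (per pixel here).

Control anchoring is per batch by default: each batch's control larvae
define the reference ratio for that batch, mirroring the per-experiment
anchoring used for membrane-order ΔGP. A ``global`` scope (one control
mean across all batches) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import math

import numpy as np
import pandas as pd

from .droplets import SegmentationConfig, quantify, segment_droplets
from .errors import (
    DegenerateControlError,
    DegenerateNormalizationError,
    MissingControlError,
    MissingDataError,
    ShapeMismatchError,
)
from .images import ChannelImage, LarvaRecord, LiverMask


@dataclass(frozen=True)
class ScoreCoefficients:
    """Weights of the three score terms (published defaults)."""

    w_ratio: float = 400.0
    w_dens: float = 10000.0
    w_area: float = 100.0

    def __post_init__(self) -> None:
        for v in (self.w_ratio, self.w_dens, self.w_area):
            if not math.isfinite(v):
                raise ValueError("score coefficients must be finite")


@dataclass(frozen=True)
class SliceScore:
    raw_ratio: float
    corrected_ratio: float
    ld_dens: float
    ld_area: float
    score: float


@dataclass(frozen=True)
class LarvaScore:
    larva_id: str
    batch_id: str
    treatment: str
    concentration: str | None
    slice_scores: tuple[SliceScore, ...]
    score: float


def raw_ratio(green: ChannelImage, blue: ChannelImage, mask: LiverMask) -> float:
    """Total green over total blue fluorescence within the liver mask."""
    if green.shape != blue.shape or green.shape != mask.shape:
        raise ShapeMismatchError("channel/mask dimensions differ")
    g = float(green.pixels[mask.mask].sum())
    b = float(blue.pixels[mask.mask].sum())
    if b == 0.0:
        raise DegenerateNormalizationError(
            "blue normalization channel sums to zero over the liver"
        )
    return g / b


def corrected_ratio(raw: float, control_mean: float) -> float:
    """Relative deviation of a raw ratio from the control-group mean."""
    if not control_mean > 0:
        raise DegenerateControlError(
            f"control mean ratio must be positive, got {control_mean}"
        )
    return (raw - control_mean) / control_mean


def slice_score(
    corrected: float,
    ld_dens: float,
    ld_area: float,
    coeffs: ScoreCoefficients | None = None,
) -> float:
    """Weighted combination of the three slice parameters."""
    if coeffs is None:
        coeffs = ScoreCoefficients()
    return (
        coeffs.w_ratio * corrected + coeffs.w_dens * ld_dens + coeffs.w_area * ld_area
    )


def larva_score(slice_scores: Sequence[float]) -> float:
    """Arithmetic mean of a larva's slice scores (warns if fewer than 3)."""
    if len(slice_scores) == 0:
        raise MissingDataError("larva has no slice scores")
    if len(slice_scores) < 3:
        warnings.warn(
            f"larva scored from {len(slice_scores)} slice(s), expected 3",
            stacklevel=2,
        )
    return float(np.mean(slice_scores))


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SliceMeasurement:
    """Raw per-slice quantities, before control anchoring."""

    larva_id: str
    batch_id: str
    treatment: str
    concentration: str | None
    slice_index: int
    raw_ratio: float
    ld_dens: float
    ld_area: float


def measure_records(
    records: Iterable[LarvaRecord], seg_cfg: SegmentationConfig | None = None
) -> list[SliceMeasurement]:
    """Quantify every slice of every larva (ratio + droplet statistics)."""
    out = []
    for rec in records:
        for sl in rec.slices:
            green = sl.channel("lipid_green")
            blue = sl.channel("norm_blue")
            droplets = segment_droplets(green, sl.mask, seg_cfg)
            q = quantify(droplets, sl.mask)
            out.append(
                SliceMeasurement(
                    larva_id=rec.larva_id,
                    batch_id=rec.batch_id,
                    treatment=rec.treatment,
                    concentration=rec.concentration,
                    slice_index=sl.slice_index,
                    raw_ratio=raw_ratio(green, blue, sl.mask),
                    ld_dens=q.ld_dens,
                    ld_area=q.ld_area,
                )
            )
    return out


def score_cohort(
    measurements: Sequence[SliceMeasurement],
    control_label: str = "DMSO",
    scope: Literal["per_batch", "global"] = "per_batch",
    coeffs: ScoreCoefficients | None = None,
) -> list[LarvaScore]:
    """Anchor ratios to the control group and assemble larva scores.

    The control mean is the mean over control larvae of each larva's mean
    raw ratio (every control larva contributes equally regardless of its
    slice count), computed per batch or globally according to ``scope``.
    Control larvae are themselves scored; their corrected ratios average
    zero within each scope unit by construction.
    """
    if coeffs is None:
        coeffs = ScoreCoefficients()
    if not measurements:
        raise MissingDataError("no slice measurements to score")

    df = pd.DataFrame([m.__dict__ for m in measurements])
    unit_of = (lambda b: b) if scope == "per_batch" else (lambda b: "__all__")
    df["unit"] = df["batch_id"].map(unit_of)

    larva_raw = df.groupby(["unit", "larva_id"], sort=False).agg(
        raw=("raw_ratio", "mean"), treatment=("treatment", "first")
    )
    control_mean: dict[str, float] = {}
    for unit in df["unit"].unique():
        sub = larva_raw.loc[unit]
        ctrl = sub[sub["treatment"] == control_label]
        if ctrl.empty:
            name = unit if scope == "per_batch" else "the cohort"
            raise MissingControlError(
                f"no {control_label!r} control larvae in batch {name}"
            )
        control_mean[unit] = float(ctrl["raw"].mean())

    scores: list[LarvaScore] = []
    for (unit, larva_id), grp in df.groupby(["unit", "larva_id"], sort=True):
        m = control_mean[unit]
        slice_scores = tuple(
            SliceScore(
                raw_ratio=row.raw_ratio,
                corrected_ratio=corrected_ratio(row.raw_ratio, m),
                ld_dens=row.ld_dens,
                ld_area=row.ld_area,
                score=slice_score(
                    corrected_ratio(row.raw_ratio, m), row.ld_dens, row.ld_area, coeffs
                ),
            )
            for row in grp.sort_values("slice_index").itertuples()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short-slice warning handled upstream
            total = larva_score([s.score for s in slice_scores])
        first = grp.iloc[0]
        scores.append(
            LarvaScore(
                larva_id=str(larva_id),
                batch_id=str(first["batch_id"]),
                treatment=str(first["treatment"]),
                concentration=first["concentration"],
                slice_scores=slice_scores,
                score=total,
            )
        )
    return scores


def scores_table(scores: Sequence[LarvaScore]) -> pd.DataFrame:
    """Flatten larva scores into the output table schema."""
    rows = []
    for s in scores:
        rows.append(
            {
                "larva_id": s.larva_id,
                "batch_id": s.batch_id,
                "treatment": s.treatment,
                "concentration": s.concentration,
                "n_slices": len(s.slice_scores),
                "raw_ratio_mean": float(np.mean([x.raw_ratio for x in s.slice_scores])),
                "corrected_ratio_mean": float(
                    np.mean([x.corrected_ratio for x in s.slice_scores])
                ),
                "ld_dens_mean": float(np.mean([x.ld_dens for x in s.slice_scores])),
                "ld_area_mean": float(np.mean([x.ld_area for x in s.slice_scores])),
                "score": s.score,
            }
        )
    return pd.DataFrame(rows)
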