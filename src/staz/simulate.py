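"""Seeded synthetic-microscopy generators with exact ground truth.

The generator emulates the structure of the assay's images rather than
larval anatomy: an elliptical "liver" emits the blue normalization signal
(weak, barely above background, in ``wildtype`` mode — mimicking tissue
autofluorescence — or strong and liver-restricted in ``transgenic`` mode,
mimicking a liver-specific blue reporter), bright circular lipid droplets
of controllable density and size lie inside the liver on a diffuse green
background, and the optics are modelled as a Gaussian PSF blur followed
by Poisson shot noise and additive Gaussian read noise.

Droplet placement is Poisson in number and uniform in position, with
non-overlap enforced by rejection sampling so that the droplet-count
ground truth is unambiguous. All randomness flows from a single seed
through spawned child streams (one per larva, one per slice), so a
larva's images do not depend on cohort composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .errors import ConfigurationError, PackingError
from .images import ChannelImage, LarvaRecord, LiverMask, SliceRecord


@dataclass(frozen=True)
class LarvaSimParams:
    """Generative parameters for one larva's three optical slices.

    Intensity levels are in arbitrary camera units; the droplet rate is
    the expected number of droplets per liver pixel (so the expected
    count is rate x liver area). Defaults depict a transgenic-mode
    acquisition at modest magnification: a ~2100 px liver, ~2.5 px
    droplet radius, SNR well above 10.
    """

    image_size: tuple[int, int] = (96, 96)
    liver_center: tuple[float, float] = (48.0, 48.0)
    liver_semiaxes: tuple[float, float] = (30.0, 22.0)
    liver_rotation_deg: float = 0.0
    mode: str = "transgenic"
    blue_liver_level: float = 120.0
    blue_background_level: float = 10.0
    green_background_level: float = 20.0
    droplet_rate: float = 2e-3
    droplet_radius_px: tuple[float, float] = (2.5, 0.4)
    droplet_radius_min: float = 1.0
    droplet_intensity: float = 150.0
    psf_sigma_px: float = 1.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    n_slices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "blue_liver_level",
            "blue_background_level",
            "green_background_level",
            "droplet_rate",
            "droplet_intensity",
            "psf_sigma_px",
            "gaussian_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mode not in ("wildtype", "transgenic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "transgenic" and not (
            self.blue_liver_level > self.blue_background_level
        ):
            raise ConfigurationError(
                "transgenic mode requires blue_liver_level > blue_background_level"
            )
        if not 1 <= self.n_slices <= 3:
            raise ConfigurationError("n_slices must be in 1..3")
        cy, cx = self.liver_center
        a, b = self.liver_semiaxes
        nr, nc = self.image_size
        r = max(a, b)
        if cy - r < 0 or cx - r < 0 or cy + r > nr or cx + r > nc:
            raise ConfigurationError("liver ellipse must lie fully inside the image")


@dataclass(frozen=True)
class SliceTruth:
    centers: np.ndarray  # (n, 2) of (row, col)
    radii: np.ndarray  # (n,)
    n_droplets: int
    droplet_area_px: int
    ld_dens: float
    ld_area: float
    raw_ratio_expected: float


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative truth for one simulated larva."""

    liver_mask: np.ndarray
    liver_area_px: int
    slices: tuple[SliceTruth, ...]

    @property
    def ld_dens(self) -> float:
        return float(np.mean([s.ld_dens for s in self.slices]))

    @property
    def ld_area(self) -> float:
        return float(np.mean([s.ld_area for s in self.slices]))

    @property
    def raw_ratio_expected(self) -> float:
        return float(np.mean([s.raw_ratio_expected for s in self.slices]))


def _ellipse_mask(params: LarvaSimParams) -> np.ndarray:
    nr, nc = params.image_size
    rr, cc = np.meshgrid(np.arange(nr) + 0.5, np.arange(nc) + 0.5, indexing="ij")
    cy, cx = params.liver_center
    a, b = params.liver_semiaxes
    th = np.deg2rad(params.liver_rotation_deg)
    u = (rr - cy) * np.cos(th) + (cc - cx) * np.sin(th)
    v = -(rr - cy) * np.sin(th) + (cc - cx) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_droplets(
    rng: np.random.Generator, liver: np.ndarray, params: LarvaSimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping droplet centers/radii inside the liver (rejection)."""
    area = int(liver.sum())
    n = int(rng.poisson(params.droplet_rate * area))
    liver_rc = np.argwhere(liver)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    mu, sd = params.droplet_radius_px
    nr, nc = liver.shape
    for _ in range(n):
        for attempt in range(1000):
            r = max(params.droplet_radius_min, rng.normal(mu, sd))
            pos = liver_rc[rng.integers(len(liver_rc))] + rng.random(2)
            # disk fully inside liver: probe its bounding box pixels
            lo = np.floor(pos - r).astype(int)
            hi = np.ceil(pos + r).astype(int)
            if lo[0] < 0 or lo[1] < 0 or hi[0] >= nr or hi[1] >= nc:
                continue
            yy, xx = np.meshgrid(
                np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij"
            )
            inside = (yy + 0.5 - pos[0]) ** 2 + (xx + 0.5 - pos[1]) ** 2 <= r**2
            if not liver[yy[inside], xx[inside]].all():
                continue
            # separation margin beyond the PSF support keeps distinct
            # droplets resolvable, so the count ground truth is unambiguous
            margin = 1.0 + 2.0 * params.psf_sigma_px
            if any(
                np.hypot(*(pos - c)) < r + rc + margin for c, rc in zip(centers, radii)
            ):
                continue
            centers.append(pos)
            radii.append(r)
            break
        else:
            raise PackingError(
                f"could not place droplet {len(centers) + 1}/{n} without overlap; "
                "lower droplet_rate or enlarge the liver"
            )
    if centers:
        return np.array(centers), np.array(radii)
    return np.empty((0, 2)), np.empty(0)


def _render_disks(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = np.meshgrid(
        np.arange(shape[0]) + 0.5, np.arange(shape[1]) + 0.5, indexing="ij"
    )
    for (py, px), r in zip(centers, radii):
        out |= (rr - py) ** 2 + (cc - px) ** 2 <= r**2
    return out


def _apply_noise(
    rng: np.random.Generator, clean: np.ndarray, params: LarvaSimParams
) -> np.ndarray:
    img = rng.poisson(clean).astype(float) if params.poisson_noise else clean.copy()
    if params.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, params.gaussian_noise_sd, size=clean.shape)
    return np.clip(img, 0.0, None)


def simulate_larva(
    params: LarvaSimParams,
    larva_id: str = "larva",
    batch_id: str = "batch1",
    treatment: str = "DMSO",
    concentration: str | None = None,
) -> tuple[LarvaRecord, GroundTruth]:
    """Render one larva's slices with exact generative ground truth.

    The expected raw fluorescence ratio in the truth table is computed
    from the noise-free blurred channels (Poisson and Gaussian noise are
    mean-preserving, so it is the exact expectation of the channel sums).
    """
    liver = _ellipse_mask(params)
    area = int(liver.sum())
    streams = np.random.default_rng(params.seed).spawn(params.n_slices)
    slices = []
    truths = []
    for i, rng in enumerate(streams, start=1):
        centers, radii = _place_droplets(rng, liver, params)
        disks = _render_disks(params.image_size, centers, radii)
        green_clean = np.full(params.image_size, params.green_background_level)
        green_clean[disks] += params.droplet_intensity
        blue_clean = np.full(params.image_size, params.blue_background_level)
        blue_clean[liver] = params.blue_liver_level
        if params.psf_sigma_px > 0:
            green_clean = ndi.gaussian_filter(green_clean, params.psf_sigma_px)
            blue_clean = ndi.gaussian_filter(blue_clean, params.psf_sigma_px)
        green = _apply_noise(rng, green_clean, params)
        blue = _apply_noise(rng, blue_clean, params)
        slices.append(
            SliceRecord(
                larva_id=larva_id,
                slice_index=i,
                channels=(
                    ChannelImage(green, "lipid_green"),
                    ChannelImage(blue, "norm_blue"),
                ),
                mask=LiverMask(liver),
            )
        )
        droplet_px = int((disks & liver).sum())
        truths.append(
            SliceTruth(
                centers=centers,
                radii=radii,
                n_droplets=len(radii),
                droplet_area_px=droplet_px,
                ld_dens=len(radii) / area,
                ld_area=droplet_px / area,
                raw_ratio_expected=float(
                    green_clean[liver].sum() / blue_clean[liver].sum()
                ),
            )
        )
    record = LarvaRecord(
        larva_id=larva_id,
        batch_id=batch_id,
        treatment=treatment,
        slices=tuple(slices),
        concentration=concentration,
    )
    return record, GroundTruth(liver_mask=liver, liver_area_px=area, slices=tuple(truths))


def simulate_gp_pair(
    true_gp_field: np.ndarray,
    total_intensity: float,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> tuple[ChannelImage, ChannelImage, np.ndarray]:
    """Invert the GP formula into an ordered/disordered channel pair.

    ``I_ord = T (1 + GP) / 2`` and ``I_dis = T (1 - GP) / 2``, optionally
    perturbed by independent multiplicative Gaussian noise of relative
    standard deviation ``noise_sd_frac`` per channel. With no noise,
    recomputing GP from the pair reproduces the input field exactly.
    """
    gp = np.asarray(true_gp_field, dtype=float)
    if np.abs(gp).max() > 1:
        raise ConfigurationError("true GP field must lie in [-1, 1]")
    if not total_intensity > 0:
        raise ConfigurationError("total_intensity must be positive")
    ordered = total_intensity * (1.0 + gp) / 2.0
    disordered = total_intensity * (1.0 - gp) / 2.0
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        ordered = ordered * np.clip(
            1.0 + rng.normal(0.0, noise_sd_frac, gp.shape), 0.0, None
        )
        disordered = disordered * np.clip(
            1.0 + rng.normal(0.0, noise_sd_frac, gp.shape), 0.0, None
        )
    return (
        ChannelImage(ordered, "gp_ordered"),
        ChannelImage(disordered, "gp_disordered"),
        gp,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One treatment arm of a simulated cohort."""

    treatment: str
    n_larvae: int
    overrides: Mapping[str, object] = field(default_factory=dict)
    concentration: str | None = None


def simulate_cohort_records(
    group_specs: Sequence[GroupSpec],
    n_batches: int = 1,
    base_params: LarvaSimParams | None = None,
    seed: int = 0,
    control_label: str = "DMSO",
    batch_intensity_sd: float = 0.0,
) -> tuple[list[LarvaRecord], list[GroundTruth], pd.DataFrame]:
    """Simulate a multi-batch cohort in memory.

    Larvae of each group are dealt round-robin across batches; each batch
    must end up with at least one control larva. A per-batch intensity
    factor ``exp(N(0, batch_intensity_sd))`` scales every fluorescence
    level of that batch's larvae, emulating staining/gain variability —
    ratiometric and per-batch-anchored statistics should shrug it off.
    """
    if base_params is None:
        base_params = LarvaSimParams()
    if not any(g.treatment == control_label for g in group_specs):
        raise ConfigurationError(f"cohort has no {control_label!r} control group")
    if any(g.treatment == control_label and g.n_larvae < n_batches for g in group_specs):
        raise ConfigurationError(
            f"control group needs >= {n_batches} larvae to cover every batch"
        )
    master = np.random.SeedSequence(seed)
    batch_rng = np.random.default_rng(master.spawn(1)[0])
    batch_factor = {
        f"batch{i + 1}": float(np.exp(batch_rng.normal(0.0, batch_intensity_sd)))
        if batch_intensity_sd > 0
        else 1.0
        for i in range(n_batches)
    }
    records: list[LarvaRecord] = []
    truths: list[GroundTruth] = []
    rows = []
    counter = 0
    for spec in group_specs:
        for j in range(spec.n_larvae):
            batch = f"batch{j % n_batches + 1}"
            child_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
            factor = batch_factor[batch]
            params = replace(
                base_params,
                **spec.overrides,
                seed=child_seed,
            )
            params = replace(
                params,
                blue_liver_level=params.blue_liver_level * factor,
                blue_background_level=params.blue_background_level * factor,
                green_background_level=params.green_background_level * factor,
                droplet_intensity=params.droplet_intensity * factor,
            )
            counter += 1
            larva_id = f"L{counter:03d}"
            rec, truth = simulate_larva(
                params,
                larva_id=larva_id,
                batch_id=batch,
                treatment=spec.treatment,
                concentration=spec.concentration,
            )
            records.append(rec)
            truths.append(truth)
            rows.append(
                {
                    "larva_id": larva_id,
                    "batch_id": batch,
                    "treatment": spec.treatment,
                    "concentration": spec.concentration,
                    "droplet_rate": params.droplet_rate,
                    "true_ld_dens": truth.ld_dens,
                    "true_ld_area": truth.ld_area,
                    "true_raw_ratio": truth.raw_ratio_expected,
                    "batch_factor": factor,
                }
            )
    return records, truths, pd.DataFrame(rows)


def simulate_cohort(
    group_specs: Sequence[GroupSpec],
    out_dir: str | Path,
    n_batches: int = 1,
    base_params: LarvaSimParams | None = None,
    seed: int = 0,
    control_label: str = "DMSO",
    batch_intensity_sd: float = 0.0,
) -> Path:
    """Simulate a cohort and write it to disk in the formats the readers
    accept: 2-plane TIFFs (green, blue), TIFF masks, a sample sheet, a
    ground-truth table and a JSON manifest echoing the seed.

    Returns the sample-sheet path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truths, truth_df = simulate_cohort_records(
        group_specs, n_batches, base_params, seed, control_label, batch_intensity_sd
    )
    sheet_rows = []
    for rec in records:
        mask_path = out_dir / f"{rec.larva_id}_mask.tif"
        tifffile.imwrite(
            mask_path, rec.slices[0].mask.mask.astype(np.uint8) * 255
        )
        for sl in rec.slices:
            img_path = out_dir / f"{rec.larva_id}_s{sl.slice_index}.tif"
            stack = np.stack(
                [sl.channel("lipid_green").pixels, sl.channel("norm_blue").pixels]
            ).astype(np.float32)
            tifffile.imwrite(img_path, stack)
            sheet_rows.append(
                {
                    "larva_id": rec.larva_id,
                    "batch_id": rec.batch_id,
                    "treatment": rec.treatment,
                    "concentration": rec.concentration,
                    "slice": sl.slice_index,
                    "image": img_path.name,
                    "mask": mask_path.name,
                }
            )
    sheet_path = out_dir / "samples.csv"
    pd.DataFrame(sheet_rows).to_csv(sheet_path, index=False)
    truth_df.to_csv(out_dir / "truth.csv", index=False, float_format="%.17g")
    manifest = {
        "seed": seed,
        "n_batches": n_batches,
        "control_label": control_label,
        "groups": [
            {"treatment": g.treatment, "n_larvae": g.n_larvae, "overrides": dict(g.overrides)}
            for g in group_specs
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return sheet_path
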