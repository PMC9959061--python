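"""Domain types and I/O for fluorescence images, liver masks and tables.

A larva is imaged as up to three optical slices. Each slice carries a
two-channel image pair — either the lipid (green) channel plus the blue
normalization channel, or the ordered/disordered emission pair used for
generalized-polarization mapping — together with a binary liver mask drawn
by the user (supplied as a mask image or an ImageJ ``.roi`` file).

Conventions
-----------
* Pixel ``(r, c)`` covers the continuous square ``[r, r+1) x [c, c+1)``;
  its center is ``(r + 0.5, c + 0.5)``. ROI polygons are rasterized with a
  pixel-center containment rule.
* In mask images any nonzero pixel counts as liver.
* Channel identity is always given explicitly through a plane -> role
  mapping; it is never guessed from intensities.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ConfigurationError,
    EmptyRoiError,
    FormatError,
    MissingDataError,
    ShapeMismatchError,
)

#: Channel roles understood by the pipeline.
ROLES = frozenset({"lipid_green", "norm_blue", "gp_ordered", "gp_disordered"})

#: Role pairs that may share a slice.
ROLE_PAIRS = (
    frozenset({"lipid_green", "norm_blue"}),
    frozenset({"gp_ordered", "gp_disordered"}),
)


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel of one optical slice.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (stored as float64).
    role
        One of ``lipid_green``, ``norm_blue``, ``gp_ordered``,
        ``gp_disordered``.
    pixel_size_um
        Lateral pixel size in micrometres, if known.
    """

    pixels: np.ndarray
    role: str
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and >= 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LiverMask:
    """Binary liver region for one slice; nonzero means liver."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask) != 0
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        if not m.any():
            raise EmptyRoiError("liver mask contains zero pixels")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SliceRecord:
    """One optical slice of one larva: a channel pair plus its mask."""

    larva_id: str
    slice_index: int
    channels: tuple[ChannelImage, ChannelImage]
    mask: LiverMask

    def __post_init__(self) -> None:
        if not 1 <= self.slice_index <= 3:
            raise ValueError("slice_index must be in 1..3")
        roles = frozenset(ch.role for ch in self.channels)
        if roles not in ROLE_PAIRS:
            raise ValueError(f"inconsistent channel roles {sorted(roles)}")
        shapes = {ch.shape for ch in self.channels} | {self.mask.shape}
        if len(shapes) != 1:
            raise ShapeMismatchError(
                f"channel/mask dimensions differ for larva {self.larva_id}: {shapes}"
            )

    def channel(self, role: str) -> ChannelImage:
        for ch in self.channels:
            if ch.role == role:
                return ch
        raise KeyError(role)


@dataclass(frozen=True)
class LarvaRecord:
    """All slices of one larva plus its experimental grouping."""

    larva_id: str
    batch_id: str
    treatment: str
    slices: tuple[SliceRecord, ...]
    concentration: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.slices) <= 3:
            raise MissingDataError(
                f"larva {self.larva_id}: expected 1..3 slices, got {len(self.slices)}"
            )
        idx = [s.slice_index for s in self.slices]
        if len(set(idx)) != len(idx):
            raise ValueError(f"larva {self.larva_id}: duplicate slice indices {idx}")


# ---------------------------------------------------------------------------
# image / mask readers
# ---------------------------------------------------------------------------


def read_multichannel_tiff(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size_um: float | None = None,
) -> list[ChannelImage]:
    """Read selected planes of a (multi-page) TIFF as ChannelImages.

    ``channel_map`` maps 0-based plane index to a channel role. Integer
    pixel data is converted losslessly to float64.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D planes, got shape {data.shape}")
    out = []
    for plane, role in sorted(channel_map.items()):
        if not 0 <= plane < data.shape[0]:
            raise ConfigurationError(
                f"{path}: plane {plane} out of range (file has {data.shape[0]} planes)"
            )
        out.append(ChannelImage(data[plane], role, pixel_size_um=pixel_size_um))
    return out


def read_mask(path: str | Path, dims: tuple[int, int]) -> LiverMask:
    """Read a liver mask from a mask image or an ImageJ ``.roi`` file.

    Mask images must match ``dims`` exactly; ROI outlines are rasterized
    onto a ``dims`` grid with the pixel-center rule.
    """
    path = Path(path)
    if path.suffix.lower() == ".roi":
        roi = read_imagej_roi(path)
        m = rasterize_roi(roi, dims)
    else:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) mask image: any nonzero channel counts
            arr = arr.max(axis=-1)
        if arr.shape != tuple(dims):
            raise ShapeMismatchError(
                f"mask {path} has shape {arr.shape}, expected {tuple(dims)}"
            )
        m = arr != 0
    if not m.any():
        raise EmptyRoiError(f"mask {path} is empty")
    return LiverMask(m)


# ---------------------------------------------------------------------------
# ImageJ ROI files (binary "Iout" format; rect / oval / polygon / freehand)
# ---------------------------------------------------------------------------

_ROI_TYPES = {0: "polygon", 1: "rect", 2: "oval", 7: "freehand"}


@dataclass(frozen=True)
class ImageJRoi:
    """Decoded single-ROI ``.roi`` outline in continuous image coordinates."""

    kind: str  # rect | oval | polygon
    top: float
    left: float
    bottom: float
    right: float
    vertices: np.ndarray | None = None  # (n, 2) array of (x, y) for polygons


def read_imagej_roi(path: str | Path) -> ImageJRoi:
    data = Path(path).read_bytes()
    if len(data) < 64 or data[:4] != b"Iout":
        raise FormatError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _ROI_TYPES:
        raise FormatError(
            f"{path}: unsupported ROI type {roi_type} "
            "(only rect/oval/polygon/freehand)"
        )
    top, left, bottom, right, n = struct.unpack(">5h", data[8:18])
    kind = _ROI_TYPES[roi_type]
    vertices = None
    if kind in ("polygon", "freehand"):
        need = 64 + 4 * n
        if len(data) < need:
            raise FormatError(f"{path}: truncated ROI coordinate block")
        xs = np.frombuffer(data[64 : 64 + 2 * n], dtype=">i2").astype(float) + left
        ys = np.frombuffer(data[64 + 2 * n : need], dtype=">i2").astype(float) + top
        vertices = np.column_stack([xs, ys])
        kind = "polygon"
    return ImageJRoi(kind, float(top), float(left), float(bottom), float(right), vertices)


def write_imagej_roi(
    path: str | Path,
    kind: str,
    *,
    rect: tuple[int, int, int, int] | None = None,
    vertices: Sequence[tuple[float, float]] | None = None,
) -> None:
    """Write a minimal single-ROI ``.roi`` file (rect, oval or polygon).

    ``rect`` is ``(top, left, bottom, right)`` in continuous coordinates;
    polygon ``vertices`` are (x, y) pairs (rounded to integers, as the
    legacy format stores int16 offsets).
    """
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    if kind in ("rect", "oval"):
        if rect is None:
            raise ValueError("rect required")
        top, left, bottom, right = rect
        header[6] = 1 if kind == "rect" else 2
        struct.pack_into(">4h", header, 8, top, left, bottom, right)
        body = b""
    elif kind == "polygon":
        if vertices is None:
            raise ValueError("vertices required")
        pts = np.asarray(vertices, dtype=float)
        xs = np.rint(pts[:, 0]).astype(int)
        ys = np.rint(pts[:, 1]).astype(int)
        top, left = int(ys.min()), int(xs.min())
        bottom, right = int(ys.max()), int(xs.max())
        header[6] = 0
        struct.pack_into(">5h", header, 8, top, left, bottom, right, len(pts))
        body = b"".join(struct.pack(">h", x - left) for x in xs) + b"".join(
            struct.pack(">h", y - top) for y in ys
        )
    else:
        raise ValueError(f"unsupported kind {kind!r}")
    Path(path).write_bytes(bytes(header) + body)


def rasterize_roi(roi: ImageJRoi, dims: tuple[int, int]) -> np.ndarray:
    """Rasterize an ROI outline onto a boolean grid (pixel centers inside)."""
    nrow, ncol = dims
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    cx = cc + 0.5  # pixel-center x (column axis)
    cy = rr + 0.5  # pixel-center y (row axis)
    if roi.kind == "rect":
        inside = (
            (cx > roi.left) & (cx < roi.right) & (cy > roi.top) & (cy < roi.bottom)
        )
    elif roi.kind == "oval":
        a = (roi.right - roi.left) / 2.0
        b = (roi.bottom - roi.top) / 2.0
        x0 = (roi.left + roi.right) / 2.0
        y0 = (roi.top + roi.bottom) / 2.0
        if a <= 0 or b <= 0:
            raise EmptyRoiError("degenerate oval ROI")
        inside = ((cx - x0) / a) ** 2 + ((cy - y0) / b) ** 2 <= 1.0
    else:  # polygon
        from matplotlib.path import Path as MplPath

        pts = np.column_stack([cx.ravel(), cy.ravel()])
        inside = (
            MplPath(roi.vertices).contains_points(pts).reshape(nrow, ncol)
        )
    return inside


# ---------------------------------------------------------------------------
# tables and sample sheets
# ---------------------------------------------------------------------------


def write_results_table(rows, path: str | Path) -> None:
    """Write scored records to CSV with full float precision.

    ``rows`` may be a DataFrame, a sequence of dicts, or a sequence of
    dataclasses sharing a schema. An empty input produces a header-only
    file when column names can be inferred (DataFrame input).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                records.append(
                    {k: getattr(r, k) for k in r.__dataclass_fields__}
                )
            else:
                records.append(dict(r))
        df = pd.DataFrame(records)
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


REQUIRED_SHEET_COLUMNS = ("larva_id", "batch_id", "treatment", "slice", "image", "mask")


@dataclass
class SampleSheet:
    """Validated sample sheet: one row per optical slice.

    Columns: larva_id, batch_id, treatment, slice (1..3), image (TIFF
    path), mask (mask image or .roi path), optional concentration.
    Relative paths resolve against the sheet's directory.
    """

    rows: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q


def load_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, dtype={"larva_id": str, "batch_id": str, "treatment": str})
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns {missing}")
    sheet = SampleSheet(df, path.parent)
    for col in ("image", "mask"):
        for p in df[col]:
            if not sheet.resolve(str(p)).exists():
                raise FormatError(f"sample sheet references missing file: {p}")
    dup = df.duplicated(subset=["larva_id", "slice"])
    if dup.any():
        raise FormatError("sample sheet has duplicate (larva_id, slice) rows")
    return sheet


def load_cohort(
    sheet: SampleSheet,
    channel_map: Mapping[int, str] | None = None,
    pixel_size_um: float | None = None,
) -> list[LarvaRecord]:
    """Materialize LarvaRecords from a sample sheet.

    By default plane 0 is the green lipid channel and plane 1 the blue
    normalization channel; pass a different ``channel_map`` for GP pairs.
    """
    if channel_map is None:
        channel_map = {0: "lipid_green", 1: "norm_blue"}
    records = []
    for larva_id, grp in sheet.rows.groupby("larva_id", sort=True):
        slices = []
        for _, row in grp.sort_values("slice").iterrows():
            channels = read_multichannel_tiff(
                sheet.resolve(str(row["image"])), channel_map, pixel_size_um
            )
            mask = read_mask(sheet.resolve(str(row["mask"])), channels[0].shape)
            slices.append(
                SliceRecord(
                    larva_id=str(larva_id),
                    slice_index=int(row["slice"]),
                    channels=(channels[0], channels[1]),
                    mask=mask,
                )
            )
        conc = grp.iloc[0].get("concentration")
        records.append(
            LarvaRecord(
                larva_id=str(larva_id),
                batch_id=str(grp.iloc[0]["batch_id"]),
                treatment=str(grp.iloc[0]["treatment"]),
                slices=tuple(slices),
                concentration=None if pd.isna(conc) else str(conc),
            )
        )
    return records
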