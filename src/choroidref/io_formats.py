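"""Reading/writing segmented OCT volumes and extracting layer boundaries.

A volume is an ordered stack of grayscale B-scans (one cross-sectional OCT
image per slice) together with a per-pixel compartment mask that labels each
pixel as background/sclera, vitreous, retina or choroid.  This module owns
the on-disk dataset layout (8-bit grayscale PNG/BMP B-scans, indexed-palette
PNG masks, a metadata JSON per eye), the extraction of the three layer
boundaries used downstream (ILM, inner choroid boundary, outer choroid
boundary) and the manufacturer-style scan-quality inclusion filter.

Coordinate conventions, used consistently across the package:

* row 0 is the top of the image (vitreous side); axial depth increases with
  row index;
* lateral pixel 0 is the left edge of the B-scan;
* indices are 0-based and intervals half-open, so for a column the choroid
  occupies rows ``[choroid_inner, choroid_outer)`` and its pixel thickness
  is ``choroid_outer - choroid_inner``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_VITREOUS",
    "LABEL_RETINA",
    "LABEL_CHOROID",
    "LABEL_NAMES",
    "ChoroidRefError",
    "GeometryOverflowError",
    "DatasetError",
    "BoundaryExtractionError",
    "ScanGeometry",
    "OctVolume",
    "BoundaryCurves",
    "extract_boundaries",
    "quality_filter",
    "read_volume",
    "write_volume",
]

# Compartment labels of the segmentation masks (indexed-PNG palette order).
LABEL_BACKGROUND = 0  # background / sclera
LABEL_VITREOUS = 1
LABEL_RETINA = 2
LABEL_CHOROID = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_VITREOUS: "vitreous",
    LABEL_RETINA: "retina",
    LABEL_CHOROID: "choroid",
}

# Palette loosely echoing the usual overlay colours (vitreous brown, retina
# blue, choroid yellow); background black.
MASK_PALETTE = {
    LABEL_BACKGROUND: (0, 0, 0),
    LABEL_VITREOUS: (139, 90, 43),
    LABEL_RETINA: (65, 105, 225),
    LABEL_CHOROID: (255, 215, 0),
}


class ChoroidRefError(Exception):
    """Base class for all errors raised by this package."""


class GeometryOverflowError(ChoroidRefError):
    """A requested layer profile does not fit inside the scan depth."""


class DatasetError(ChoroidRefError):
    """An on-disk dataset is malformed (missing/misaligned/mislabelled files)."""


class BoundaryExtractionError(ChoroidRefError):
    """A compartment mask violates the one-run-per-column layer model."""


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of an OCT volume scan.

    Defaults follow the 20 degree x 20 degree horizontal line-scan protocol
    used to build the reference database: 25 B-scans spaced 221 um apart,
    512 x 496 pixels each, 5.3 mm scan length, 1.9 mm scan depth.
    """

    width_px: int = 512
    depth_px: int = 496
    n_bscans: int = 25
    width_um: float = 5300.0
    depth_um: float = 1900.0
    bscan_spacing_um: float = 221.0

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            if getattr(self, name.name) <= 0:
                raise ValueError(f"ScanGeometry.{name.name} must be > 0")

    @property
    def lateral_scale(self) -> float:
        """Micrometres per lateral pixel."""
        return self.width_um / self.width_px

    @property
    def axial_scale(self) -> float:
        """Micrometres per axial pixel."""
        return self.depth_um / self.depth_px

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


@dataclass
class OctVolume:
    """An ordered stack of B-scans plus acquisition metadata.

    ``bscans`` has shape ``(n_bscans, depth_px, width_px)``; slice order
    corresponds to physical position with spacing
    ``geometry.bscan_spacing_um``.
    """

    bscans: np.ndarray
    geometry: ScanGeometry
    quality: int | None = None
    eye_id: str = "eye"
    side: str = "OD"
    sex: str = "unknown"
    origin: str = "unknown"

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans)
        if self.bscans.ndim != 3:
            raise ValueError("bscans must be a (n_bscans, depth, width) stack")
        n, d, w = self.bscans.shape
        g = self.geometry
        if (n, d, w) != (g.n_bscans, g.depth_px, g.width_px):
            raise ValueError(
                f"bscan stack shape {(n, d, w)} does not match geometry "
                f"{(g.n_bscans, g.depth_px, g.width_px)}"
            )
        if self.side not in ("OD", "OS"):
            raise ValueError(f"side must be 'OD' or 'OS', got {self.side!r}")

    def metadata(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "side": self.side,
            "sex": self.sex,
            "origin": self.origin,
            "quality": self.quality,
            "geometry": self.geometry.to_dict(),
        }


@dataclass
class BoundaryCurves:
    """Per-B-scan depth profiles of the three measured layer boundaries.

    All arrays have shape ``(n_bscans, width_px)`` and are in axial pixels
    with depth increasing downward.  ``ilm`` is the vitreous/retina border,
    ``choroid_inner`` the retina/choroid border (just above the
    choriocapillaris), ``choroid_outer`` the choroid/background border
    (choroid-sclera junction) under the half-open convention, so that
    ``choroid_outer - choroid_inner`` equals the per-column choroid pixel
    count.
    """

    ilm: np.ndarray
    choroid_inner: np.ndarray
    choroid_outer: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.choroid_inner = np.asarray(self.choroid_inner, dtype=float)
        self.choroid_outer = np.asarray(self.choroid_outer, dtype=float)
        if not (self.ilm.shape == self.choroid_inner.shape == self.choroid_outer.shape):
            raise ValueError("boundary arrays must share one shape")
        if np.any(self.ilm > self.choroid_inner) or np.any(
            self.choroid_inner > self.choroid_outer
        ):
            raise ValueError("boundaries must satisfy ilm <= inner <= outer")


def _first_offending(flags: np.ndarray) -> tuple[int, int]:
    b, x = np.argwhere(flags)[0]
    return int(b), int(x)


def _label_runs(
    masks: np.ndarray, label: int, *, required: bool, context: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First row, last row and pixel count of ``label`` per column.

    Raises :class:`BoundaryExtractionError` if the label forms more than one
    vertical run in any column, or (when ``required``) is absent from one.
    """
    present = masks == label
    count = present.sum(axis=1)
    first = present.argmax(axis=1)
    last = masks.shape[1] - 1 - present[:, ::-1, :].argmax(axis=1)
    split = (count > 0) & (last - first + 1 != count)
    if split.any():
        b, x = _first_offending(split)
        raise BoundaryExtractionError(
            f"{context}: {LABEL_NAMES[label]} split into multiple runs "
            f"in B-scan {b}, column {x}"
        )
    if required and (count == 0).any():
        b, x = _first_offending(count == 0)
        raise BoundaryExtractionError(
            f"{context}: no {LABEL_NAMES[label]} pixels in B-scan {b}, column {x}"
        )
    return first, last, count


def extract_boundaries(masks: np.ndarray, *, context: str = "volume") -> BoundaryCurves:
    """Extract ILM and choroid boundary curves from a compartment mask stack.

    Every column of every B-scan must contain exactly one contiguous run of
    retina and one of choroid, in the fixed vertical order
    vitreous -> retina -> choroid -> background; violations raise
    :class:`BoundaryExtractionError` naming the offending B-scan and column.
    """
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.ndim != 3:
        raise ValueError("masks must be a (n_bscans, depth, width) stack")
    known = np.isin(masks, list(LABEL_NAMES))
    if not known.all():
        bad = int(masks[~known].flat[0])
        raise BoundaryExtractionError(f"{context}: unknown label value {bad}")

    ret_first, ret_last, _ = _label_runs(
        masks, LABEL_RETINA, required=True, context=context
    )
    cho_first, cho_last, cho_count = _label_runs(
        masks, LABEL_CHOROID, required=True, context=context
    )
    vit_first, vit_last, vit_count = _label_runs(
        masks, LABEL_VITREOUS, required=False, context=context
    )
    _label_runs(masks, LABEL_BACKGROUND, required=False, context=context)

    # Vertical ordering: vitreous (if any) strictly above retina, retina
    # above choroid.
    disorder = ((vit_count > 0) & (vit_last >= ret_first)) | (ret_last >= cho_first)
    if disorder.any():
        b, x = _first_offending(disorder)
        raise BoundaryExtractionError(
            f"{context}: compartments out of vertical order in B-scan {b}, column {x}"
        )
    return BoundaryCurves(
        ilm=ret_first, choroid_inner=cho_first, choroid_outer=cho_last + 1
    )


def quality_filter(
    volumes: Sequence[OctVolume], threshold: int = 25
) -> tuple[list[OctVolume], list[OctVolume]]:
    """Partition volumes by the manufacturer-style scan-quality score.

    Volumes with ``quality >= threshold`` are included (the boundary value
    itself passes); the partition is exhaustive and disjoint.  A missing
    quality score raises :class:`DatasetError`.
    """
    included: list[OctVolume] = []
    excluded: list[OctVolume] = []
    for vol in volumes:
        if vol.quality is None:
            raise DatasetError(f"volume {vol.eye_id!r} has no quality score")
        (included if vol.quality >= threshold else excluded).append(vol)
    return included, excluded


# ---------------------------------------------------------------------------
# On-disk dataset layout:
#   <eye_dir>/metadata.json
#   <eye_dir>/bscan_000.png ... (or .bmp)   8-bit grayscale
#   <eye_dir>/mask_000.png ...              indexed PNG, palette above
# ---------------------------------------------------------------------------


def _mask_to_image(mask: np.ndarray) -> Image.Image:
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [0] * 768
    for label, (r, g, b) in MASK_PALETTE.items():
        palette[3 * label : 3 * label + 3] = [r, g, b]
    img.putpalette(palette)
    return img


def write_volume(
    directory: str | Path,
    volume: OctVolume,
    masks: np.ndarray,
    *,
    image_format: str = "png",
    extra_metadata: dict | None = None,
) -> Path:
    """Write one eye's B-scans, masks and metadata JSON to ``directory``."""
    if image_format not in ("png", "bmp"):
        raise ValueError("image_format must be 'png' or 'bmp'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    masks = np.asarray(masks, dtype=np.uint8)
    if masks.shape != volume.bscans.shape:
        raise DatasetError("mask stack shape does not match B-scan stack")
    for i, (bscan, mask) in enumerate(zip(volume.bscans, masks)):
        Image.fromarray(np.asarray(bscan, dtype=np.uint8), mode="L").save(
            directory / f"bscan_{i:03d}.{image_format}"
        )
        _mask_to_image(mask).save(directory / f"mask_{i:03d}.png")
    meta = volume.metadata()
    if extra_metadata:
        meta.update(extra_metadata)
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_volume(directory: str | Path) -> tuple[OctVolume, np.ndarray]:
    """Read one eye directory back into an (OctVolume, mask stack) pair.

    Images and masks are aligned by their zero-padded index; a missing mask,
    a size mismatch or an unknown label value raises :class:`DatasetError`
    naming the offending file.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise DatasetError(f"missing metadata.json in {directory}")
    meta = json.loads(meta_path.read_text())
    geometry = ScanGeometry.from_dict(meta["geometry"])

    bscan_paths = sorted(
        p for p in directory.iterdir() if p.stem.startswith("bscan_")
    )
    if len(bscan_paths) != geometry.n_bscans:
        raise DatasetError(
            f"{directory}: expected {geometry.n_bscans} B-scans, "
            f"found {len(bscan_paths)}"
        )
    bscans, masks = [], []
    for bpath in bscan_paths:
        index = bpath.stem.split("_")[1]
        mpath = directory / f"mask_{index}.png"
        if not mpath.exists():
            raise DatasetError(f"missing mask for B-scan file {bpath.name}")
        bscan = np.asarray(Image.open(bpath).convert("L"))
        mask = np.asarray(Image.open(mpath))
        if bscan.shape != (geometry.depth_px, geometry.width_px):
            raise DatasetError(f"{bpath.name}: image size {bscan.shape} mismatch")
        if mask.shape != bscan.shape:
            raise DatasetError(f"{mpath.name}: mask size {mask.shape} mismatch")
        unknown = set(np.unique(mask)) - set(LABEL_NAMES)
        if unknown:
            raise DatasetError(
                f"{mpath.name}: unknown label value(s) {sorted(unknown)}"
            )
        bscans.append(bscan)
        masks.append(mask)
    volume = OctVolume(
        bscans=np.stack(bscans),
        geometry=geometry,
        quality=meta.get("quality"),
        eye_id=meta.get("eye_id", directory.name),
        side=meta.get("side", "OD"),
        sex=meta.get("sex", "unknown"),
        origin=meta.get("origin", "unknown"),
    )
    return volume, np.stack(masks)
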