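"""Locating the nulla: the deepest foveolar point on the smoothed ILM.

The ILM depth profile extracted from the segmentation is noisy, so it is
first smoothed with a two-dimensional moving average over the
(B-scan index x lateral pixel) grid.  The nulla is the global depth maximum
of the smoothed surface across the whole volume; when several grid points
tie for the deepest value (typically adjacent, e.g. on a flat-bottomed pit)
the unweighted centre of mass of the tied points is reported, which may
yield fractional B-scan and lateral coordinates.

Depth is measured in axial pixels with row 0 at the top of the image, so
"deepest" means the maximum depth value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["IlmSurface", "NullaPoint", "smooth_ilm", "find_nulla", "DEFAULT_WINDOW"]

#: Default smoothing window: 3 B-scans x 31 lateral pixels (~0.32 mm laterally
#: at the default geometry) — wide enough laterally to suppress segmentation
#: jitter while spanning only one slice either side of the 221 um-spaced
#: B-scans.
DEFAULT_WINDOW: tuple[int, int] = (3, 31)

#: Depths within this tolerance (axial px) of the maximum count as tied.
TIE_TOLERANCE = 1e-9


@dataclass
class IlmSurface:
    """Smoothed ILM depth values on the (B-scan x lateral pixel) grid."""

    values: np.ndarray  # axial px, possibly fractional after smoothing
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ILM surface must be a 2D (n_bscans, width) grid")


@dataclass(frozen=True)
class NullaPoint:
    """The deepest smoothed-ILM location in a volume.

    Coordinates may be fractional when several grid points tie for the
    deepest value; ``n_tied`` records how many points entered the centroid.
    """

    bscan: float
    lateral: float
    depth: float
    n_tied: int = 1


def smooth_ilm(raw: np.ndarray, window: tuple[int, int] = DEFAULT_WINDOW) -> IlmSurface:
    """Smooth a raw ILM grid with a 2D moving average.

    Each output value is the arithmetic mean of the raw values inside the
    ``(w_bscans, w_lateral)`` window centred on the cell, intersected with
    the grid (the window shrinks at the borders, so border cells average
    fewer neighbours).  Window ``(1, 1)`` is the identity.

    Both window dimensions must be odd, positive and no larger than the
    corresponding grid dimension.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw ILM grid must be 2D (n_bscans, width)")
    w_b, w_l = window
    for w, size, axis in ((w_b, raw.shape[0], "B-scan"), (w_l, raw.shape[1], "lateral")):
        if w < 1 or w % 2 == 0:
            raise ValueError(f"{axis} window must be a positive odd integer, got {w}")
        if w > size:
            raise ValueError(f"{axis} window {w} exceeds grid dimension {size}")
    # Zero-padded windowed mean divided by the in-grid window fraction gives
    # the shrinking-window mean exactly (up to float rounding).
    num = ndimage.uniform_filter(raw, size=window, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(
        np.ones_like(raw), size=window, mode="constant", cval=0.0
    )
    return IlmSurface(values=num / den, window=(w_b, w_l))


def find_nulla(surface: IlmSurface, tie_tolerance: float = TIE_TOLERANCE) -> NullaPoint:
    """Locate the deepest point of a smoothed ILM surface.

    All grid points whose depth lies within ``tie_tolerance`` of the global
    maximum are collected and their unweighted centroid returned as the
    (bscan, lateral) coordinates; the reported depth is the global maximum.
    """
    values = surface.values
    if values.size == 0:
        raise ValueError("cannot locate the nulla on an empty surface")
    depth = float(values.max())
    tied = np.argwhere(values >= depth - tie_tolerance)
    centroid = tied.mean(axis=0)
    return NullaPoint(
        bscan=float(centroid[0]),
        lateral=float(centroid[1]),
        depth=depth,
        n_tied=int(len(tied)),
    )
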