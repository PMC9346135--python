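"""Nulla-anchored choroidal landmark morphometry on a single B-scan.

On the B-scan containing the nulla, nine axial choroidal thicknesses are
measured: T5 directly under the nulla and T1-T4 / T6-T9 at 500 um steps out
to +/-2000 um on the nasal and temporal sides.  Between adjacent thickness
landmarks the eight choroidal cross-sectional areas A1-A8 are integrated
(A4 and A5 flank the nulla).  A central-bouquet (umbo) sub-analysis adds
thicknesses 100 um nasal/temporal of the nulla (TUn, TUt) and the areas of
the two adjoining 100 um half-spans (AUn, AUt).  Together the grid yields
17 parameters (9 thicknesses + 8 areas) and the nulla sub-analysis 5
(T5, TUn, TUt, AUn, AUt).

Thickness is strictly axial (along image columns); boundary depths are
linearly interpolated between lateral pixels so landmarks at fractional
pixel positions are stable.  The landmark axis runs nasal -> temporal
(T1 most nasal), with the image direction of "nasal" resolved from the eye
side by the laterality convention: with the default ``nasal_positive_od``,
nasal is +x (increasing lateral pixel) for right eyes and -x for left eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    BoundaryCurves,
    ChoroidRefError,
    OctVolume,
    ScanGeometry,
    extract_boundaries,
)
from .nulla import DEFAULT_WINDOW, NullaPoint, find_nulla, smooth_ilm

__all__ = [
    "MeasureConfig",
    "EyeMeasurement",
    "MEASURE_COLUMNS",
    "THICKNESS_NAMES",
    "AREA_NAMES",
    "UMBO_NAMES",
    "nasal_sign",
    "thickness_at",
    "measure_landmarks",
    "area_between",
    "measure_eye",
    "measure_cohort",
]

THICKNESS_NAMES = tuple(f"T{i}" for i in range(1, 10))
AREA_NAMES = tuple(f"A{i}" for i in range(1, 9))
UMBO_NAMES = ("TUn", "TUt", "AUn", "AUt")
MEASURE_COLUMNS = THICKNESS_NAMES + AREA_NAMES + UMBO_NAMES


class MeasurementSpanError(ChoroidRefError):
    """A requested lateral position falls outside the scanned extent."""


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable parameters of the measurement stage."""

    smoothing_window: tuple[int, int] = DEFAULT_WINDOW
    landmark_spacing_um: float = 500.0
    max_offset_um: float = 2000.0
    umbo_offset_um: float = 100.0
    laterality_convention: str = "nasal_positive_od"
    quality_threshold: int = 25

    def __post_init__(self) -> None:
        if self.laterality_convention not in ("nasal_positive_od", "nasal_positive_os"):
            raise ValueError(
                f"unknown laterality convention {self.laterality_convention!r}"
            )


@dataclass
class EyeMeasurement:
    """The 21 measured values of one eye plus covariates and nulla metadata."""

    eye_id: str
    side: str
    sex: str
    origin: str
    quality: int | None
    nulla: NullaPoint
    nulla_bscan: int  # integer B-scan the grid was measured on
    nulla_x_um: float
    thicknesses_um: np.ndarray  # T1..T9
    areas_um2: np.ndarray  # A1..A8
    umbo_thicknesses_um: tuple[float, float]  # (TUn, TUt)
    umbo_areas_um2: tuple[float, float]  # (AUn, AUt)

    @property
    def grid_parameters(self) -> dict[str, float]:
        """The 17 grid parameters: T1-T9 and A1-A8."""
        out = {n: float(v) for n, v in zip(THICKNESS_NAMES, self.thicknesses_um)}
        out.update({n: float(v) for n, v in zip(AREA_NAMES, self.areas_um2)})
        return out

    @property
    def nulla_subanalysis(self) -> dict[str, float]:
        """The 5 umbo sub-analysis parameters: T5, TUn, TUt, AUn, AUt."""
        return {
            "T5": float(self.thicknesses_um[4]),
            "TUn": float(self.umbo_thicknesses_um[0]),
            "TUt": float(self.umbo_thicknesses_um[1]),
            "AUn": float(self.umbo_areas_um2[0]),
            "AUt": float(self.umbo_areas_um2[1]),
        }

    def to_dict(self) -> dict:
        row = {
            "eye_id": self.eye_id,
            "side": self.side,
            "sex": self.sex,
            "origin": self.origin,
            "quality": self.quality,
            "nulla_bscan": self.nulla_bscan,
            "nulla_x_um": float(self.nulla_x_um),
        }
        row.update(self.grid_parameters)
        row["TUn"], row["TUt"] = map(float, self.umbo_thicknesses_um)
        row["AUn"], row["AUt"] = map(float, self.umbo_areas_um2)
        return row


def nasal_sign(side: str, convention: str = "nasal_positive_od") -> int:
    """Image-x direction of "nasal" (+1 right, -1 left) for an eye side."""
    if side not in ("OD", "OS"):
        raise ValueError(f"side must be 'OD' or 'OS', got {side!r}")
    base = 1 if convention == "nasal_positive_od" else -1
    return base if side == "OD" else -base


def _interp_boundary(profile: np.ndarray, x_px: np.ndarray | float) -> np.ndarray:
    grid = np.arange(profile.shape[0], dtype=float)
    return np.interp(x_px, grid, profile)


def _check_span(x_um: np.ndarray | float, geometry: ScanGeometry, what: str) -> None:
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    max_um = (geometry.width_px - 1) * geometry.lateral_scale
    if np.any(x < 0) or np.any(x > max_um):
        raise MeasurementSpanError(
            f"{what} at {x[(x < 0) | (x > max_um)][0]:.1f} um is outside the "
            f"scanned extent [0, {max_um:.1f}] um"
        )


def thickness_at(
    boundaries: BoundaryCurves,
    bscan: int,
    x_um: float,
    geometry: ScanGeometry,
) -> float:
    """Axial choroidal thickness (um) at a lateral position on one B-scan.

    Both choroid boundaries are linearly interpolated between adjacent
    lateral pixels; the pixel-unit difference is converted to micrometres
    with the axial scale.
    """
    _check_span(x_um, geometry, "thickness landmark")
    x_px = x_um / geometry.lateral_scale
    inner = _interp_boundary(boundaries.choroid_inner[bscan], x_px)
    outer = _interp_boundary(boundaries.choroid_outer[bscan], x_px)
    return float((outer - inner) * geometry.axial_scale)


def landmark_positions_um(
    nulla_x_um: float,
    side: str,
    config: MeasureConfig = MeasureConfig(),
) -> np.ndarray:
    """Lateral positions (um, image frame) of T1..T9 for an eye side."""
    sign = nasal_sign(side, config.laterality_convention)
    # T_i sits (5 - i) * spacing on the nasal side: T1 most nasal, T9 most
    # temporal, T5 at the nulla.
    offsets = np.array([(5 - i) * config.landmark_spacing_um for i in range(1, 10)])
    return nulla_x_um + sign * offsets


def measure_landmarks(
    boundaries: BoundaryCurves,
    nulla: NullaPoint,
    side: str,
    geometry: ScanGeometry,
    config: MeasureConfig = MeasureConfig(),
    *,
    bscan: int | None = None,
) -> np.ndarray:
    """Measure T1..T9 (um) on the nulla's B-scan."""
    if bscan is None:
        bscan = _nearest_bscan(nulla.bscan, geometry.n_bscans)
    nulla_x_um = nulla.lateral * geometry.lateral_scale
    positions = landmark_positions_um(nulla_x_um, side, config)
    out = np.empty(9)
    for i, x in enumerate(positions):
        try:
            _check_span(x, geometry, f"landmark T{i + 1}")
        except MeasurementSpanError as err:
            raise MeasurementSpanError(str(err)) from None
        out[i] = thickness_at(boundaries, bscan, float(x), geometry)
    return out


def area_between(
    boundaries: BoundaryCurves,
    bscan: int,
    x1_um: float,
    x2_um: float,
    geometry: ScanGeometry,
) -> float:
    """Choroidal cross-sectional area (um^2) over a lateral interval.

    The integral of the axial thickness over ``[x1, x2]`` is computed with
    the trapezoid rule over every lateral pixel node inside the interval
    plus the two (possibly fractional) end points — i.e. the piecewise-linear
    boundary interpolant is integrated exactly.
    """
    if not x1_um < x2_um:
        raise MeasurementSpanError(
            f"area interval is inverted or empty: [{x1_um}, {x2_um}]"
        )
    _check_span([x1_um, x2_um], geometry, "area bound")
    s = geometry.lateral_scale
    x1_px, x2_px = x1_um / s, x2_um / s
    interior = np.arange(np.floor(x1_px) + 1, np.ceil(x2_px))
    nodes_px = np.concatenate(([x1_px], interior, [x2_px]))
    inner = _interp_boundary(boundaries.choroid_inner[bscan], nodes_px)
    outer = _interp_boundary(boundaries.choroid_outer[bscan], nodes_px)
    thickness_um = (outer - inner) * geometry.axial_scale
    return float(np.trapezoid(thickness_um, nodes_px * s))


def _nearest_bscan(bscan_coord: float, n_bscans: int) -> int:
    """Nearest integer B-scan; half-way ties resolve toward the volume centre."""
    lo = int(np.floor(bscan_coord))
    hi = int(np.ceil(bscan_coord))
    if lo == hi:
        return lo
    if bscan_coord - lo < hi - bscan_coord:
        return lo
    if hi - bscan_coord < bscan_coord - lo:
        return hi
    centre = (n_bscans - 1) / 2
    return lo if abs(lo - centre) <= abs(hi - centre) else hi


def measure_eye(
    volume: OctVolume,
    masks: np.ndarray,
    config: MeasureConfig = MeasureConfig(),
) -> EyeMeasurement:
    """Run the full deterministic measurement stage on one segmented volume.

    Extracts boundary curves from the masks, smooths the ILM, locates the
    nulla, then measures the 17-parameter landmark grid and the 4 umbo
    values on the B-scan containing the nulla.
    """
    try:
        boundaries = extract_boundaries(masks, context=volume.eye_id)
        surface = smooth_ilm(boundaries.ilm, config.smoothing_window)
        nulla_pt = find_nulla(surface)
        geometry = volume.geometry
        bscan = _nearest_bscan(nulla_pt.bscan, geometry.n_bscans)
        nulla_x_um = nulla_pt.lateral * geometry.lateral_scale

        thicknesses = measure_landmarks(
            boundaries, nulla_pt, volume.side, geometry, config, bscan=bscan
        )
        positions = landmark_positions_um(nulla_x_um, volume.side, config)
        areas = np.empty(8)
        for i in range(8):
            lo, hi = sorted((positions[i], positions[i + 1]))
            areas[i] = area_between(boundaries, bscan, lo, hi, geometry)

        sign = nasal_sign(volume.side, config.laterality_convention)
        x_nasal = nulla_x_um + sign * config.umbo_offset_um
        x_temporal = nulla_x_um - sign * config.umbo_offset_um
        tun = thickness_at(boundaries, bscan, x_nasal, geometry)
        tut = thickness_at(boundaries, bscan, x_temporal, geometry)
        aun = area_between(boundaries, bscan, *sorted((nulla_x_um, x_nasal)), geometry)
        aut = area_between(
            boundaries, bscan, *sorted((nulla_x_um, x_temporal)), geometry
        )
    except ChoroidRefError as err:
        raise type(err)(f"eye {volume.eye_id!r}: {err}") from None

    return EyeMeasurement(
        eye_id=volume.eye_id,
        side=volume.side,
        sex=volume.sex,
        origin=volume.origin,
        quality=volume.quality,
        nulla=nulla_pt,
        nulla_bscan=bscan,
        nulla_x_um=nulla_x_um,
        thicknesses_um=thicknesses,
        areas_um2=areas,
        umbo_thicknesses_um=(tun, tut),
        umbo_areas_um2=(aun, aut),
    )


def measure_cohort(
    eyes,
    config: MeasureConfig = MeasureConfig(),
) -> pd.DataFrame:
    """Measure an iterable of (volume, masks, ...) tuples into a table.

    Applies the scan-quality inclusion filter from ``config`` before
    measuring, so the returned frame contains one row per *included* eye.
    Streams, so it works for cohorts too large to hold in memory.
    """
    rows = []
    for item in eyes:
        volume, masks = item[0], item[1]
        if volume.quality is not None and volume.quality < config.quality_threshold:
            continue
        rows.append(measure_eye(volume, masks, config).to_dict())
    columns = [
        "eye_id", "side", "sex", "origin", "quality", "nulla_bscan",
        "nulla_x_um", *MEASURE_COLUMNS,
    ]
    return pd.DataFrame(rows, columns=columns)
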