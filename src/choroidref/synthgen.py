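"""Synthetic segmented OCT volumes with analytically known morphometry.

No scan data accompany the reference database, so this module emulates the
acquisition: volumes on the Spectralis-style geometry (25 B-scans, 512x496
px, 5.3 x 1.9 mm), a foveal pit in the ILM, a choroid band whose thickness
profile passes exactly through nine per-eye landmark targets, per-pixel
compartment masks, and a manufacturer-style integer quality score.  Because
the layer profiles are parametric, every one of the 21 landmark values
(T1-T9, A1-A8, TUn, TUt, AUn, AUt) is known in closed form, which makes the
whole measurement pipeline verifiable by parameter recovery.

Model choices:

* the foveal pit is an inverted 2D Gaussian in the ILM depth (optionally
  with a flat bottom to exercise tie handling); the pit centre is the
  unique true deepest point;
* the inner choroid boundary is flat, so retinal thickness varies with the
  pit while the choroid band is controlled independently;
* the choroidal thickness profile is piecewise linear through the nine
  landmark targets at 500 um steps (constant beyond +/-2000 um), so
  thickness and trapezoid-area truths are exact by construction;
* left eyes (OS) are generated as mirror images of right-eye geometry: the
  profile is laid out in the nasal/temporal frame and mapped to image x via
  the laterality convention;
* speckle-like multiplicative noise affects only the intensity image; the
  masks stay noise-free because segmentation is taken as given.

The module also houses the ground-truth bookkeeping of the segmentation
training stage (train/validation/test split arithmetic and the
mirror+rotate augmentation), which operates on B-scan counts and images
only — the CNN itself is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import (
    LABEL_BACKGROUND,
    LABEL_CHOROID,
    LABEL_RETINA,
    LABEL_VITREOUS,
    GeometryOverflowError,
    OctVolume,
    ScanGeometry,
    write_volume,
)
from .morphometry import AREA_NAMES, MEASURE_COLUMNS, THICKNESS_NAMES, nasal_sign

__all__ = [
    "ScanGeometry",
    "EyeParams",
    "EyeGeometryTruth",
    "PopulationModel",
    "paper_cohort",
    "generate_eye",
    "generate_cohort",
    "iter_cohort",
    "write_cohort",
    "split_ground_truth",
    "augment_bscans",
    "TRUTH_TABLE_COLUMNS",
]

TRUTH_TABLE_COLUMNS = ["eye_id", "side", "sex", "origin", "quality", *MEASURE_COLUMNS]

#: Landmark nasal offsets in um, T1 (most nasal, +2000) .. T9 (most temporal).
LANDMARK_NASAL_OFFSETS_UM = np.array([(5 - i) * 500.0 for i in range(1, 10)])

# Mean grayscale levels used when rendering intensity images.
_COMPARTMENT_LEVELS = {
    LABEL_BACKGROUND: 25,
    LABEL_VITREOUS: 35,
    LABEL_RETINA: 150,
    LABEL_CHOROID: 105,
}


@dataclass(frozen=True)
class EyeParams:
    """Parametric description of one synthetic eye.

    Depths are measured downward from the image top in micrometres.
    ``landmark_thicknesses_um`` are the choroid targets at the nine nasal
    offsets +2000 .. -2000 um (T1..T9); the thickness profile interpolates
    them linearly and is constant beyond +/-2000 um.
    """

    eye_id: str = "eye_000"
    side: str = "OD"
    sex: str = "unknown"
    origin: str = "unknown"
    quality: int = 30
    pit_bscan: int = 12
    pit_lateral_um: float = 2650.0
    pit_depth_um: float = 120.0
    pit_sigma_lateral_um: float = 450.0
    pit_sigma_bscan_um: float = 350.0
    pit_plateau_halfwidth_um: float = 0.0
    ilm_base_um: float = 320.0
    inner_boundary_um: float = 640.0
    landmark_thicknesses_um: tuple[float, ...] = (193.0,) * 9
    noise_sigma: float = 0.2
    laterality_convention: str = "nasal_positive_od"

    def __post_init__(self) -> None:
        if len(self.landmark_thicknesses_um) != 9:
            raise ValueError("exactly nine landmark thicknesses are required")
        if min(self.landmark_thicknesses_um) <= 0:
            raise ValueError("landmark thicknesses must be positive")


@dataclass
class EyeGeometryTruth:
    """Closed-form ground truth for one generated eye."""

    pit_center: tuple[int, float]  # (B-scan index, lateral um)
    ilm_profile: Callable[[np.ndarray, np.ndarray], np.ndarray]
    retina_thickness_profile: Callable[[np.ndarray], np.ndarray]
    choroid_thickness_profile: Callable[[np.ndarray], np.ndarray]
    true_measurements: dict[str, float]


def _choroid_profile_nasal(params: EyeParams) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear thickness profile over the signed nasal offset (um)."""
    # np.interp needs ascending knots: temporal (-2000, T9) .. nasal (+2000, T1).
    knots = LANDMARK_NASAL_OFFSETS_UM[::-1]
    values = np.asarray(params.landmark_thicknesses_um, dtype=float)[::-1]

    def profile(offset_nasal_um: np.ndarray) -> np.ndarray:
        return np.interp(offset_nasal_um, knots, values)

    return profile


def _ilm_profile(
    params: EyeParams, geometry: ScanGeometry
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    def profile(bscan: np.ndarray, x_um: np.ndarray) -> np.ndarray:
        d_lat = np.maximum(
            0.0, np.abs(np.asarray(x_um, float) - params.pit_lateral_um)
            - params.pit_plateau_halfwidth_um
        )
        d_b = (np.asarray(bscan, float) - params.pit_bscan) * geometry.bscan_spacing_um
        bump = np.exp(
            -(
                d_lat**2 / (2 * params.pit_sigma_lateral_um**2)
                + d_b**2 / (2 * params.pit_sigma_bscan_um**2)
            )
        )
        return params.ilm_base_um + params.pit_depth_um * bump

    return profile


def _true_measurements(params: EyeParams) -> dict[str, float]:
    """Landmark truths computed in closed form from the thickness targets."""
    t = np.asarray(params.landmark_thicknesses_um, dtype=float)
    out = {name: float(v) for name, v in zip(THICKNESS_NAMES, t)}
    # Areas between adjacent landmarks: exact trapezoids of the linear profile.
    areas = 500.0 * (t[:-1] + t[1:]) / 2.0
    out.update({name: float(a) for name, a in zip(AREA_NAMES, areas)})
    # Umbo values 100 um to either side: linear interpolation toward T4/T6.
    t5 = t[4]
    tun = t5 + (t[3] - t5) * (100.0 / 500.0)
    tut = t5 + (t[5] - t5) * (100.0 / 500.0)
    out["TUn"] = float(tun)
    out["TUt"] = float(tut)
    out["AUn"] = float(100.0 * (t5 + tun) / 2.0)
    out["AUt"] = float(100.0 * (t5 + tut) / 2.0)
    return out


def generate_eye(
    geometry: ScanGeometry,
    params: EyeParams,
    seed: int = 0,
    *,
    render_intensity: bool = True,
) -> tuple[OctVolume, np.ndarray, EyeGeometryTruth]:
    """Generate one synthetic eye: intensity volume, mask stack and truth.

    The parametric boundary profiles are evaluated on the pixel grid
    (lateral position ``px * lateral_scale``) and rasterized by rounding to
    the nearest axial pixel, so rasterized boundaries sit within one axial
    pixel of the continuous profiles.  Profiles that do not fit inside the
    scan depth raise :class:`GeometryOverflowError`.
    """
    ilm_fn = _ilm_profile(params, geometry)
    choroid_fn = _choroid_profile_nasal(params)
    sign = nasal_sign(params.side, params.laterality_convention)

    b_idx = np.arange(geometry.n_bscans)[:, None]
    x_um = (np.arange(geometry.width_px) * geometry.lateral_scale)[None, :]
    ilm_um = ilm_fn(b_idx, x_um)
    inner_um = np.full_like(ilm_um, params.inner_boundary_um)
    offset_nasal = (x_um - params.pit_lateral_um) * sign
    outer_um = inner_um + choroid_fn(np.broadcast_to(offset_nasal, ilm_um.shape))

    axial = geometry.axial_scale
    if (
        ilm_um.max() + axial >= params.inner_boundary_um
        or outer_um.max() + axial >= geometry.depth_um
        or ilm_um.min() <= 0
    ):
        raise GeometryOverflowError(
            "layer profiles (pit + retina + choroid) exceed the scan depth "
            f"of {geometry.depth_um} um"
        )

    ilm_px = np.rint(ilm_um / axial).astype(int)
    inner_px = np.rint(inner_um / axial).astype(int)
    outer_px = np.rint(outer_um / axial).astype(int)

    # Count how many boundaries lie at or above each row: 0 -> vitreous,
    # 1 -> retina, 2 -> choroid, 3 -> background.
    rows = np.arange(geometry.depth_px, dtype=np.int32)[None, :, None]
    zone = (
        (rows >= ilm_px[:, None, :]).astype(np.uint8)
        + (rows >= inner_px[:, None, :])
        + (rows >= outer_px[:, None, :])
    )
    lut = np.array(
        [LABEL_VITREOUS, LABEL_RETINA, LABEL_CHOROID, LABEL_BACKGROUND], dtype=np.uint8
    )
    masks = lut[zone]

    if render_intensity:
        rng = np.random.default_rng(seed)
        levels = np.zeros(max(_COMPARTMENT_LEVELS) + 1)
        for label, level in _COMPARTMENT_LEVELS.items():
            levels[label] = level
        base = levels[masks]
        speckle = rng.lognormal(
            mean=-0.5 * params.noise_sigma**2, sigma=params.noise_sigma, size=base.shape
        )
        bscans = np.clip(base * speckle, 0, 255).astype(np.uint8)
    else:
        bscans = np.zeros(masks.shape, dtype=np.uint8)

    volume = OctVolume(
        bscans=bscans,
        geometry=geometry,
        quality=params.quality,
        eye_id=params.eye_id,
        side=params.side,
        sex=params.sex,
        origin=params.origin,
    )
    truth = EyeGeometryTruth(
        pit_center=(params.pit_bscan, params.pit_lateral_um),
        ilm_profile=ilm_fn,
        retina_thickness_profile=lambda x: params.inner_boundary_um
        - ilm_fn(np.full_like(np.asarray(x, float), params.pit_bscan), x),
        choroid_thickness_profile=choroid_fn,
        true_measurements=_true_measurements(params),
    )
    return volume, masks, truth


# ---------------------------------------------------------------------------
# Cohort-level population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """Population distributions from which per-eye parameters are drawn.

    ``landmark_mean_um``/``landmark_sd_um`` parameterize independent normal
    draws of the nine landmark thickness targets (floored at 60 um to keep
    the band physical; at reference parameters the floor is ~9 sd away).
    Covariate frequencies are (category -> probability) maps that must sum
    to one; the quality score is a uniform integer on
    ``[quality_min, quality_max]``.
    """

    n_eyes: int = 50
    landmark_mean_um: tuple[float, ...] = (190.0,) * 9
    landmark_sd_um: tuple[float, ...] = (14.8,) * 9
    sex_freq: dict = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5}
    )
    origin_freq: dict = field(
        default_factory=lambda: {"Mauritius": 0.5, "Asia": 0.5}
    )
    side_freq: dict = field(default_factory=lambda: {"OD": 0.5, "OS": 0.5})
    quality_min: int = 15
    quality_max: int = 40
    pit_depth_range_um: tuple[float, float] = (100.0, 140.0)
    pit_lateral_jitter_um: float = 200.0
    pit_bscan_jitter: int = 1
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes <= 0:
            raise ValueError("n_eyes must be positive")
        if len(self.landmark_mean_um) != 9 or len(self.landmark_sd_um) != 9:
            raise ValueError("landmark distributions need nine entries")
        if min(self.landmark_sd_um) < 0:
            raise ValueError("landmark sd must be >= 0")
        for name in ("sex_freq", "origin_freq", "side_freq"):
            freqs = getattr(self, name)
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


#: Overall mean choroidal thickness at the nulla (um) and its coefficient of
#: variation used by the reference-cohort preset.
PAPER_COHORT_NULLA_MEAN_UM = 192.83
PAPER_COHORT_NULLA_CV_PCT = 7.8


def paper_cohort(n_eyes: int = 374, seed: int = 0) -> PopulationModel:
    """The reference-cohort preset.

    Encodes the published cohort composition (39.30% female eyes, 53.21%
    Mauritius / 42.51% Asia / 4.28% unknown origin, 50.27% right eyes) and a
    nulla thickness distribution with mean 192.83 um and CV 7.8%; the other
    landmark means are calibrated to the reported subgroup summary tables.
    All quality scores are >= 25 because the published cohort is already
    quality-filtered.
    """
    means = (190.0, 191.0, 190.0, 191.0, PAPER_COHORT_NULLA_MEAN_UM, 191.0, 192.0,
             192.0, 192.0)
    sds = tuple(round(m * PAPER_COHORT_NULLA_CV_PCT / 100.0, 4) for m in means)
    return PopulationModel(
        n_eyes=n_eyes,
        landmark_mean_um=means,
        landmark_sd_um=sds,
        sex_freq={"female": 0.393, "male": 0.607},
        origin_freq={"Mauritius": 0.5321, "Asia": 0.4251, "unknown": 0.0428},
        side_freq={"OD": 0.5027, "OS": 0.4973},
        quality_min=25,
        quality_max=40,
        seed=seed,
    )


PRESETS: dict[str, Callable[..., PopulationModel]] = {"paper_cohort": paper_cohort}

_LANDMARK_FLOOR_UM = 60.0


def draw_cohort_params(
    model: PopulationModel, geometry: ScanGeometry
) -> tuple[list[EyeParams], pd.DataFrame]:
    """Draw per-eye parameters and the closed-form truth table.

    Reproducible: identical (model, geometry) pairs give identical output.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_eyes

    def draw_cat(freqs: dict) -> np.ndarray:
        cats = list(freqs)
        return rng.choice(cats, size=n, p=[freqs[c] for c in cats])

    sexes = draw_cat(model.sex_freq)
    origins = draw_cat(model.origin_freq)
    sides = draw_cat(model.side_freq)
    qualities = rng.integers(model.quality_min, model.quality_max + 1, size=n)
    landmarks = rng.normal(
        loc=model.landmark_mean_um, scale=model.landmark_sd_um, size=(n, 9)
    )
    landmarks = np.maximum(landmarks, _LANDMARK_FLOOR_UM)
    pit_depths = rng.uniform(*model.pit_depth_range_um, size=n)
    centre_b = (geometry.n_bscans - 1) // 2
    pit_bscans = centre_b + rng.integers(
        -model.pit_bscan_jitter, model.pit_bscan_jitter + 1, size=n
    )
    pit_laterals = geometry.width_um / 2 + rng.uniform(
        -model.pit_lateral_jitter_um, model.pit_lateral_jitter_um, size=n
    )

    params: list[EyeParams] = []
    rows: list[dict] = []
    for i in range(n):
        p = EyeParams(
            eye_id=f"eye_{i:03d}",
            side=str(sides[i]),
            sex=str(sexes[i]),
            origin=str(origins[i]),
            quality=int(qualities[i]),
            pit_bscan=int(pit_bscans[i]),
            pit_lateral_um=float(pit_laterals[i]),
            pit_depth_um=float(pit_depths[i]),
            landmark_thicknesses_um=tuple(landmarks[i]),
            noise_sigma=model.noise_sigma,
        )
        params.append(p)
        row = {
            "eye_id": p.eye_id,
            "side": p.side,
            "sex": p.sex,
            "origin": p.origin,
            "quality": p.quality,
        }
        row.update(_true_measurements(p))
        rows.append(row)
    truth = pd.DataFrame(rows, columns=TRUTH_TABLE_COLUMNS)
    return params, truth


def iter_cohort(
    model: PopulationModel,
    geometry: ScanGeometry | None = None,
    *,
    render_intensity: bool = True,
) -> Iterator[tuple[OctVolume, np.ndarray, EyeGeometryTruth]]:
    """Yield generated eyes one at a time (memory-friendly for large cohorts)."""
    geometry = geometry or ScanGeometry()
    params, _ = draw_cohort_params(model, geometry)
    eye_seeds = np.random.default_rng(model.seed + 1).integers(0, 2**31, size=len(params))
    for p, s in zip(params, eye_seeds):
        yield generate_eye(geometry, p, seed=int(s), render_intensity=render_intensity)


def generate_cohort(
    model: PopulationModel,
    geometry: ScanGeometry | None = None,
    *,
    render_intensity: bool = True,
) -> tuple[list[tuple[OctVolume, np.ndarray, EyeGeometryTruth]], pd.DataFrame]:
    """Generate a whole cohort in memory plus its closed-form truth table.

    For cohorts of hundreds of eyes prefer :func:`iter_cohort`, which
    streams eyes instead of holding every mask stack at once.
    """
    geometry = geometry or ScanGeometry()
    _, truth = draw_cohort_params(model, geometry)
    eyes = list(iter_cohort(model, geometry, render_intensity=render_intensity))
    return eyes, truth


def write_cohort(
    directory: str | Path,
    model: PopulationModel,
    geometry: ScanGeometry | None = None,
    *,
    image_format: str = "png",
) -> Path:
    """Write a generated cohort to disk: one directory per eye + truth table."""
    geometry = geometry or ScanGeometry()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _, truth = draw_cohort_params(model, geometry)
    for volume, masks, _ in iter_cohort(model, geometry):
        write_volume(directory / volume.eye_id, volume, masks, image_format=image_format)
    truth.to_csv(directory / "truth.csv", index=False, float_format="%.4f")
    (directory / "population.json").write_text(
        json.dumps(dataclasses.asdict(model), indent=2)
    )
    return directory


# ---------------------------------------------------------------------------
# Ground-truth split / augmentation bookkeeping of the segmentation stage
# ---------------------------------------------------------------------------


def split_ground_truth(
    n_eyes: int, bscans_per_eye: int, split_eyes: tuple[int, int, int]
) -> tuple[int, int, int]:
    """B-scan counts of a (train, validation, test) eye-level split.

    The split must account for every eye; counts are eyes x B-scans per eye
    (e.g. 44 eyes of 25 B-scans split 27/9/8 -> 675/225/200).
    """
    if sum(split_eyes) != n_eyes:
        raise ValueError(
            f"split {split_eyes} does not sum to the {n_eyes} ground-truth eyes"
        )
    return tuple(s * bscans_per_eye for s in split_eyes)  # type: ignore[return-value]


def augment_bscans(
    bscans: Sequence[np.ndarray],
    rotation_range_deg: tuple[float, float] = (-8.0, 8.0),
    seed: int = 0,
) -> list[np.ndarray]:
    """Triple a training set: originals + vertical mirrors + random rotations.

    Mirroring flips each B-scan about its vertical axis; each original is
    additionally rotated by an angle drawn uniformly from
    ``rotation_range_deg`` (bilinear interpolation, frame preserved), so 675
    inputs become 2025 outputs.  Angles are reproducible from ``seed``.
    """
    if len(bscans) == 0:
        raise ValueError("cannot augment an empty B-scan list")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(*rotation_range_deg, size=len(bscans))
    originals = [np.asarray(b) for b in bscans]
    mirrored = [np.fliplr(b) for b in originals]
    rotated = [
        ndimage.rotate(b.astype(float), a, reshape=False, order=1, mode="nearest")
        for b, a in zip(originals, angles)
    ]
    return originals + mirrored + rotated
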