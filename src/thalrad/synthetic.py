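"""Synthetic phantom cohorts with the statistical structure the pipeline assumes.

Real clinical MRI cohorts for this analysis are not publicly available, so
every downstream stage is exercised on phantoms: per-subject stationary
Gaussian random fields inside jittered ellipsoidal ROIs, with a controllable
between-class effect, plus symptom-scale (PANSS) trajectories with a
controllable responder fraction.

Texture model
    Each subject's volume is white noise smoothed with a subject-specific
    Gaussian kernel (a stationary Gaussian random field), rescaled to a
    subject-specific field SD, plus a subject mean and iid acquisition noise.
    ``texture_effect`` shifts the class-1 mean of both the kernel width
    (spatial correlation length) and the log field SD, in units of their
    between-subject SDs — so it moves both co-occurrence correlation-type
    features and first-order dispersion features. ``intensity_effect``
    shifts the class-1 mean intensity the same way. Both effects zero makes
    the two classes exchangeable by construction.

Randomness
    All draws flow from a single root seed through fixed named substreams
    (``default_rng([seed, stream, index])``): stream 0 for cohort-level
    draws, stream 1 for per-subject volumes/ROIs, stream 2 for PANSS
    trajectories. Identical specs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .features import RoiMask, VoxelGrid
from .outcomes import SubjectRecord

__all__ = ["CohortSpec", "generate_cohort", "generate_panss"]

# between-subject SDs of the generative parameters (one unit of
# texture/intensity effect equals one of these SDs)
_SIGMA_MEAN = 1.0        # voxels, mean smoothing kernel width
_SIGMA_SD = 0.25
_LOG_FIELD_SD_MEAN = np.log(10.0)
_LOG_FIELD_SD_SD = 0.10
_INTENSITY_MEAN = 100.0
_INTENSITY_SD = 5.0
_MIN_ROI_VOXELS = 200


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one phantom cohort (two classes).

    Defaults emulate a two-scanner case-control cohort of 200 subjects on a
    48 mm cube at 2 mm isotropic spacing, with a one-SD texture difference
    between classes and a 56% responder fraction (61/109) among patients.
    """

    n_per_class: int = 100
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    roi_kind: str = "ellipsoid"          # or "two_ellipsoids"
    texture_effect: float = 1.0
    intensity_effect: float = 0.0
    noise_sd: float = 1.0
    responder_fraction: float = 61.0 / 109.0
    panss_baseline_mean_sd: tuple[float, float] = (90.0, 17.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ConfigurationError("n_per_class must be >= 2")
        if any(n < 8 for n in self.grid_shape):
            raise ConfigurationError("grid_shape entries must be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing_mm must be positive")
        if self.roi_kind not in ("ellipsoid", "two_ellipsoids"):
            raise ConfigurationError(f"unknown roi_kind {self.roi_kind!r}")
        if self.texture_effect < 0 or self.intensity_effect < 0:
            raise ConfigurationError("effects must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must lie in [0, 1]")


def _subject_rng(spec: CohortSpec, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream, index])


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _make_mask(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered axis-aligned ellipsoid(s); two mirrored components emulate a
    bilateral deep gray-matter structure treated as one union ROI."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    if spec.roi_kind == "ellipsoid":
        base = shape * np.array([0.34, 0.34, 0.32])
        semi = base * (1.0 + rng.uniform(-0.08, 0.08, size=3))
        center = (shape - 1) / 2.0
        mask = _ellipsoid(spec.grid_shape, center, semi)
        centers_semis = [(center, semi)]
    else:
        base = shape * np.array([0.34, 0.30, 0.16])
        centers_semis = []
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for side in (-1, 1):
            semi = base * (1.0 + rng.uniform(-0.08, 0.08, size=3))
            center = (shape - 1) / 2.0 + np.array(
                [0.0, 0.0, side * shape[2] * 0.22]
            )
            mask |= _ellipsoid(spec.grid_shape, center, semi)
            centers_semis.append((center, semi))
    for center, semi in centers_semis:
        lo = center - semi
        hi = center + semi
        if (lo < 1.0).any() or (hi > shape - 2.0).any():
            raise ConfigurationError(
                "ROI does not fit inside the grid with a 1-voxel margin"
            )
    if mask.sum() < _MIN_ROI_VOXELS:
        raise ConfigurationError(
            f"grid {spec.grid_shape} yields a {int(mask.sum())}-voxel ROI; "
            f"at least {_MIN_ROI_VOXELS} voxels are required"
        )
    return mask


def _make_volume(spec: CohortSpec, rng: np.random.Generator, cls: int) -> np.ndarray:
    sigma = rng.normal(
        _SIGMA_MEAN + cls * spec.texture_effect * _SIGMA_SD, _SIGMA_SD
    )
    sigma = max(sigma, 0.3)
    log_sd = rng.normal(
        _LOG_FIELD_SD_MEAN + cls * spec.texture_effect * _LOG_FIELD_SD_SD,
        _LOG_FIELD_SD_SD,
    )
    mean = rng.normal(
        _INTENSITY_MEAN + cls * spec.intensity_effect * _INTENSITY_SD,
        _INTENSITY_SD,
    )
    field = gaussian_filter(
        rng.standard_normal(spec.grid_shape), sigma, mode="wrap"
    )
    field /= field.std()
    noise = rng.standard_normal(spec.grid_shape) * spec.noise_sd
    return mean + np.exp(log_sd) * field + noise


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[VoxelGrid, RoiMask]], list[SubjectRecord]]:
    """Generate ``2 * n_per_class`` phantom subjects with subject records.

    Class 0 subjects are labelled controls, class 1 patients; dataset ids
    alternate 1/2 within each class (emulating a two-scanner design).
    Patients receive PANSS baseline/discharge totals drawn per the spec's
    responder fraction. Fully reproducible from the spec's seed.
    """
    images: list[tuple[VoxelGrid, RoiMask]] = []
    records: list[SubjectRecord] = []
    n = spec.n_per_class
    panss = generate_panss(spec, n)
    for i in range(2 * n):
        cls = i // n
        rng = _subject_rng(spec, 1, i)
        mask = _make_mask(spec, rng)
        vol = _make_volume(spec, rng, cls)
        images.append((VoxelGrid(vol, spec.spacing_mm), RoiMask(mask)))
        if cls == 1:
            b, d = panss[i - n]
            rec = SubjectRecord(
                subject_id=f"sub-{i:04d}", class_label="patient",
                dataset_id=1 + (i % 2), panss_baseline_total=b,
                panss_discharge_total=d,
            )
        else:
            rec = SubjectRecord(
                subject_id=f"sub-{i:04d}", class_label="control",
                dataset_id=1 + (i % 2),
            )
        records.append(rec)
    return images, records


def generate_panss(
    spec: CohortSpec, n_patients: int
) -> list[tuple[int, int]]:
    """Draw (baseline, discharge) PANSS totals for ``n_patients`` patients.

    Baselines are normal draws truncated at the 60-point inclusion floor.
    Each patient is a responder with probability ``responder_fraction``;
    the percentage reduction relative to the 30-point scale floor is drawn
    from a component on the matching side of the 30% threshold (responders
    ~ N(51, 16) truncated to [30, 95], non-responders ~ N(16, 11) truncated
    to [0, 30)), so the realized responder fraction converges to the
    configured one. All totals stay at or above the 30-point floor.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    mu, sd = spec.panss_baseline_mean_sd
    rng = _subject_rng(spec, 2, 0)
    out: list[tuple[int, int]] = []
    for _ in range(n_patients):
        baseline = 0.0
        while baseline < 60.0:
            baseline = rng.normal(mu, sd)
        baseline = int(round(baseline))
        is_resp = rng.random() < spec.responder_fraction
        while True:
            if is_resp:
                pct = rng.normal(51.0, 16.0)
                if 30.0 <= pct <= 95.0:
                    break
            else:
                pct = rng.normal(16.0, 11.0)
                if 0.0 <= pct < 30.0:
                    break
        discharge = int(round(baseline - pct / 100.0 * (baseline - 30)))
        discharge = max(discharge, 30)
        # integer rounding can flip the label right at the 30% boundary;
        # nudge discharge one point to keep the drawn label
        realized = (baseline - discharge) / (baseline - 30) * 100.0
        if is_resp and realized < 30.0:
            discharge -= 1
        elif not is_resp and realized >= 30.0:
            discharge += 1
        out.append((baseline, max(discharge, 30)))
    return out


def null_spec(spec: CohortSpec, seed: int | None = None) -> CohortSpec:
    """The same study conditions with both class effects removed."""
    return replace(
        spec,
        texture_effect=0.0,
        intensity_effect=0.0,
        seed=spec.seed if seed is None else seed,
    )
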