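"""Radiomics feature extraction from a 3D scalar volume and an aligned ROI mask.

Four feature families are computed, mirroring the classical radiomics
catalogue used in structural-MRI studies of deep gray-matter structures:

* 14 first-order intensity statistics from the in-ROI histogram;
* 8 shape descriptors of the mask geometry;
* texture features from gray level co-occurrence (GLCM) and gray level
  run-length (GLRLM) matrices, built per direction over the 13 unique axes
  of the 26-neighborhood;
* all intensity/texture features repeated on the 8 subbands of a
  single-level separable 3D wavelet decomposition (plus the original image),
  giving 9 channels named ``W1`` (original) through ``W9`` (HHH).

Feature names follow ``W<k>.<family>.<feature>[_<direction>|_mean]`` with the
channel→subband mapping recorded in the run manifest; ``shape.*`` features are
computed once per subject on the mask alone. Texture formulas follow the
image biomarker standardization initiative (IBSI) definitions.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.spatial.distance import pdist

from .errors import DecompositionError, DegenerateRoiError, ResamplingError

__all__ = [
    "VoxelGrid",
    "RoiMask",
    "DiscretizedRoi",
    "DirectionOffset",
    "DIRECTIONS",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "WaveletStack",
    "FeatureConfig",
    "resample_mean_pool",
    "discretize",
    "first_order_features",
    "shape_features",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "wavelet_decompose",
    "extract_all",
    "catalog_size",
    "run_manifest",
    "paper_style_name",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar lattice with physical voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three positive reals")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing_mm", sp)


@dataclass(frozen=True)
class RoiMask:
    """Boolean region membership on the same lattice as its VoxelGrid."""

    membership: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.membership, dtype=bool)
        if m.ndim != 3:
            raise ValueError("membership must be a 3D boolean array")
        object.__setattr__(self, "membership", m)

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer gray levels 1..G on in-mask voxels; 0 marks out-of-mask."""

    levels: np.ndarray
    n_levels: int


@dataclass(frozen=True)
class DirectionOffset:
    """One of the 13 unique axes of the 26-neighborhood.

    Opposite vectors are identified; the canonical representative has its
    first nonzero component positive. ``index`` runs 1..13 in the fixed
    order of :data:`DIRECTIONS`.
    """

    delta: tuple[int, int, int]
    index: int

    def __post_init__(self):
        d = self.delta
        if d == (0, 0, 0) or any(abs(x) > 1 for x in d):
            raise ValueError("delta must be a nonzero vector in {-1,0,1}^3")
        first = next(x for x in d if x != 0)
        if first <= 0:
            raise ValueError("canonical representative has first nonzero > 0")


DIRECTIONS: tuple[DirectionOffset, ...] = tuple(
    DirectionOffset(d, i + 1)
    for i, d in enumerate(
        [
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
            (0, 1, 1), (0, 1, -1),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
        ]
    )
)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric GLCM for one direction; ``empty`` if no valid voxel pair."""

    counts: np.ndarray          # G x G, symmetric accumulation
    offset: DirectionOffset
    empty: bool = False

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total


@dataclass(frozen=True)
class RunLengthMatrix:
    """GLRLM: counts[g-1, l-1] = number of maximal runs of level g, length l."""

    counts: np.ndarray          # G x Lmax
    offset: DirectionOffset


@dataclass(frozen=True)
class WaveletStack:
    """Original image plus the 8 single-level 3D subbands, all full-size.

    Channel 1 is the untouched input; channels 2..9 are the LLL..HHH
    subbands, each reconstructed back to the original lattice so that the
    stack shares one shape and spacing (and the 8 subbands sum to the
    original by linearity of the inverse transform).
    """

    channels: tuple[VoxelGrid, ...]
    subband_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.channels) != 9:
            raise ValueError("a WaveletStack has exactly 9 channels")


SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FIRST_ORDER_NAMES = (
    "energy", "entropy", "kurtosis", "maximum", "mean", "mad", "median",
    "minimum", "range", "rms", "skewness", "std", "uniformity", "variance",
)

SHAPE_NAMES = (
    "compactness1", "compactness2", "max_diameter_3d",
    "spherical_disproportion", "sphericity", "surface_area",
    "surface_to_volume_ratio", "volume",
)

GLCM_FEATURES_DEFAULT = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "contrast",
    "correlation", "diff_entropy", "diff_variance", "dissimilarity",
    "energy", "entropy", "homogeneity1", "homogeneity2", "imc1", "imc2",
    "max_prob", "sum_average", "sum_entropy", "sum_variance", "variance",
)

GLRLM_FEATURES_DEFAULT = (
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction configuration.

    n_levels
        Gray levels G for fixed-bin-count discretization (equal-width bins
        over the in-ROI [min, max]); keeps texture matrices bounded and all
        discretization-based features invariant to intensity shifts.
    wavelet
        PyWavelets family for the single-level 3D decomposition.
    target_spacing_mm
        If set, block mean-pool the volume (majority-vote the mask) to this
        spacing before extraction; must be an integer multiple of the input
        spacing per axis — no interpolation kernel is ever applied.
    channels
        Subset of 1..9 to extract intensity/texture features from (1 is the
        original image); shape features are always computed once on the mask.
    """

    n_levels: int = 32
    wavelet: str = "coif1"
    target_spacing_mm: tuple[float, float, float] | None = None
    glcm_features: tuple[str, ...] = GLCM_FEATURES_DEFAULT
    glrlm_features: tuple[str, ...] = GLRLM_FEATURES_DEFAULT
    channels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if any(c < 1 or c > 9 for c in self.channels) or not self.channels:
            raise ValueError("channels must be a nonempty subset of 1..9")


# --------------------------------------------------------------------------
# resampling and discretization
# --------------------------------------------------------------------------

def resample_mean_pool(
    grid: VoxelGrid, mask: RoiMask, target_spacing_mm
) -> tuple[VoxelGrid, RoiMask]:
    """Downsample by block mean-pooling; mask by >=50% majority vote.

    The target spacing must be an integer multiple of the input spacing on
    every axis (no interpolation). Trailing partial blocks use only the
    source voxels that exist.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    factors = []
    for t, s in zip(target, grid.spacing_mm):
        r = t / s
        if abs(r - round(r)) > 1e-6 or round(r) < 1:
            raise ResamplingError(
                f"target spacing {t} is not an integer multiple of {s}"
            )
        factors.append(int(round(r)))
    if all(f == 1 for f in factors):
        return VoxelGrid(grid.values.copy(), grid.spacing_mm), RoiMask(
            mask.membership.copy()
        )

    vals, msk = grid.values, mask.membership
    shape = vals.shape
    padded = [int(math.ceil(n / f)) * f for n, f in zip(shape, factors)]
    pad = [(0, p - n) for p, n in zip(padded, shape)]
    v = np.pad(vals, pad)
    present = np.pad(np.ones(shape), pad)
    m = np.pad(msk.astype(float), pad)

    def block_sum(a):
        (fz, fy, fx) = factors
        nz, ny, nx = (p // f for p, f in zip(padded, factors))
        return a.reshape(nz, fz, ny, fy, nx, fx).sum(axis=(1, 3, 5))

    cnt = block_sum(present)
    pooled = block_sum(v) / cnt
    pooled_mask = block_sum(m) / cnt >= 0.5
    if not pooled_mask.any():
        raise DegenerateRoiError("pooled mask is empty")
    return VoxelGrid(pooled, target), RoiMask(pooled_mask)


def discretize(grid: VoxelGrid, mask: RoiMask, n_levels: int) -> DiscretizedRoi:
    """Equal-width fixed-bin-count discretization over the in-ROI range.

    The maximum intensity maps to level G; a constant ROI maps entirely to
    level 1. Out-of-mask voxels carry the sentinel 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    m = mask.membership
    if not m.any():
        raise DegenerateRoiError("empty mask")
    vals = grid.values[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(grid.values.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
    else:
        lv = np.floor((grid.values[m] - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
        levels[m] = lv
    return DiscretizedRoi(levels, n_levels)


# --------------------------------------------------------------------------
# first-order and shape families
# --------------------------------------------------------------------------

def first_order_features(
    grid: VoxelGrid, mask: RoiMask, n_levels: int = 32
) -> "OrderedDict[str, float]":
    """The 14 first-order intensity statistics of the in-ROI histogram.

    Conventions: energy = Σx²; RMS = √(Σx²/n); population variance;
    MAD = mean |x − mean|; entropy (bits) and uniformity on the fixed-bin
    discretized histogram; Pearson kurtosis (normal → 3); skewness and
    kurtosis of a constant ROI are reported as 0.
    """
    m = mask.membership
    if not m.any():
        raise DegenerateRoiError("empty mask")
    x = grid.values[m].astype(float)
    n = x.size
    mean = x.mean()
    var = float(((x - mean) ** 2).mean())
    std = math.sqrt(var)
    if var > 0:
        skew = float(((x - mean) ** 3).mean()) / std**3
        kurt = float(((x - mean) ** 4).mean()) / var**2
    else:
        skew = 0.0
        kurt = 0.0
    disc = discretize(grid, mask, n_levels)
    hist = np.bincount(disc.levels[m], minlength=n_levels + 1)[1:]
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    out = OrderedDict()
    out["energy"] = float((x**2).sum())
    out["entropy"] = entropy
    out["kurtosis"] = kurt
    out["maximum"] = float(x.max())
    out["mean"] = float(mean)
    out["mad"] = float(np.abs(x - mean).mean())
    out["median"] = float(np.median(x))
    out["minimum"] = float(x.min())
    out["range"] = float(x.max() - x.min())
    out["rms"] = math.sqrt(float((x**2).mean()))
    out["skewness"] = skew
    out["std"] = std
    out["uniformity"] = uniformity
    out["variance"] = var
    return out


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of mask faces exposed to background (boundary mesh)."""
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for ax in range(3):
        padded = np.pad(mask, [(1, 1) if k == ax else (0, 0) for k in range(3)])
        transitions = np.abs(np.diff(padded.astype(np.int8), axis=ax)).sum()
        area += float(transitions) * face[ax]
    return area


def _max_diameter(mask: np.ndarray, spacing) -> float:
    coords = np.argwhere(mask)
    if len(coords) == 1:
        return 0.0
    # only surface voxels can realize the maximum distance
    inner = np.ones_like(mask)
    for ax in range(3):
        padded = np.pad(mask, [(1, 1) if k == ax else (0, 0) for k in range(3)])
        lo = padded[tuple(slice(0, -2) if k == ax else slice(None) for k in range(3))]
        hi = padded[tuple(slice(2, None) if k == ax else slice(None) for k in range(3))]
        inner &= lo & hi
    surf = np.argwhere(mask & ~inner)
    pts = surf * np.asarray(spacing)
    if len(pts) > 800:
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def shape_features(mask: RoiMask, spacing_mm) -> "OrderedDict[str, float]":
    """The 8 shape descriptors of the mask geometry.

    volume V = voxel count × voxel volume; surface area A by exposed-face
    counting; sphericity = π^{1/3}(6V)^{2/3}/A; compactness1 = V/(√π·A^{3/2});
    compactness2 = 36πV²/A³; spherical disproportion = A/(4πR²) with
    R = (3V/4π)^{1/3}; maximum 3D diameter = largest center-to-center
    distance between in-mask voxels.
    """
    m = mask.membership
    if not m.any():
        raise DegenerateRoiError("empty mask")
    sp = tuple(float(s) for s in spacing_mm)
    vox_vol = sp[0] * sp[1] * sp[2]
    v = m.sum() * vox_vol
    a = _surface_area(m, sp)
    r = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
    out = OrderedDict()
    out["compactness1"] = v / (math.sqrt(math.pi) * a**1.5)
    out["compactness2"] = 36.0 * math.pi * v**2 / a**3
    out["max_diameter_3d"] = _max_diameter(m, sp)
    out["spherical_disproportion"] = a / (4.0 * math.pi * r**2)
    out["sphericity"] = math.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a
    out["surface_area"] = a
    out["surface_to_volume_ratio"] = a / v
    out["volume"] = v
    return out


# --------------------------------------------------------------------------
# texture matrices
# --------------------------------------------------------------------------

def _offset_slices(shape, delta):
    """Slices (src, dst) such that dst voxels are src voxels displaced by delta."""
    src, dst = [], []
    for n, d in zip(shape, delta):
        src.append(slice(max(0, -d), n - max(0, d)))
        dst.append(slice(max(0, d), n + min(0, d)))
    return tuple(src), tuple(dst)


def glcm(disc: DiscretizedRoi, offset: DirectionOffset) -> CooccurrenceMatrix:
    """Gray level co-occurrence matrix for one of the 13 direction axes.

    Each in-mask voxel pair separated by the offset is accumulated in both
    orders, so the matrix is symmetric by construction. If no valid pair
    exists the matrix is flagged empty and downstream features take their
    documented degenerate values.
    """
    g = disc.n_levels
    src, dst = _offset_slices(disc.levels.shape, offset.delta)
    a = disc.levels[src].ravel()
    b = disc.levels[dst].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    if a.size == 0:
        return CooccurrenceMatrix(np.zeros((g, g)), offset, empty=True)
    counts = np.bincount(a * g + b, minlength=g * g).reshape(g, g).astype(float)
    counts = counts + counts.T
    return CooccurrenceMatrix(counts, offset, empty=False)


def glcm_features(
    m: CooccurrenceMatrix, which: tuple[str, ...] = GLCM_FEATURES_DEFAULT
) -> "OrderedDict[str, float]":
    """IBSI-style scalar features of a normalized co-occurrence matrix.

    Degenerate conventions (flagged-empty matrix, or a constant ROI whose
    marginal variance is zero): correlation 1, every entropy 0, energy and
    maximum probability 1, homogeneities 1, IMC1/IMC2 0, moment-type
    features 0 — all finite and documented.
    """
    g = m.counts.shape[0]
    if m.empty:
        degenerate = {
            "correlation": 1.0, "energy": 1.0, "max_prob": 1.0,
            "homogeneity1": 1.0, "homogeneity2": 1.0,
        }
        return OrderedDict((f, degenerate.get(f, 0.0)) for f in which)

    p = m.probabilities
    i = np.arange(1, g + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)                      # symmetric: px == py
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())

    # diagonal (difference) and cross-diagonal (sum) probability distributions
    k_diff = np.arange(g, dtype=float)      # |i-j| = 0..G-1
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * g + 1, dtype=float)
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = ent(p)
    hx = ent(px)
    # joint entropies against the product of the marginals
    outer = np.outer(px, px)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log2(outer[nz2])).sum())

    vals: dict[str, float] = {}
    vals["autocorrelation"] = float((ii * jj * p).sum())
    vals["cluster_prominence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())
    vals["cluster_shade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    vals["contrast"] = float(((ii - jj) ** 2 * p).sum())
    vals["correlation"] = (
        (vals["autocorrelation"] - mu * mu) / sig2 if sig2 > 0 else 1.0
    )
    vals["diff_entropy"] = ent(p_diff)
    mu_d = float((k_diff * p_diff).sum())
    vals["diff_variance"] = float(((k_diff - mu_d) ** 2 * p_diff).sum())
    vals["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    vals["energy"] = float((p**2).sum())
    vals["entropy"] = hxy
    vals["homogeneity1"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    vals["homogeneity2"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    vals["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = -2.0 * (hxy2 - hxy)
    vals["imc2"] = math.sqrt(1.0 - math.exp(arg)) if arg < 0 else 0.0
    vals["max_prob"] = float(p.max())
    sa = float((k_sum * p_sum).sum())
    vals["sum_average"] = sa
    vals["sum_entropy"] = ent(p_sum)
    vals["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    vals["variance"] = float(((ii - mu) ** 2 * p).sum())
    return OrderedDict((f, vals[f]) for f in which)


def _pull(a: np.ndarray, delta, fill):
    """out[v] = a[v + delta] where in bounds, else fill."""
    out = np.full_like(a, fill)
    dst, src = _offset_slices(a.shape, delta)
    out[dst] = a[src]
    return out


def glrlm(disc: DiscretizedRoi, offset: DirectionOffset) -> RunLengthMatrix:
    """Gray level run-length matrix along one direction axis.

    A run is a maximal streak of in-mask voxels sharing one gray level along
    a lattice line in the offset direction; runs end at mask boundaries, so
    the lines partition the ROI and Σ l·counts equals the ROI voxel count.
    """
    lv = disc.levels
    inmask = lv > 0
    if not inmask.any():
        raise DegenerateRoiError("empty mask")
    d = offset.delta
    nxt_lv = _pull(lv, d, fill=-1)
    same_next = inmask & (nxt_lv == lv)

    # run length seen from each voxel toward +delta, by backward propagation
    runlen = inmask.astype(np.int64)
    max_steps = int(sum(abs(x) * (n - 1) for x, n in zip(d, lv.shape))) + 1
    for _ in range(max_steps):
        new = np.where(same_next, 1 + _pull(runlen, d, fill=0), inmask.astype(np.int64))
        if np.array_equal(new, runlen):
            break
        runlen = new

    prev_same = _pull(same_next, tuple(-x for x in d), fill=False)
    starts = inmask & ~prev_same
    g_idx = lv[starts] - 1
    l_idx = runlen[starts] - 1
    lmax = int(l_idx.max()) + 1
    counts = np.zeros((disc.n_levels, lmax), dtype=np.int64)
    np.add.at(counts, (g_idx, l_idx), 1)
    return RunLengthMatrix(counts, offset)


def glrlm_features(
    m: RunLengthMatrix, which: tuple[str, ...] = GLRLM_FEATURES_DEFAULT
) -> "OrderedDict[str, float]":
    """IBSI-style scalar features of a run-length matrix."""
    r = m.counts.astype(float)
    nr = r.sum()
    if nr == 0:
        raise DegenerateRoiError("run-length matrix holds no runs")
    g = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    np_vox = float((l * r).sum())
    vals: dict[str, float] = {}
    vals["sre"] = float((r / l**2).sum()) / nr
    vals["lre"] = float((r * l**2).sum()) / nr
    vals["gln"] = float((r.sum(axis=1) ** 2).sum()) / nr
    vals["rln"] = float((r.sum(axis=0) ** 2).sum()) / nr
    vals["rp"] = nr / np_vox
    vals["lglre"] = float((r / g**2).sum()) / nr
    vals["hglre"] = float((r * g**2).sum()) / nr
    vals["srlgle"] = float((r / (g**2 * l**2)).sum()) / nr
    vals["srhgle"] = float((r * g**2 / l**2).sum()) / nr
    vals["lrlgle"] = float((r * l**2 / g**2).sum()) / nr
    vals["lrhgle"] = float((r * g**2 * l**2).sum()) / nr
    return OrderedDict((f, vals[f]) for f in which)


# --------------------------------------------------------------------------
# wavelet channels
# --------------------------------------------------------------------------

def wavelet_decompose(grid: VoxelGrid, wavelet: str = "coif1") -> WaveletStack:
    """Single-level separable 3D decomposition into 8 full-size subbands.

    Each subband is reconstructed alone back to the original lattice
    (periodized transform), so all 9 channels share the input shape and the
    8 subbands sum to the original image. For an orthogonal filter the
    subband energies sum to the input energy (exact on even-sized grids).
    """
    w = pywt.Wavelet(wavelet)
    x = grid.values
    if min(x.shape) < w.dec_len:
        raise DecompositionError(
            f"grid shape {x.shape} smaller than filter length {w.dec_len}"
        )
    coeffs = pywt.dwtn(x, w, mode="periodization")
    channels = [VoxelGrid(x.copy(), grid.spacing_mm)]
    for label in SUBBAND_ORDER:
        key = label.replace("L", "a").replace("H", "d")
        single = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(single, w, mode="periodization")
        rec = rec[tuple(slice(0, n) for n in x.shape)]
        channels.append(VoxelGrid(rec, grid.spacing_mm))
    return WaveletStack(tuple(channels), ("original",) + SUBBAND_ORDER)


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

def extract_all(
    grid: VoxelGrid, mask: RoiMask, config: FeatureConfig = FeatureConfig()
) -> "OrderedDict[str, float]":
    """Compute the full named feature vector for one subject.

    Shape features are computed once on the mask; first-order and texture
    features are computed on every requested channel of the wavelet stack,
    texture features per direction (``_1``..``_13``) plus the
    across-direction mean (``_mean``). The name set is a pure function of
    the configuration.
    """
    if config.target_spacing_mm is not None:
        grid, mask = resample_mean_pool(grid, mask, config.target_spacing_mm)
    if mask.n_voxels < 2:
        raise DegenerateRoiError("texture extraction needs >= 2 in-mask voxels")

    out: OrderedDict[str, float] = OrderedDict()
    for name, val in shape_features(mask, grid.spacing_mm).items():
        out[f"shape.{name}"] = val

    if config.channels == (1,):
        stack_grids = {1: grid}
    else:
        stack = wavelet_decompose(grid, config.wavelet)
        stack_grids = {k: stack.channels[k - 1] for k in config.channels}

    for k in config.channels:
        ch = stack_grids[k]
        for name, val in first_order_features(ch, mask, config.n_levels).items():
            out[f"W{k}.firstorder.{name}"] = val
        disc = discretize(ch, mask, config.n_levels)
        glcm_acc = np.zeros(len(config.glcm_features))
        glrlm_acc = np.zeros(len(config.glrlm_features))
        for off in DIRECTIONS:
            cf = glcm_features(glcm(disc, off), config.glcm_features)
            for j, (name, val) in enumerate(cf.items()):
                out[f"W{k}.glcm.{name}_{off.index}"] = val
                glcm_acc[j] += val
            rf = glrlm_features(glrlm(disc, off), config.glrlm_features)
            for j, (name, val) in enumerate(rf.items()):
                out[f"W{k}.glrlm.{name}_{off.index}"] = val
                glrlm_acc[j] += val
        for j, name in enumerate(config.glcm_features):
            out[f"W{k}.glcm.{name}_mean"] = glcm_acc[j] / len(DIRECTIONS)
        for j, name in enumerate(config.glrlm_features):
            out[f"W{k}.glrlm.{name}_mean"] = glrlm_acc[j] / len(DIRECTIONS)
    return out


def catalog_size(config: FeatureConfig = FeatureConfig()) -> int:
    """Number of features produced by :func:`extract_all` under ``config``."""
    per_channel = len(FIRST_ORDER_NAMES) + 14 * (
        len(config.glcm_features) + len(config.glrlm_features)
    )
    return len(SHAPE_NAMES) + len(config.channels) * per_channel


def run_manifest(config: FeatureConfig = FeatureConfig()) -> dict:
    """Machine-readable record of the extraction configuration."""
    return {
        "n_levels": config.n_levels,
        "wavelet": config.wavelet,
        "target_spacing_mm": config.target_spacing_mm,
        "channels": list(config.channels),
        "channel_map": {"W1": "original", **{
            f"W{i + 2}": lab for i, lab in enumerate(SUBBAND_ORDER)
        }},
        "first_order": list(FIRST_ORDER_NAMES),
        "shape": list(SHAPE_NAMES),
        "glcm_features": list(config.glcm_features),
        "glrlm_features": list(config.glrlm_features),
        "directions": {d.index: list(d.delta) for d in DIRECTIONS},
        "catalog_size": catalog_size(config),
    }


# optional alias map to the abbreviated naming style common in the clinical
# radiomics literature (e.g. "W6.Co_Corr_7"); used only for cross-referencing
_PAPER_TOKENS = {
    "firstorder": {
        "energy": "Energy", "entropy": "Entropy", "kurtosis": "Kurtosis",
        "maximum": "Max", "mean": "Mean", "mad": "MAD", "median": "Mid",
        "minimum": "Min", "range": "Range", "rms": "RMS",
        "skewness": "Skewness", "std": "SD", "uniformity": "Uniformity",
        "variance": "Variance",
    },
    "shape": {
        "compactness1": "Compactness1", "compactness2": "Compactness2",
        "max_diameter_3d": "Max3Ddiam",
        "spherical_disproportion": "SphericalDisprop",
        "sphericity": "Sphericity", "surface_area": "Surface",
        "surface_to_volume_ratio": "SVR", "volume": "Volume",
    },
    "glcm": {
        "autocorrelation": "AutoCorr", "cluster_prominence": "Cluster_Prom",
        "cluster_shade": "Cluster_Shade", "contrast": "Contrast",
        "correlation": "Co_Corr", "diff_entropy": "Diff_entropy",
        "diff_variance": "Diff_var", "dissimilarity": "Dissimilarity",
        "energy": "Energy_GLCM", "entropy": "Entropy_GLCM",
        "homogeneity1": "Homo1", "homogeneity2": "Homo2", "imc1": "IMC1",
        "imc2": "IMC2", "max_prob": "Max_GLCM", "sum_average": "Sum_avg",
        "sum_entropy": "Sum_entropy", "sum_variance": "Sum_var",
        "variance": "Co_Var",
    },
    "glrlm": {f: f.upper() for f in GLRLM_FEATURES_DEFAULT},
}


def paper_style_name(canonical: str) -> str:
    """Map a canonical feature name to the abbreviated literature style.

    ``"W6.glcm.correlation_7" -> "W6.Co_Corr_7"``; shape features drop the
    channel prefix (``"shape.volume" -> "Volume"``).
    """
    if canonical.startswith("shape."):
        return _PAPER_TOKENS["shape"][canonical.split(".", 1)[1]]
    chan, family, feat = canonical.split(".")
    suffix = ""
    if family in ("glcm", "glrlm"):
        feat, _, d = feat.rpartition("_")
        suffix = f"_{d}"
    return f"{chan}.{_PAPER_TOKENS[family][feat]}{suffix}"
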