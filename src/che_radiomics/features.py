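"""Radiomic feature extraction: 423 features per ROI.

Per ROI the feature space is 14 intensity (histogram) features, 22 GLCM and
11 GLRLM texture features on the original intensities, plus the same 47
features recomputed on each of 8 undecimated wavelet subbands (LLL..HHH):
14 + 22 + 11 + 8*47 = 423.

Conventions (fixed so golden values are unambiguous):

* discretization: 32 equal-width bins over the per-ROI min-max; the maximum
  maps to the top level; a constant ROI maps to level 1 everywhere;
* texture matrices: distance 1, all 13 unique 3D lattice directions,
  per-direction feature values averaged over non-empty directions;
* GLCM is symmetrized and normalized to sum 1; pairs require both voxels
  in-mask; GLRLM runs are maximal same-level sequences broken by the mask;
* variance is the population (1/N) form; kurtosis is excess kurtosis;
  entropies use log2;
* degenerate single-level matrices: correlation, IMC1, IMC2 defined 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .imaging_io import ImageVolume, ROIMask, ROIVoxels, ValidationError, apply_mask

N_BINS_DEFAULT = 32

#: The 13 unique 3D lattice offsets (half of the 26-neighborhood).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: Wavelet subband order; L = low-pass, H = high-pass, letters follow axes 0,1,2.
SUBBANDS: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

INTENSITY_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
    "StandardDeviation", "MeanAbsoluteDeviation", "RootMeanSquare", "Energy",
    "Skewness", "Kurtosis", "Entropy", "Uniformity",
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Dissimilarity", "JointEnergy", "JointEntropy",
    "InverseDifferenceMoment", "InverseDifferenceMomentNormalized",
    "InverseDifference", "InverseDifferenceNormalized", "InverseVariance",
    "InformationalMeasureOfCorrelation1", "InformationalMeasureOfCorrelation2",
    "MaximumProbability", "SumAverage", "SumEntropy",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonuniformity",
    "RunLengthNonuniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

FEATURES_PER_ROI = len(INTENSITY_NAMES) + len(GLCM_NAMES) + len(GLRLM_NAMES)  # 47
TOTAL_PER_ROI = FEATURES_PER_ROI * (1 + len(SUBBANDS))  # 423


@dataclass
class DiscretizedROI:
    """Integer gray levels 1..n_bins inside the mask (0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray


@dataclass
class TextureMatrix:
    kind: str  # "GLCM" | "GLRLM"
    matrix: np.ndarray
    direction: tuple[int, int, int]
    normalized: bool
    empty: bool = False


def discretize(roi: ROIVoxels, n_bins: int = N_BINS_DEFAULT) -> DiscretizedROI:
    """Equal-width binning of in-mask intensities into levels 1..n_bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = roi.values
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(roi.grid.shape, dtype=np.int32)
    if hi == lo:  # constant ROI: single level by convention
        levels[roi.mask] = 1
        edges = np.array([lo, lo + 1.0])
    else:
        width = (hi - lo) / n_bins
        lv = np.floor((roi.grid - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[roi.mask] = lv[roi.mask]
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedROI(levels=levels, mask=roi.mask.copy(), n_bins=n_bins,
                          bin_edges=edges)


# ---------------------------------------------------------------------------
# intensity (histogram) features
# ---------------------------------------------------------------------------

def intensity_features(roi: ROIVoxels, n_bins: int = N_BINS_DEFAULT) -> dict[str, float]:
    """The 14 first-order statistics of the in-mask intensity histogram."""
    x = np.asarray(roi.values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute intensity features of an empty ROI")
    n = x.size
    mean = x.mean()
    if np.ptp(x) == 0:  # exactly constant: moments defined 0 by convention
        var = 0.0
        sd = skew = kurt = 0.0
    else:
        var = x.var()  # population form
        sd = np.sqrt(var)
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4) - 3.0)
    # histogram over n_bins equal-width bins spanning min..max
    if x.max() > x.min():
        counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        counts = np.array([n])
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    return {
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(var),
        "StandardDeviation": float(sd),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RootMeanSquare": float(np.sqrt(np.mean(x ** 2))),
        "Energy": float(np.sum(x ** 2)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": entropy,
        "Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Return (a, b) views such that b is arr displaced by +d relative to a."""
    sl_a, sl_b = [], []
    for ax, step in enumerate(d):
        n = arr.shape[ax]
        if step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        elif step < 0:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
        else:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm(disc: DiscretizedROI, direction: tuple[int, int, int],
         distance: int = 1) -> TextureMatrix:
    """Symmetric, normalized co-occurrence matrix for one lattice offset.

    Only voxel pairs with both ends in-mask are counted; each unordered pair
    contributes to (i, j) and (j, i).
    """
    d = tuple(int(c) * distance for c in direction)
    lv_a, lv_b = _shifted_views(disc.levels, d)
    valid = (lv_a > 0) & (lv_b > 0)
    nb = disc.n_bins
    mat = np.zeros((nb, nb), dtype=float)
    if valid.any():
        i = lv_a[valid].ravel() - 1
        j = lv_b[valid].ravel() - 1
        np.add.at(mat, (i, j), 1.0)
        mat = mat + mat.T  # symmetrize: count each ordered pair both ways
        mat /= mat.sum()
        return TextureMatrix("GLCM", mat, direction, normalized=True)
    return TextureMatrix("GLCM", mat, direction, normalized=False, empty=True)


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 22 GLCM statistics of one normalized matrix (IBSI definitions)."""
    nb = p.shape[0]
    i = np.arange(1, nb + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(nb)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * nb + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    diff_avg = float((k_diff * p_diff).sum())
    hxy = ent(p)
    hx = ent(px)
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = ent(pxpy)

    # symmetric matrix: hx == hy, so max(HX, HY) == hx
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    corr = float((((ii - mu) * (jj - mu) * p).sum()) / sig2) if sig2 > 0 else 0.0

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off].astype(float) ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "InverseDifferenceMoment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "InverseDifferenceMomentNormalized":
            float((p / (1.0 + ((ii - jj) / nb) ** 2)).sum()),
        "InverseDifference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "InverseDifferenceNormalized":
            float((p / (1.0 + np.abs(ii - jj) / nb)).sum()),
        "InverseVariance": inv_var,
        "InformationalMeasureOfCorrelation1": float(imc1),
        "InformationalMeasureOfCorrelation2": imc2,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
    }


def glcm_features(disc: DiscretizedROI,
                  directions=DIRECTIONS_13, distance: int = 1) -> dict[str, float]:
    """Per-direction GLCM statistics averaged over non-empty directions."""
    per_dir = []
    for d in directions:
        m = glcm(disc, d, distance)
        if not m.empty:
            per_dir.append(_glcm_features_single(m.matrix))
    if not per_dir:
        raise ValidationError("no valid voxel pair in any GLCM direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm(disc: DiscretizedROI, direction: tuple[int, int, int]) -> TextureMatrix:
    """Run-length matrix along one lattice direction.

    A run is a maximal sequence of equal-level in-mask voxels along the
    direction; out-of-mask voxels break runs.  matrix[g-1, l-1] counts runs
    of gray level g with length l.
    """
    max_len = min(disc.levels.shape[ax]
                  for ax in range(3) if direction[ax] != 0)
    return _glrlm_propagate(disc, direction, max_len)


def _slices_for(shape, d):
    sl_a, sl_b = [], []
    for ax, step in enumerate(d):
        n = shape[ax]
        if step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        elif step < 0:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
        else:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
    return tuple(sl_a), tuple(sl_b)


def _glrlm_propagate(disc: DiscretizedROI, direction: tuple[int, int, int],
                     max_len: int) -> TextureMatrix:
    """Run-length counting by frontier propagation along the direction.

    Each run is owned by its start voxel (in-mask, no same-level in-mask
    predecessor).  A frontier mask is advanced one lattice step at a time,
    carrying the flat index of the owning start so exact lengths accumulate
    without per-voxel Python loops.
    """
    lv = disc.levels
    shape = lv.shape
    in_mask = lv > 0

    sl_a, sl_b = _slices_for(shape, direction)
    cont = np.zeros(shape, dtype=bool)  # cont[v]: run continues from v to v+d
    cont[sl_a] = (lv[sl_a] > 0) & (lv[sl_b] > 0) & (lv[sl_a] == lv[sl_b])

    prev = np.zeros(shape, dtype=bool)  # prev[v]: v extends the run from v-d
    prev[sl_b] = cont[sl_a]
    start = in_mask & ~prev

    nb = disc.n_bins
    mat = np.zeros((nb, max_len), dtype=float)
    if not start.any():
        return TextureMatrix("GLRLM", mat, direction, normalized=False, empty=True)

    frontier = start.copy()
    lengths = np.zeros(shape, dtype=np.int64)
    lengths[start] = 1
    start_of = np.full(shape, -1, dtype=np.int64)
    flat = np.arange(lv.size).reshape(shape)
    start_of[start] = flat[start]

    for _ in range(max_len - 1):
        grow = frontier[sl_a] & cont[sl_a]
        if not grow.any():
            break
        nxt = np.zeros(shape, dtype=bool)
        carried = np.full(shape, -1, dtype=np.int64)
        nxt[sl_b] = grow
        carried[sl_b] = np.where(grow, start_of[sl_a], -1)
        np.add.at(lengths.ravel(), carried[nxt], 1)
        frontier = nxt
        start_of = carried

    np.add.at(mat, (lv[start] - 1, lengths[start] - 1), 1.0)
    return TextureMatrix("GLRLM", mat, direction, normalized=False)


def glrlm_features(disc: DiscretizedROI,
                   directions=DIRECTIONS_13) -> dict[str, float]:
    """Per-direction run-length statistics averaged over non-empty directions."""
    per_dir = []
    for d in directions:
        m = glrlm(disc, d)
        if m.empty:
            continue
        per_dir.append(_glrlm_features_single(m.matrix))
    if not per_dir:
        raise ValidationError("no valid run in any GLRLM direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def _glrlm_features_single(r: np.ndarray) -> dict[str, float]:
    nb, lmax = r.shape
    g = np.arange(1, nb + 1, dtype=float)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    nr = r.sum()
    npix = (r * l).sum()  # voxels covered by runs in this direction
    rg = r.sum(axis=1)
    rl = r.sum(axis=0)
    return {
        "ShortRunEmphasis": float((r / l ** 2).sum() / nr),
        "LongRunEmphasis": float((r * l ** 2).sum() / nr),
        "GrayLevelNonuniformity": float((rg ** 2).sum() / nr),
        "RunLengthNonuniformity": float((rl ** 2).sum() / nr),
        "RunPercentage": float(nr / npix),
        "LowGrayLevelRunEmphasis": float((r / g ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((r * g ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((r / (g ** 2 * l ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((r * g ** 2 / l ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((r * l ** 2 / g ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((r * g ** 2 * l ** 2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# wavelet subbands
# ---------------------------------------------------------------------------

def wavelet_subbands(data: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """One-level undecimated (stationary) 3D wavelet transform.

    Returns the 8 subbands LLL..HHH on the original grid so the original
    mask applies unchanged.  Odd axes are padded by edge replication to even
    length for the transform and cropped back afterwards.
    """
    data = np.asarray(data, dtype=float)
    flen = len(pywt.Wavelet(wavelet).dec_lo)
    if min(data.shape) < flen:
        raise ValueError(
            f"axis length {min(data.shape)} shorter than wavelet filter ({flen})")
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="edge") if any(p[1] for p in pad) else data
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    crop = tuple(slice(0, s) for s in data.shape)
    out = {}
    for band in SUBBANDS:
        key = band.replace("L", "a").replace("H", "d")
        out[band] = coeffs[key][crop]
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _all_47(roi: ROIVoxels, n_bins: int, distance: int) -> dict[str, float]:
    disc = discretize(roi, n_bins)
    feats: dict[str, float] = {}
    for k, v in intensity_features(roi, n_bins).items():
        feats[f"intensity_{k}"] = v
    for k, v in glcm_features(disc, distance=distance).items():
        feats[f"glcm_{k}"] = v
    for k, v in glrlm_features(disc).items():
        feats[f"glrlm_{k}"] = v
    return feats


def extract_roi_features(volume: ImageVolume, mask: ROIMask,
                         n_bins: int = N_BINS_DEFAULT, distance: int = 1,
                         wavelet: str = "haar") -> dict[str, float]:
    """All 423 features for one ROI, named ``<roi>_<family>_<feature>[_<band>]``."""
    roi = apply_mask(volume, mask)
    out: dict[str, float] = {}
    for k, v in _all_47(roi, n_bins, distance).items():
        out[f"{mask.name}_{k}"] = v
    bands = wavelet_subbands(volume.data, wavelet)
    for band in SUBBANDS:
        filt = ImageVolume(bands[band], volume.spacing, volume.subject_id)
        roi_b = apply_mask(filt, mask)
        for k, v in _all_47(roi_b, n_bins, distance).items():
            out[f"{mask.name}_{k}_{band}"] = v
    if len(out) != TOTAL_PER_ROI:
        raise RuntimeError(f"expected {TOTAL_PER_ROI} features, got {len(out)}")
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValidationError(f"non-finite features for ROI '{mask.name}': {bad[:5]}")
    return out


def extract_all(volume: ImageVolume, masks: list[ROIMask],
                n_bins: int = N_BINS_DEFAULT, distance: int = 1,
                wavelet: str = "haar") -> dict[str, float]:
    """Concatenate per-ROI feature vectors for one subject (423 per ROI)."""
    out: dict[str, float] = {}
    for mask in masks:
        out.update(extract_roi_features(volume, mask, n_bins, distance, wavelet))
    return out


def extract_feature_table(images: dict, n_bins: int = N_BINS_DEFAULT,
                          distance: int = 1, wavelet: str = "haar"):
    """Subjects x features table from ``{subject: {roi: (volume, mask)}}``.

    Failing ROIs raise (a subject is flagged by the error, never silently
    dropped); column order is deterministic.
    """
    import pandas as pd

    rows = {}
    for sid, rois in images.items():
        feats: dict[str, float] = {}
        for roi, (vol, mask) in rois.items():
            try:
                feats.update(extract_roi_features(vol, mask, n_bins, distance,
                                                  wavelet))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(
                    f"subject '{sid}' ROI '{roi}' failed extraction: {exc}"
                ) from exc
        rows[sid] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table
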