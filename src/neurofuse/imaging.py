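"""Region-of-interest extraction and handcrafted texture features.

Deep imaging models consume fixed-size 3D crops of atlas-defined brain
regions; shallow baselines consume handcrafted first-order intensity
statistics and gray-level co-occurrence (GLCM) summaries of the same crops.

Crops are taken around the atlas bounding box of each region, center-cropped
or symmetrically zero-padded to the configured shape (default 22 x 23 x 18
voxels, i.e. 9108 voxels per region), with voxels outside the region label
zeroed. Intensities are min-max scaled to [0, 1] per patient *before*
cropping, which makes every downstream feature invariant to global affine
rescaling of the input volume.

GLCM conventions (configurable): co-occurrence is counted at offsets along
the three voxel axes at distances 1..5; the numeric suffix in a feature
name like ``"Mean GLCM 3 left amygdala"`` is the distance, and the
mean/median/sum summarize the contrast property over the three axis
directions. Intensities are quantized to 8 gray levels by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VolumeSet

DEFAULT_CROP_SHAPE = (22, 23, 18)
DEFAULT_DISTANCES = (1, 2, 3, 4, 5)
DEFAULT_N_LEVELS = 8


@dataclass
class ROISet:
    """Per-patient, per-region crops of a common shape.

    ``crops`` maps patient id -> array of shape (n_regions, *crop_shape);
    ``bounding_boxes`` records the atlas box each crop came from.
    """

    crops: dict[str, np.ndarray]
    region_ids: list[int]
    region_names: dict[int, str]
    crop_shape: tuple
    bounding_boxes: dict[int, tuple]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.crops)

    def stack(self, patient_ids=None) -> np.ndarray:
        """(n_patients, n_regions, *crop_shape) array in the given order."""
        ids = self.patient_ids if patient_ids is None else list(patient_ids)
        return np.stack([self.crops[p] for p in ids])


def extract_rois(vols: VolumeSet, region_ids=None, crop_shape=DEFAULT_CROP_SHAPE) -> ROISet:
    """Extract fixed-size masked crops for each requested atlas region."""
    if region_ids is None:
        region_ids = sorted(l for l in np.unique(vols.atlas) if l != 0)
    region_ids = list(region_ids)
    crop_shape = tuple(crop_shape)

    boxes = {}
    masks = {}
    for r in region_ids:
        where = np.argwhere(vols.atlas == r)
        if where.size == 0:
            raise ValueError(f"region {r} is empty in the atlas")
        lo = where.min(axis=0)
        hi = where.max(axis=0) + 1
        boxes[r] = tuple((int(a), int(b)) for a, b in zip(lo, hi))
        masks[r] = vols.atlas == r

    crops = {}
    for pid, vol in vols.volumes.items():
        vmin, vmax = vol.min(), vol.max()
        scaled = (vol - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(vol)
        patient = np.empty((len(region_ids),) + crop_shape)
        for i, r in enumerate(region_ids):
            masked = np.where(masks[r], scaled, 0.0)
            box = masked[tuple(slice(a, b) for a, b in boxes[r])]
            patient[i] = _fit_to_shape(box, crop_shape)
        crops[pid] = patient

    names = {r: vols.region_names.get(r, f"region {r}") for r in region_ids}
    return ROISet(crops=crops, region_ids=region_ids, region_names=names,
                  crop_shape=crop_shape, bounding_boxes=boxes)


def _fit_to_shape(box: np.ndarray, shape: tuple) -> np.ndarray:
    """Center-crop oversized axes, symmetrically zero-pad undersized ones."""
    out = box
    for ax in range(3):
        d, target = out.shape[ax], shape[ax]
        if d > target:
            start = (d - target) // 2
            out = np.take(out, range(start, start + target), axis=ax)
        elif d < target:
            before = (target - d) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (before, target - d - before)
            out = np.pad(out, pad)
    return out


# ---------------------------------------------------------------------------
# Handcrafted features
# ---------------------------------------------------------------------------

def quantize(crop: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize [0,1] intensities to integer gray levels 0..n_levels-1."""
    return np.minimum((np.asarray(crop) * n_levels).astype(np.int64), n_levels - 1)


def glcm(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric, normalized 3D gray-level co-occurrence matrix.

    Counts voxel pairs (v, v+offset) over the valid overlap, adds the
    transpose (symmetry), and normalizes to sum 1. An offset with no valid
    pairs yields an all-zero matrix.
    """
    levels = np.asarray(levels)
    sl_a, sl_b = [], []
    for d, size in zip(offset, levels.shape):
        if abs(d) >= size:
            return np.zeros((n_levels, n_levels))
        sl_a.append(slice(None, size - d) if d >= 0 else slice(-d, None))
        sl_b.append(slice(d, None) if d >= 0 else slice(None, size + d))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def glcm_contrast(p: np.ndarray) -> float:
    i, j = np.indices(p.shape)
    return float(np.sum(p * (i - j) ** 2))


def intensity_entropy(levels: np.ndarray, n_levels: int) -> float:
    """Shannon entropy (bits) of the quantized intensity histogram."""
    counts = np.bincount(levels.ravel(), minlength=n_levels).astype(float)
    probs = counts / counts.sum()
    nz = probs > 0
    return float(-np.sum(probs[nz] * np.log2(probs[nz])))


def handcrafted_features(
    rois: ROISet,
    distances=DEFAULT_DISTANCES,
    n_levels: int = DEFAULT_N_LEVELS,
) -> pd.DataFrame:
    """First-order and GLCM features per region, one row per patient.

    Columns follow the naming scheme ``"<Summary> GLCM <distance> <region>"``
    (summaries of the contrast property over the three axis offsets) and
    ``"<Statistic> intensity <region>"``.
    """
    rows = {}
    columns = None
    for pid in rois.patient_ids:
        feats = {}
        for i, r in enumerate(rois.region_ids):
            crop = rois.crops[pid][i]
            region = rois.region_names[r]
            levels = quantize(crop, n_levels)
            feats[f"Mean intensity {region}"] = float(crop.mean())
            feats[f"Median intensity {region}"] = float(np.median(crop))
            feats[f"Entropy intensity {region}"] = intensity_entropy(levels, n_levels)
            for d in distances:
                vals = [
                    glcm_contrast(glcm(levels, off, n_levels))
                    for off in ((d, 0, 0), (0, d, 0), (0, 0, d))
                ]
                feats[f"Mean GLCM {d} {region}"] = float(np.mean(vals))
                feats[f"Median GLCM {d} {region}"] = float(np.median(vals))
                feats[f"Sum GLCM {d} {region}"] = float(np.sum(vals))
        if columns is None:
            columns = list(feats)
        rows[pid] = feats
    out = pd.DataFrame.from_dict(rows, orient="index")[columns]
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite handcrafted feature value")
    return out
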