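"""Brain extraction, tissue segmentation and the supraventricular WM ROI.

These operations stand in for the external skull-stripping and tissue
segmentation tools of a clinical pipeline. They are intensity-based and
deterministic: Otsu thresholding plus largest-component/hole-filling for
the brain, and a quantile-seeded 1-D k-means (k = 3) on the T2 histogram
for CSF (bright) / grey matter (mid) / white matter (dark).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import MaskingError
from .volume import ImageVolume, ROIMask, TissueMasks

__all__ = ["extract_brain", "segment_tissues", "supraventricular_roi", "volumetrics"]


def _bbox(mask: np.ndarray, margin: int = 0) -> tuple[slice, ...]:
    """Bounding-box slices of a 3-D boolean mask, padded by ``margin``."""
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        prof = mask.any(axis=other)
        idx = np.flatnonzero(prof)
        slices.append(
            slice(max(int(idx[0]) - margin, 0), min(int(idx[-1]) + 1 + margin, mask.shape[axis]))
        )
    return tuple(slices)


def _fill_holes_per_slice(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if sl.any():
            out[:, :, z] = ndi.binary_fill_holes(sl)
    return out


def extract_brain(volume: ImageVolume) -> np.ndarray:
    """Binary brain mask: largest supra-threshold component after hole-filling.

    The threshold is Otsu's on the intensity histogram. Holes (interior
    CSF) are filled per axial slice before the largest connected
    component is selected, so the mask covers the whole cranial content.

    Raises
    ------
    MaskingError
        If the volume is empty or has no intensity contrast (all
        background).
    """
    data = np.asarray(volume.data)
    if data.size == 0:
        raise MaskingError("cannot extract a brain mask from an empty volume")
    dmin, dmax = float(data.min()), float(data.max())
    if dmin == dmax:
        raise MaskingError("volume has no intensity contrast (all background)")
    # histogram on an in-plane 2x subsample: Otsu's threshold is a
    # histogram statistic and is insensitive to this decimation
    sample = data[::2, ::2, :] if data.shape[0] > 8 and data.shape[1] > 8 else data
    counts, edges = np.histogram(sample, bins=256, range=(dmin, dmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = threshold_otsu(hist=(counts, centers))
    supra = data > thr
    if not supra.any():
        raise MaskingError("no voxels above the Otsu threshold")
    box = _bbox(supra, margin=0)
    filled = _fill_holes_per_slice(supra[box])
    labels, n = ndi.label(filled)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        filled = labels == int(sizes.argmax())
    out = np.zeros_like(supra)
    out[box] = filled
    return out


def _histogram_kmeans3(values: np.ndarray, n_bins: int = 512, max_iter: int = 100):
    """Deterministic 3-cluster 1-D k-means on a histogram.

    Centers are seeded at 1/6, 3/6 and 5/6 of the percentile-clipped
    intensity range, so the result is reproducible without a random state
    and invariant to positive rescaling of the intensities.

    Returns the two decision boundaries (lower, upper).
    """
    lo, hi = float(values.min()), float(values.max())
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    cdf = np.cumsum(hist) / hist.sum()
    r_lo = mids[int(np.searchsorted(cdf, 0.01))]
    r_hi = mids[int(np.searchsorted(cdf, 0.99))]
    centers = r_lo + np.array([1 / 6, 3 / 6, 5 / 6]) * (r_hi - r_lo)
    if len(np.unique(centers)) < 3:
        raise MaskingError(
            "fewer than 3 distinct intensity levels in the brain; "
            "supply a label volume instead"
        )
    for _ in range(max_iter):
        bounds = 0.5 * (centers[:-1] + centers[1:])
        assign = np.digitize(mids, bounds)
        new = centers.copy()
        for k in range(3):
            w = hist[assign == k]
            if w.sum() == 0:
                raise MaskingError(
                    "intensity clustering produced an empty class; "
                    "supply a label volume instead"
                )
            new[k] = np.average(mids[assign == k], weights=w)
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    bounds = 0.5 * (centers[:-1] + centers[1:])
    return float(bounds[0]), float(bounds[1])


def segment_tissues(
    volume: ImageVolume,
    brain: np.ndarray,
    labels: np.ndarray | None = None,
    min_ventricle_mm3: float = 100.0,
) -> TissueMasks:
    """Split the brain into WM / GM / CSF and identify the ventricles.

    With T2 contrast the darkest intensity cluster is white matter, the
    middle one grey matter and the brightest CSF. Ventricles are interior
    CSF components: connected CSF regions that do not touch the brain-mask
    boundary and exceed ``min_ventricle_mm3`` (the volume floor keeps
    small CSF-bright specks, such as perivascular spaces, from being
    mistaken for ventricle). The estimated WM mask is hole-filled per
    slice (minus the ventricles) so that those same interior specks stay
    part of the white matter.

    If ``labels`` is given it is used verbatim (``source="labels"``).
    """
    if labels is not None:
        return TissueMasks.from_labels(labels)
    brain_full = np.asarray(brain, dtype=bool)
    if not brain_full.any():
        raise MaskingError("brain mask is empty")
    # all clustering/morphology happens inside the brain bounding box
    box = _bbox(brain_full, margin=1)
    data = np.asarray(volume.data)[box]
    brain = brain_full[box]
    vals = data[brain]
    b_lo, b_hi = _histogram_kmeans3(vals)

    wm_raw = brain & (data <= b_lo)
    gm_raw = brain & (data > b_lo) & (data <= b_hi)
    csf_raw = brain & (data > b_hi)

    # interior CSF components = candidate ventricles
    boundary = brain & ~ndi.binary_erosion(brain)
    csf_labels, n = ndi.label(csf_raw)
    ventricle = np.zeros_like(brain)
    if n > 0:
        sizes = np.bincount(csf_labels.ravel(), minlength=n + 1)
        touching = np.unique(csf_labels[boundary])
        voxel = float(np.prod(volume.spacing))
        good = np.zeros(n + 1, dtype=bool)
        good[1:] = sizes[1:] * voxel >= min_ventricle_mm3
        good[touching] = False
        ventricle = good[csf_labels]

    wm = _fill_holes_per_slice(wm_raw) & ~ventricle
    gm = gm_raw & ~wm
    csf = (csf_raw & ~wm) | ventricle

    out = {}
    for name, cropped in (
        ("wm", wm), ("gm", gm), ("csf", csf), ("ventricle", ventricle)
    ):
        full = np.zeros_like(brain_full)
        full[box] = cropped
        out[name] = full
    return TissueMasks(brain=brain_full, source="estimated", **out)


def supraventricular_roi(
    masks: TissueMasks,
    spacing: Sequence[float],
    min_area_mm2: float = 10.0,
) -> ROIMask:
    """White matter at and above the level of the lateral ventricle bodies.

    The ventricular level ``z_level`` is the superior-most axial slice
    whose ventricle cross-section area is at least ``min_area_mm2``; the
    ROI is every WM voxel on slices ``z >= z_level``.
    """
    if not masks.ventricle.any():
        raise MaskingError("ventricle mask is empty; cannot locate the ventricular level")
    pixel_area = float(spacing[0]) * float(spacing[1])
    areas = masks.ventricle.sum(axis=(0, 1)) * pixel_area
    qualifying = np.nonzero(areas >= min_area_mm2)[0]
    if qualifying.size == 0:
        raise MaskingError(
            f"no slice has ventricle cross-section >= {min_area_mm2} mm^2"
        )
    z_level = int(qualifying.max())
    roi = masks.wm.copy()
    roi[:, :, :z_level] = False
    return ROIMask(mask=roi, z_level=z_level)


def volumetrics(masks: TissueMasks, spacing: Sequence[float]) -> tuple[float, float]:
    """(brain volume, WM volume) in mm^3: voxel counts times voxel volume."""
    voxel = float(np.prod([float(s) for s in spacing]))
    return float(masks.brain.sum()) * voxel, float(masks.wm.sum()) * voxel
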