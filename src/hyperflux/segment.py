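"""Bright-field segmentation into cell (SC) and fibre-tissue (FT) ROIs.

The bright-field image is first flattened by a low-order polynomial
illumination fit (structure-free pixels see the illumination directly),
so absorption contrast becomes comparable across the field of view.
Cells are the darkest intensity class (3-class multi-Otsu), hole-filled,
split by a watershed on the distance transform and filtered by area and
solidity (cell blobs are compact; fibre fragments are not). Fibres are
curvilinear ridges: a multi-scale Hessian tubularity (Sato) response,
thresholded outside a safety margin around the cells (cell rims are
ridge-like and would otherwise leak in), skeletonised, length-filtered
and dilated back to ridge width. Pixels claimed by both detectors
belong to the cells, so the two masks are disjoint. Labels are ordered
row-major by centroid so outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from hyperflux.io_core import BrightField, SpectralStack


@dataclass
class LabelMask:
    """Integer ROI labels (0 = background) of one structure kind."""

    labels: np.ndarray
    kind: str  # "cell" or "fibre"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        if self.kind not in ("cell", "fibre"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    @property
    def roi_count(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def roi_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


def _relabel_by_centroid(labels: np.ndarray) -> np.ndarray:
    """Renumber ROIs 1..n in row-major centroid order (deterministic)."""
    props = measure.regionprops(labels)
    if not props:
        return labels
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels)
    for new_id, p in enumerate(order, start=1):
        out[labels == p.label] = new_id
    return out


def _empty(shape: tuple[int, int], kind: str) -> LabelMask:
    return LabelMask(labels=np.zeros(shape, dtype=np.int32), kind=kind)


def _flatten_brightfield(img: np.ndarray) -> np.ndarray:
    """Divide out the smooth illumination so contrast is comparable."""
    from hyperflux.preprocess import _fit_brightfield_field

    field = _fit_brightfield_field(img, degree=2, n_tiles=8)
    return img / np.clip(field, 1e-6, None)


def _cell_threshold(corr: np.ndarray) -> float:
    """Darkest-class upper bound: multi-Otsu when trimodal, Otsu otherwise."""
    try:
        return float(filters.threshold_multiotsu(corr, classes=3)[0])
    except ValueError:
        return float(filters.threshold_otsu(corr))


def segment_cells(
    brightfield: BrightField,
    min_area_px: int = 12,
    max_area_px: int = 2000,
    min_distance: int = 5,
    min_solidity: float = 0.8,
) -> LabelMask:
    """Detect cell blobs (darkest absorption class) in the bright-field.

    Illumination-corrected image -> darkest multi-Otsu class -> hole
    filling -> watershed split of touching blobs on the distance
    transform -> area filter [min_area_px, max_area_px] and solidity
    filter (set ``min_solidity=0`` to disable the shape criterion).
    """
    img = np.asarray(brightfield.data, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("bright-field image contains non-finite values")
    if np.ptp(img) == 0:
        return _empty(img.shape, "cell")
    corr = _flatten_brightfield(img)
    fg = corr < _cell_threshold(corr)
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return _empty(img.shape, "cell")
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels = measure.label(fg, connectivity=1)
    else:
        labels = segmentation.watershed(-dist, markers=markers, mask=fg, connectivity=1)
    out = np.zeros_like(labels)
    next_id = 1
    for p in measure.regionprops(labels):
        if min_area_px <= p.area <= max_area_px and p.solidity >= min_solidity:
            out[labels == p.label] = next_id
            next_id += 1
    return LabelMask(labels=_relabel_by_centroid(out), kind="cell")


def segment_fibres(
    brightfield: BrightField,
    min_length_px: int = 15,
    cell_mask: LabelMask | None = None,
    sigmas: tuple[float, ...] = (1.0, 1.5, 2.5),
    cell_margin: int = 4,
    dilation_radius: int = 1,
) -> LabelMask:
    """Detect curvilinear fibre ridges in the bright-field image.

    Multi-scale Sato tubularity of the illumination-corrected, inverted
    image, Otsu-thresholded; a ``cell_margin``-pixel dilation of the
    cell regions is excluded first, because cell rims produce long
    ridge-like halos. Components whose skeleton is shorter than
    ``min_length_px`` are dropped; surviving skeletons are dilated by
    ``dilation_radius`` back to ridge width. Cell pixels never appear
    in the result, so the two masks are disjoint.
    """
    img = np.asarray(brightfield.data, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("bright-field image contains non-finite values")
    if np.ptp(img) == 0:
        return _empty(img.shape, "fibre")
    corr = _flatten_brightfield(img)
    ridge = filters.sato(corr.max() - corr, sigmas=sigmas, black_ridges=False)
    if ridge.max() <= 0:
        return _empty(img.shape, "fibre")
    mask = ridge > filters.threshold_otsu(ridge)
    if cell_mask is not None and (cell_mask.labels > 0).any():
        # exclude cells and their ridge-like rims
        dark = ndimage.binary_fill_holes(corr < _cell_threshold(corr))
        excl = ndimage.binary_dilation(dark | (cell_mask.labels > 0), iterations=cell_margin)
        mask &= ~excl
    mask = morphology.remove_small_objects(mask, max_size=7)  # drop specks < 8 px
    if not mask.any():
        return _empty(img.shape, "fibre")
    skel = morphology.skeletonize(mask)
    skel_labels = measure.label(skel, connectivity=2)
    keep = np.zeros(img.shape, dtype=bool)
    for p in measure.regionprops(skel_labels):
        if p.area >= min_length_px:  # skeleton pixel count ~ curve length
            keep |= skel_labels == p.label
    if not keep.any():
        return _empty(img.shape, "fibre")
    restored = ndimage.binary_dilation(keep, structure=morphology.disk(dilation_radius))
    if cell_mask is not None:
        restored &= ~(cell_mask.labels > 0)
    labels = measure.label(restored, connectivity=2)
    return LabelMask(labels=_relabel_by_centroid(labels), kind="fibre")


def extract_roi_spectra(stack: SpectralStack, mask: LabelMask) -> dict[int, np.ndarray]:
    """Per-ROI collections of pixel spectra.

    Returns ``{roi_id: (n_pixels, n_channels) array}`` for every
    positive label.
    """
    if mask.labels.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack")
    out: dict[int, np.ndarray] = {}
    for roi_id in mask.roi_ids():
        sel = mask.labels == roi_id
        out[int(roi_id)] = stack.data[sel]
    return out
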