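"""Acquisition-artefact removal for spectral stacks.

Order contract (applied by :func:`preprocess_stack`):

1. bad-pixel detection and median repair (dead / saturated camera pixels)
2. background-fluorescence subtraction (per-channel median over the
   tissue-free lowest-intensity decile)
3. flattening of uneven illumination (smooth positive field, mean 1)
4. Poisson denoising (variance-stabilising square-root transform,
   spatial-only Gaussian smoothing, inverse transform)

Smoothing never mixes spectral channels, so unmixing is not biased by
spectral blur. All steps preserve non-negativity and stack shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from hyperflux.io_core import BrightField, SpectralStack

REASON_NONE, REASON_DEAD, REASON_SATURATED = 0, 1, 2


@dataclass
class BadPixelMask:
    """Flagged camera pixels with a per-pixel reason code."""

    mask: np.ndarray  # bool (h, w)
    reason: np.ndarray  # uint8 (h, w): 0 none, 1 dead, 2 saturated

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.mask.shape != self.reason.shape:
            raise ValueError("mask and reason shapes differ")

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


@dataclass
class IlluminationField:
    """Smooth positive per-channel illumination field, spatial mean 1.

    One spatial field is shared across channels (vignetting is an
    optical property of the light path, not of the emission filter);
    ``field`` broadcasts over the channel axis.
    """

    field: np.ndarray  # (h, w), strictly positive, mean 1

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        if (self.field <= 0).any():
            raise ValueError("illumination field must be strictly positive")
        mean = self.field.mean()
        if abs(mean - 1.0) > 1e-6:
            self.field = self.field / mean


def detect_bad_pixels(
    stack: SpectralStack, saturation_value: float, min_saturated_channels: int = 3
) -> BadPixelMask:
    """Flag dead (zero in every channel) and saturated camera pixels.

    A pixel is saturated when it reaches ``saturation_value`` in at
    least ``min_saturated_channels`` channels.
    """
    if saturation_value <= 0:
        raise ValueError("saturation_value must be positive")
    dead = (stack.data <= 0).all(axis=2)
    n_sat = (stack.data >= saturation_value).sum(axis=2)
    saturated = n_sat >= min_saturated_channels
    reason = np.zeros(stack.spatial_shape, dtype=np.uint8)
    reason[saturated] = REASON_SATURATED
    reason[dead] = REASON_DEAD
    return BadPixelMask(mask=dead | saturated, reason=reason)


def repair_bad_pixels(stack: SpectralStack, mask: BadPixelMask) -> SpectralStack:
    """Replace each flagged pixel by the median of its good neighbours.

    Per channel, the median over the un-flagged 8-neighbourhood; the
    window expands ring by ring when every neighbour is also flagged.
    """
    if mask.mask.all():
        raise ValueError("cannot repair a fully-flagged image")
    if not mask.mask.any():
        return stack.with_data(stack.data.copy())
    data = stack.data.copy()
    h, w = stack.spatial_shape
    bad = mask.mask
    ys, xs = np.nonzero(bad)
    for y, x in zip(ys, xs):
        r = 1
        while True:
            y0, y1 = max(0, y - r), min(h, y + r + 1)
            x0, x1 = max(0, x - r), min(w, x + r + 1)
            window_good = ~bad[y0:y1, x0:x1]
            window_good[y - y0, x - x0] = False
            if window_good.any():
                data[y, x, :] = np.median(stack.data[y0:y1, x0:x1][window_good], axis=0)
                break
            r += 1
            if r > max(h, w):  # pragma: no cover - guarded by the all() check
                raise RuntimeError("no un-flagged neighbour found")
    return stack.with_data(data)


def estimate_background(
    stack: SpectralStack,
    brightfield: BrightField | None = None,
    tissue_free_quantile: float = 0.10,
) -> np.ndarray:
    """Per-channel background spectrum from tissue-free pixels.

    Tissue-free pixels are the lowest-``quantile`` of total intensity;
    the background is their per-channel median. Returns zeros (with a
    warning) when no tissue-free region is distinguishable.
    """
    total = stack.data.sum(axis=2)
    thresh = np.quantile(total, tissue_free_quantile)
    free = total <= thresh
    if free.sum() < max(1, int(0.01 * total.size)):
        warnings.warn("no tissue-free region found; background set to zero", stacklevel=2)
        return np.zeros(stack.n_channels)
    return np.median(stack.data[free], axis=0)


def subtract_background(stack: SpectralStack, background: np.ndarray) -> SpectralStack:
    """Subtract a background (spectrum or full field), clamping at zero."""
    background = np.asarray(background)
    if background.ndim == 1:
        background = background[None, None, :]
    return stack.with_data(np.clip(stack.data - background, 0.0, None))


def estimate_background_field(
    stack: SpectralStack, smooth_sigma_frac: float = 0.12
) -> np.ndarray:
    """Spatially varying background: smooth amplitude field x spectrum.

    Tissue-free pixels (below the Otsu level of total intensity) define
    the background's spectral shape (their median spectrum) and its
    per-pixel amplitude (projection onto that shape); the amplitude is
    interpolated across tissue by normalised convolution with a wide
    Gaussian. Returns an (x, y, n_channels) additive field. This
    captures the smooth spatial variation of background fluorescence
    that a single per-channel scalar cannot.
    """
    from skimage.filters import threshold_otsu

    total = stack.data.sum(axis=2)
    if not total.any():
        return np.zeros_like(stack.data)
    try:
        level = threshold_otsu(total)
    except ValueError:
        level = np.quantile(total, 0.5)
    empty = total < level
    if empty.mean() < 0.05:  # nearly everything is tissue: fall back to decile
        empty = total <= np.quantile(total, 0.10)
    spectrum = np.median(stack.data[empty], axis=0)
    norm = np.linalg.norm(spectrum)
    if norm == 0:
        return np.zeros_like(stack.data)
    spectrum = spectrum / norm
    amp = np.zeros_like(total)
    amp[empty] = stack.data[empty] @ spectrum
    sigma = smooth_sigma_frac * max(total.shape)
    weight = ndimage.gaussian_filter(empty.astype(np.float64), sigma)
    smooth_amp = ndimage.gaussian_filter(amp, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        field_amp = np.where(weight > 1e-12, smooth_amp / weight, 0.0)
    return np.clip(field_amp[..., None] * spectrum[None, None, :], 0.0, None)


def _fit_polynomial_field(total: np.ndarray, degree: int, n_tiles: int) -> np.ndarray:
    """Low-order 2-D polynomial fit to tile medians of the intensity image."""
    h, w = total.shape
    ty = np.array_split(np.arange(h), n_tiles)
    tx = np.array_split(np.arange(w), n_tiles)
    pts, vals = [], []
    floor = 0.05 * total.mean()
    for ys in ty:
        for xs in tx:
            tile = total[np.ix_(ys, xs)]
            good = tile > floor
            if good.sum() < 0.2 * tile.size:
                continue
            pts.append((ys.mean() / h - 0.5, xs.mean() / w - 0.5))
            vals.append(np.median(tile[good]))
    if len(pts) < (degree + 1) * (degree + 2) // 2:
        return np.ones((h, w))
    pts_arr = np.array(pts)
    vals_arr = np.array(vals)

    def design(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(y)]
        for d in range(1, degree + 1):
            for py in range(d + 1):
                cols.append(y**py * x ** (d - py))
        return np.stack(cols, axis=-1)

    coef, *_ = np.linalg.lstsq(design(pts_arr[:, 0], pts_arr[:, 1]), vals_arr, rcond=None)
    yy = (np.arange(h)[:, None] / h - 0.5) * np.ones((1, w))
    xx = np.ones((h, 1)) * (np.arange(w)[None, :] / w - 0.5)
    field = design(yy.ravel(), xx.ravel()) @ coef
    return field.reshape(h, w)


def estimate_illumination(
    stack: SpectralStack,
    brightfield: BrightField | None = None,
    method: str | None = None,
    degree: int = 2,
    n_tiles: int = 8,
    smooth_sigma_frac: float = 0.15,
) -> IlluminationField:
    """Estimate the smooth illumination field.

    ``brightfield`` (default when a bright-field image is supplied):
    fits a low-order 2-D polynomial to per-tile high quantiles of the
    bright-field image — structure-free bright-field pixels see the
    illumination directly, so this works even when fluorescent tissue
    is sparse. ``polynomial`` fits tile medians of the stack's
    total-intensity image (appropriate for densely fluorescent scenes);
    ``smooth`` uses large-kernel Gaussian smoothing of the intensity.
    The field is clipped positive and normalised to spatial mean 1.
    """
    if method is None:
        method = "brightfield" if brightfield is not None else "polynomial"
    total = stack.data.sum(axis=2)
    if method == "brightfield":
        if brightfield is None:
            raise ValueError("brightfield method requires a bright-field image")
        field = _fit_brightfield_field(brightfield.data, degree=degree, n_tiles=n_tiles)
    elif method == "polynomial":
        if not total.any():
            return IlluminationField(field=np.ones(stack.spatial_shape))
        field = _fit_polynomial_field(total, degree=degree, n_tiles=n_tiles)
    elif method == "smooth":
        if not total.any():
            return IlluminationField(field=np.ones(stack.spatial_shape))
        field = ndimage.gaussian_filter(total, sigma=smooth_sigma_frac * max(total.shape))
    else:
        raise ValueError(f"unknown illumination method {method!r}")
    field = np.clip(field, 0.05 * max(field.max(), 1e-12), None)
    return IlluminationField(field=field)


def _fit_brightfield_field(bf: np.ndarray, degree: int, n_tiles: int) -> np.ndarray:
    """Polynomial fit to per-tile upper quantiles of the bright-field.

    Tissue structures absorb (appear dark), so the bright quantile of
    each tile approximates the bare illumination there.
    """
    h, w = bf.shape
    ty = np.array_split(np.arange(h), n_tiles)
    tx = np.array_split(np.arange(w), n_tiles)
    pts, vals = [], []
    for ys in ty:
        for xs in tx:
            tile = bf[np.ix_(ys, xs)]
            pts.append((ys.mean() / h - 0.5, xs.mean() / w - 0.5))
            vals.append(np.quantile(tile, 0.85))
    pts_arr = np.array(pts)
    vals_arr = np.array(vals)

    def design(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(y)]
        for d in range(1, degree + 1):
            for py in range(d + 1):
                cols.append(y**py * x ** (d - py))
        return np.stack(cols, axis=-1)

    coef, *_ = np.linalg.lstsq(design(pts_arr[:, 0], pts_arr[:, 1]), vals_arr, rcond=None)
    yy = (np.arange(h)[:, None] / h - 0.5) * np.ones((1, w))
    xx = np.ones((h, 1)) * (np.arange(w)[None, :] / w - 0.5)
    field = design(yy.ravel(), xx.ravel()) @ coef
    return field.reshape(h, w)


def flatten_illumination(stack: SpectralStack, field: IlluminationField) -> SpectralStack:
    """Divide every channel by the illumination field (not idempotent)."""
    if (field.field <= 0).any():
        raise ValueError("illumination field must be strictly positive")
    return stack.with_data(stack.data / field.field[..., None])


def estimate_gain(stack: SpectralStack) -> float:
    """Robust photon-gain estimate from the Poisson mean-variance relation.

    Local high-pass residual variance is regressed against local mean
    by a robust (median-of-ratios) slope; for Poisson noise
    var = gain * mean. Works on stacks that still carry shot noise.
    """
    total_ratio = []
    n_chan = stack.n_channels
    for c in range(0, n_chan, max(1, n_chan // 8)):
        img = stack.data[:, :, c]
        smooth = ndimage.uniform_filter(img, size=3)
        resid = img - smooth
        # E[resid^2] for a 3x3 box high-pass of iid noise is (1 - 1/9) * var
        local_var = resid**2 / (1.0 - 1.0 / 9.0)
        good = smooth > 0.1 * img.mean() if img.mean() > 0 else smooth > 0
        if good.sum() < 50:
            continue
        total_ratio.append(np.median(local_var[good] / smooth[good]))
    if not total_ratio:
        return 1.0
    return float(max(np.median(total_ratio), 1e-12))


def denoise_poisson(stack: SpectralStack, gain: float, sigma: float = 1.0) -> SpectralStack:
    """Variance-stabilised spatial denoising of Poisson-noisy data.

    Counts ``I/gain`` go through the square-root (Anscombe-type)
    transform ``sqrt(c + 3/8)`` whose variance is ~1/4 regardless of
    mean; a small Gaussian kernel smooths in x/y only (never across
    the spectral axis); the algebraic inverse maps back to intensity.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    counts = np.clip(stack.data / gain, 0.0, None)
    t = np.sqrt(counts + 3.0 / 8.0)
    t = ndimage.gaussian_filter(t, sigma=(sigma, sigma, 0.0))
    out = np.clip(t**2 - 3.0 / 8.0, 0.0, None) * gain
    return stack.with_data(out)


def preprocess_stack(
    stack: SpectralStack,
    brightfield: BrightField | None = None,
    saturation_value: float | None = None,
    gain: float | None = None,
    denoise_sigma: float = 0.0,
    background_mode: str = "smooth",
    illumination_method: str | None = None,
) -> tuple[SpectralStack, dict]:
    """Full artefact-removal chain; returns (clean stack, QC report).

    Saturation defaults to the stack's maximum value (dtype maximum for
    integer acquisitions); gain is estimated from the noise statistics
    when not supplied. ``background_mode`` "smooth" (default) removes a
    spatially varying background field; "median" subtracts one
    per-channel scalar spectrum.
    """
    if saturation_value is None:
        saturation_value = float(stack.data.max()) if stack.data.max() > 0 else 1.0
    bad = detect_bad_pixels(stack, saturation_value=saturation_value)
    repaired = repair_bad_pixels(stack, bad) if bad.n_flagged else stack
    if background_mode == "smooth":
        background_field = estimate_background_field(repaired)
        background = np.median(background_field.reshape(-1, stack.n_channels), axis=0)
        bg_sub = subtract_background(repaired, background_field)
    else:
        background = estimate_background(repaired, brightfield)
        bg_sub = subtract_background(repaired, background)
    illum = estimate_illumination(bg_sub, brightfield=brightfield)
    flat = flatten_illumination(bg_sub, illum)
    # spatial denoising is opt-in: at the shot-noise levels this pipeline
    # targets, genuine spectral texture exceeds the noise and smoothing
    # degrades per-pixel abundances more than it removes noise
    if denoise_sigma > 0:
        if gain is None:
            gain = estimate_gain(flat)
        clean = denoise_poisson(flat, gain=gain, sigma=denoise_sigma)
    else:
        gain = gain if gain is not None else 0.0
        clean = flat
    qc = {
        "n_bad_pixels": bad.n_flagged,
        "n_dead": int((bad.reason == REASON_DEAD).sum()),
        "n_saturated": int((bad.reason == REASON_SATURATED).sum()),
        "background_spectrum": background.tolist(),
        "illumination_range": [float(illum.field.min()), float(illum.field.max())],
        "gain": float(gain),
    }
    return clean, qc
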