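"""Non-negative linear-mixing-model unmixing of spectral stacks.

Each pixel spectrum x (length n_channels) is modelled as a non-negative
combination of fluorophore endmember spectra S (n_fluor x n_channels):

    x ~= a @ S,   a >= 0.

Blind unmixing estimates both S and the abundances a from the stack
alone, by alternating non-negative least squares (HALS updates) under a
robust, Huber-weighted squared loss so that outlier pixels (residual
debris, uncorrected artefacts) are down-weighted rather than dragging
the endmembers. Components are *not* forced towards statistical
independence — correlated fluorophore abundances are expected in
tissue. With endmembers known (or after a blind fit), per-pixel
abundances come from exact non-negative least squares, and "relative"
abundances are normalised by the per-pixel total signal including the
unexplained residual, so they sum to at most 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from hyperflux.io_core import SpectralStack

DEFAULT_COMPONENT_NAMES = ("NAD(P)H", "flavins", "collagen")


@dataclass
class EndmemberSet:
    """Matrix of fluorophore emission signatures (rows unit L2 norm)."""

    spectra: np.ndarray  # (n_fluor, n_channels)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        if (self.spectra < -1e-12).any():
            raise ValueError("endmember spectra must be non-negative")
        norms = np.linalg.norm(self.spectra, axis=1)
        if (norms == 0).any():
            raise ValueError("endmember rows must be non-zero")
        self.spectra = self.spectra / norms[:, None]
        if not self.names:
            self.names = [f"component_{i}" for i in range(self.n_fluor)]
        if len(self.names) != self.n_fluor:
            raise ValueError("one name per endmember row required")

    @property
    def n_fluor(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]


@dataclass
class AbundanceMaps:
    """Per-pixel fluorophore abundances, (n_fluor, x, y)."""

    maps: np.ndarray
    names: list[str] = field(default_factory=list)
    normalisation: str = "relative"  # or "raw"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("abundance maps must be (n_fluor, x, y)")
        if (self.maps < -1e-9).any():
            raise ValueError("abundances must be non-negative")
        self.maps = np.clip(self.maps, 0.0, None)
        if self.normalisation == "relative":
            sums = self.maps.sum(axis=0)
            if (sums > 1.0 + 1e-6).any():
                raise ValueError("relative abundances must sum to <= 1 per pixel")
        if not self.names:
            self.names = [f"component_{i}" for i in range(self.maps.shape[0])]

    @property
    def n_fluor(self) -> int:
        return self.maps.shape[0]


# ---------------------------------------------------------------------------
# exact NNLS, vectorised over pixels


def _nnls_enumerate(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Exact NNLS for every row of X against endmember rows of S.

    Enumerates all support subsets (feasible for small n_fluor), solves
    the unconstrained normal equations on each support for all pixels
    simultaneously, and keeps the feasible solution with the smallest
    residual. The true NNLS optimum is one of these candidates, and no
    feasible candidate can beat it, so the minimum is exact.
    """
    n_pix, _ = X.shape
    k = S.shape[0]
    G = S @ S.T  # (k, k) Gram
    B = X @ S.T  # (n_pix, k)
    best_res = np.einsum("ij,ij->i", X, X)  # residual^2 of the all-zero solution
    best_coef = np.zeros((n_pix, k))
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            idx = list(subset)
            Gs = G[np.ix_(idx, idx)]
            try:
                coef_s = np.linalg.solve(Gs, B[:, idx].T).T  # (n_pix, r)
            except np.linalg.LinAlgError:
                continue
            feasible = (coef_s >= -1e-12).all(axis=1)
            # residual^2 = x.x - c.b  (c solves the normal equations exactly)
            res_s = np.einsum("ij,ij->i", X, X) - np.einsum(
                "ij,ij->i", coef_s, B[:, idx]
            )
            better = feasible & (res_s < best_res - 1e-12)
            if better.any():
                best_res[better] = res_s[better]
                best_coef[better] = 0.0
                best_coef[np.ix_(np.where(better)[0], idx)] = np.clip(
                    coef_s[better], 0.0, None
                )
    return best_coef


def nnls_pixels(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Non-negative least squares abundances for a pixel matrix.

    Uses exhaustive support enumeration for n_fluor <= 6 (vectorised over
    pixels); larger problems fall back to scipy's Lawson-Hanson solver.
    """
    X = np.asarray(X, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if S.shape[0] <= 6:
        return _nnls_enumerate(X, S)
    from scipy.optimize import nnls as _scipy_nnls

    out = np.empty((X.shape[0], S.shape[0]))
    for i, x in enumerate(X):
        out[i], _ = _scipy_nnls(S.T, x)
    return out


def unmix_known(
    stack: SpectralStack,
    endmembers: EndmemberSet,
    normalisation: str = "relative",
) -> AbundanceMaps:
    """Per-pixel NNLS abundances against known endmembers.

    In ``relative`` mode each pixel's abundances are divided by the
    total explained-plus-residual signal (sum of raw abundances plus the
    L2 norm of the model residual), so fluorophore fractions per pixel
    sum to at most 1, with the remainder attributable to unmodelled
    background.
    """
    S = endmembers.spectra
    if np.linalg.matrix_rank(S) < endmembers.n_fluor:
        raise ValueError("endmember matrix is rank-deficient")
    h, w = stack.spatial_shape
    X = stack.pixels()
    raw = nnls_pixels(X, S)
    if normalisation == "raw":
        maps = raw.T.reshape(endmembers.n_fluor, h, w)
        return AbundanceMaps(maps=maps, names=list(endmembers.names), normalisation="raw")
    resid = X - raw @ S
    resid_norm = np.linalg.norm(resid, axis=1)
    denom = raw.sum(axis=1) + resid_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom[:, None] > 0, raw / denom[:, None], 0.0)
    rel = np.clip(rel, 0.0, 1.0)
    maps = rel.T.reshape(endmembers.n_fluor, h, w)
    return AbundanceMaps(maps=maps, names=list(endmembers.names), normalisation="relative")


# ---------------------------------------------------------------------------
# blind factorisation


def _spa_init(X: np.ndarray, k: int) -> np.ndarray:
    """Successive-projection initial endmembers: greedy extreme pixels."""
    R = X.copy()
    rows = []
    for _ in range(k):
        norms = np.einsum("ij,ij->i", R, R)
        j = int(np.argmax(norms))
        v = X[j].astype(np.float64)
        nv = np.linalg.norm(R[j])
        if nv == 0:
            break
        u = R[j] / nv
        R = R - np.outer(R @ u, u)
        rows.append(np.clip(v, 0, None))
    while len(rows) < k:
        rows.append(np.abs(np.random.default_rng(len(rows)).standard_normal(X.shape[1])))
    S = np.array(rows)
    norms = np.linalg.norm(S, axis=1)
    norms[norms == 0] = 1.0
    return S / norms[:, None]


def _huber_weights(X: np.ndarray, A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-pixel Huber weights on the residual norm (1 inside, delta/r outside)."""
    r = np.linalg.norm(X - A @ S, axis=1)
    med = np.median(r)
    if med <= 0:
        return np.ones_like(r)
    delta = 1.345 * med / 0.6745  # MAD-consistent scale for half-normal-ish residuals
    with np.errstate(divide="ignore"):
        w = np.where(r > delta, delta / r, 1.0)
    return w


def _hals_abundances(X: np.ndarray, A: np.ndarray, S: np.ndarray, n_inner: int = 1) -> np.ndarray:
    G = S @ S.T
    B = X @ S.T
    for _ in range(n_inner):
        for j in range(S.shape[0]):
            num = B[:, j] - A @ G[:, j] + A[:, j] * G[j, j]
            A[:, j] = np.clip(num / max(G[j, j], 1e-12), 0.0, None)
    return A


def _hals_endmembers(
    X: np.ndarray, A: np.ndarray, S: np.ndarray, w: np.ndarray, n_inner: int = 1
) -> np.ndarray:
    Aw = A * w[:, None]
    G = A.T @ Aw  # (k, k)
    H = Aw.T @ X  # (k, c)
    for _ in range(n_inner):
        for j in range(S.shape[0]):
            num = H[j] - G[j] @ S + G[j, j] * S[j]
            S[j] = np.clip(num / max(G[j, j], 1e-12), 0.0, None)
            if not S[j].any():
                S[j] = 1e-6  # revive dead component
    return S


def fit_blind_unmixing(
    stack: SpectralStack,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    max_fit_pixels: int = 20000,
    component_names: tuple[str, ...] | None = None,
) -> tuple[EndmemberSet, AbundanceMaps, dict]:
    """Blind robust non-negative unmixing of a preprocessed stack.

    Alternating HALS non-negative factorisation of the pixels-by-channels
    matrix under a Huber-weighted squared loss, with multiple seeded
    restarts (restart 0 starts from successive-projection extreme
    pixels, the rest from random non-negative spectra); the best-loss
    solution is kept, ties broken by lowest restart index. Endmember
    rows are renormalised to unit L2 with compensating abundance
    scaling, components are named by ascending peak channel (NAD(P)H
    bluest, collagen reddest by default), and final abundances are
    recomputed for every pixel by exact NNLS in relative normalisation.

    Returns ``(endmembers, abundances, diagnostics)``.
    """
    if n_components > stack.n_channels:
        raise ValueError("n_components cannot exceed the number of channels")
    X_full = stack.pixels()
    if not X_full.any():
        raise ValueError("cannot unmix an all-zero stack")
    rng = np.random.default_rng(seed)
    if X_full.shape[0] > max_fit_pixels:
        # favour informative (bright) pixels but keep some of everything
        intensity = X_full.sum(axis=1)
        p = intensity + 0.05 * intensity.mean()
        p = p / p.sum()
        sel = rng.choice(X_full.shape[0], size=max_fit_pixels, replace=False, p=p)
        X = X_full[sel]
    else:
        X = X_full

    best: dict | None = None
    restart_losses = []
    for restart in range(n_restarts):
        r_rng = np.random.default_rng(seed + restart)
        if restart == 0:
            S = _spa_init(X, n_components)
        else:
            S = r_rng.exponential(1.0, size=(n_components, stack.n_channels))
            S = S / np.linalg.norm(S, axis=1)[:, None]
        A = np.clip(X @ S.T @ np.linalg.pinv(S @ S.T), 0.0, None)
        w = np.ones(X.shape[0])
        prev_loss = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            A = _hals_abundances(X, A, S)
            S = _hals_endmembers(X, A, S, w)
            if n_iter % 5 == 0 or n_iter == max_iter:
                w = _huber_weights(X, A, S)
                resid = X - A @ S
                loss = float(np.sum(w * np.einsum("ij,ij->i", resid, resid)))
                if prev_loss < np.inf and abs(prev_loss - loss) <= tol * max(prev_loss, 1e-30):
                    prev_loss = loss
                    break
                prev_loss = loss
        restart_losses.append(prev_loss)
        if best is None or prev_loss < best["loss"] - 1e-15:
            best = {"loss": prev_loss, "S": S.copy(), "iters": n_iter, "restart": restart}

    assert best is not None
    S = best["S"]
    norms = np.linalg.norm(S, axis=1)
    norms[norms == 0] = 1.0
    S = S / norms[:, None]
    # name components by emission peak position (bluest first)
    order = np.argsort(np.argmax(S, axis=1))
    S = S[order]
    if component_names is None:
        component_names = (
            DEFAULT_COMPONENT_NAMES if n_components == 3 else tuple(f"component_{i}" for i in range(n_components))
        )
    ems = EndmemberSet(spectra=S, names=list(component_names))
    abundances = unmix_known(stack, ems, normalisation="relative")
    diagnostics = {
        "loss": best["loss"],
        "restart_losses": restart_losses,
        "best_restart": best["restart"],
        "iterations": best["iters"],
        "n_fit_pixels": X.shape[0],
    }
    return ems, abundances, diagnostics


# ---------------------------------------------------------------------------
# diagnostics


def match_components(
    estimated: EndmemberSet, reference: EndmemberSet
) -> tuple[tuple[int, ...], np.ndarray]:
    """Best permutation of estimated components onto a reference set.

    Exhaustive over permutations (fine for n_fluor <= 6); returns the
    permutation ``perm`` such that ``estimated.spectra[perm[i]]`` matches
    ``reference.spectra[i]``, plus the per-pair cosine similarities.
    """
    if estimated.spectra.shape != reference.spectra.shape:
        raise ValueError("endmember sets must have matching shapes")
    k = estimated.n_fluor
    if k > 6:
        raise ValueError("exhaustive matching supports at most 6 components")
    C = reference.spectra @ estimated.spectra.T  # rows unit-norm -> cosines
    best_perm = None
    best_total = -np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(C[i, perm[i]] for i in range(k))
        if total > best_total:
            best_total = total
            best_perm = perm
    assert best_perm is not None
    cosines = np.array([C[i, best_perm[i]] for i in range(k)])
    return best_perm, cosines


def reconstruction_error(
    stack: SpectralStack, endmembers: EndmemberSet, abundances: AbundanceMaps
) -> dict:
    """Residual statistics of stack ~= abundance . endmembers.

    With relative abundances the reconstruction is rescaled per pixel by
    the least-squares optimal scalar, since relative normalisation
    discards per-pixel intensity.
    """
    h, w = stack.spatial_shape
    if abundances.maps.shape[1:] != (h, w):
        raise ValueError("abundance maps do not match stack shape")
    X = stack.pixels()
    A = abundances.maps.reshape(abundances.n_fluor, -1).T
    model = A @ endmembers.spectra
    if abundances.normalisation == "relative":
        num = np.einsum("ij,ij->i", model, X)
        den = np.einsum("ij,ij->i", model, model)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(den > 0, num / den, 0.0)
        model = model * scale[:, None]
    resid = X - model
    per_pixel = np.linalg.norm(resid, axis=1).reshape(h, w)
    stack_norm = np.linalg.norm(X)
    rel = float(np.linalg.norm(resid) / stack_norm) if stack_norm > 0 else 0.0
    return {
        "relative_frobenius_error": rel,
        "per_pixel_residual": per_pixel,
        "max_pixel_residual": float(per_pixel.max()),
    }
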