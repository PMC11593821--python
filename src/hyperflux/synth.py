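"""Synthetic hyperspectral tissue scenes and patient cohorts.

Generates (x, y, lambda) stacks whose pixel spectra are non-negative
mixtures of three fluorophore endmembers — NAD(P)H, flavins, collagen —
arranged into elliptical cell blobs and curvilinear fibre ridges, then
corrupted the way a real acquisition is: additive smooth background
fluorescence, multiplicative uneven illumination, Poisson shot noise at
a target SNR, and dead/saturated camera pixels. Every scene carries a
:class:`SceneTruth` with the clean abundances, structure masks,
endmembers, illumination field and bad-pixel mask, so each pipeline
stage can be scored against ground truth.

Cohorts follow the study design of the source data: 22 patients in four
disease/pain groups (IA-Low n=8, IA-Mid n=1, RA-Mid n=4, RA-High n=9),
with group-mean abundances encoding the reported effect directions:
NAD(P)H and the optical redox ratio higher in active (RA) groups,
flavins lowest in RA-High, collagen highest in RA-High and lowest in
IA-Low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from hyperflux.io_core import OBSERVED_GROUPS, BrightField, Group, PatientRecord, SpectralStack
from hyperflux.unmix import EndmemberSet

DEFAULT_N_CHANNELS = 69

#: Group mean abundance fractions (NAD(P)H, flavins, collagen).
#: Directions: NAD(P)H higher in RA than IA groups; flavins lowest in
#: RA-High (and highest among RA in the mid-pain group); collagen
#: highest in RA-High, lowest in IA-Low; implied redox ratio
#: (NAD(P)H/flavins) highest in the RA groups. Separations are >= 1.5
#: within-group SDs at the default CV so group differences are clearly
#: resolvable.
DEFAULT_EFFECT_TABLE: dict[Group, tuple[float, float, float]] = {
    Group.IA_LOW: (0.24, 0.30, 0.20),
    Group.IA_MID: (0.26, 0.34, 0.25),
    Group.RA_MID: (0.40, 0.25, 0.28),
    Group.RA_HIGH: (0.40, 0.15, 0.40),
}

#: Structure-type modulation of the group abundance triple. Cells are
#: metabolically dominated (NAD(P)H/flavins), fibres are collagen-rich;
#: within a structure kind the modulation is a fixed positive scale, so
#: all between-group orderings are preserved in both strata.
_CELL_MODULATION = np.array([1.10, 1.10, 0.45])
# fibre collagen enrichment is kept moderate: abundances are analysed in
# relative (compositional) form, and a stronger collagen boost would let
# closure reverse the NAD(P)H group ordering within the fibre stratum
_FIBRE_MODULATION = np.array([0.70, 0.70, 1.30])


@dataclass(frozen=True)
class FluorophoreSpec:
    """Emission-signature shape of one fluorophore along the channel axis."""

    name: str
    peak_channel: float
    width_channels: float
    shape: str = "gaussian"  # or "skewed-gaussian"

    def __post_init__(self) -> None:
        if self.width_channels <= 0:
            raise ValueError("width_channels must be positive")
        if self.shape not in ("gaussian", "skewed-gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")


def default_fluorophores(n_channels: int = DEFAULT_N_CHANNELS) -> list[FluorophoreSpec]:
    """NAD(P)H (bluest), flavins, collagen peaks on an n-channel ladder."""
    scale = n_channels / DEFAULT_N_CHANNELS
    return [
        FluorophoreSpec("NAD(P)H", 10.0 * scale, 6.0 * scale, "skewed-gaussian"),
        FluorophoreSpec("flavins", 30.0 * scale, 7.0 * scale, "skewed-gaussian"),
        FluorophoreSpec("collagen", 52.0 * scale, 7.0 * scale, "gaussian"),
    ]


def make_endmembers(
    n_channels: int,
    specs: list[FluorophoreSpec] | None = None,
    seed: int = 0,
    ripple: float = 0.02,
) -> EndmemberSet:
    """Build a unit-L2-norm endmember matrix from fluorophore specs.

    Peaks must be pairwise separated by at least the larger of the two
    widths, so the mixing matrix stays well conditioned; a small seeded
    channel ripple keeps the signatures from being analytically exact
    Gaussians.
    """
    if specs is None:
        specs = default_fluorophores(n_channels)
    if n_channels < len(specs):
        raise ValueError("need at least as many channels as fluorophores")
    for i, a in enumerate(specs):
        if not (0 <= a.peak_channel < n_channels):
            raise ValueError(f"{a.name}: peak_channel outside [0, {n_channels})")
        for b in specs[i + 1 :]:
            min_sep = max(a.width_channels, b.width_channels)
            if abs(a.peak_channel - b.peak_channel) < min_sep:
                raise ValueError(
                    f"peaks of {a.name} and {b.name} closer than one width; "
                    "the mixing matrix would be ill-conditioned"
                )
    rng = np.random.default_rng(seed)
    lam = np.arange(n_channels, dtype=np.float64)
    rows = []
    for s in specs:
        z = (lam - s.peak_channel) / s.width_channels
        profile = np.exp(-0.5 * z**2)
        if s.shape == "skewed-gaussian":
            # mild red tail, as real emission spectra have
            from scipy.stats import norm

            profile = profile * (1.0 + np.clip(2.0 * norm.cdf(1.5 * z) - 1.0, 0, None) * 0.6)
        profile = profile * (1.0 + ripple * rng.standard_normal(n_channels))
        profile = np.clip(profile, 0.0, None)
        rows.append(profile / np.linalg.norm(profile))
    spectra = np.array(rows)
    ems = EndmemberSet(spectra=spectra, names=[s.name for s in specs])
    cos = spectra @ spectra.T
    off = cos[~np.eye(len(specs), dtype=bool)]
    if off.size and off.max() >= 0.95:
        raise ValueError(f"endmembers too similar (max pairwise cosine {off.max():.3f})")
    return ems


@dataclass
class SceneParams:
    """Geometry and corruption settings for one synthetic scene."""

    size: int = 128
    n_cells: int = 18
    n_fibres: int = 6
    snr_db: float = 30.0
    cell_radius: tuple[float, float] = (4.0, 9.0)
    fibre_width: int = 3
    pixel_cv: float = 0.20
    composition_concentration: float = 5.0
    intensity_scale: float = 1000.0
    background_amplitude: float = 0.08
    illumination_range: float = 0.25
    bad_pixel_fraction: float = 0.005
    saturation_value: float = 4095.0
    brightfield_noise: float = 0.02

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("scene size must be >= 8")
        if self.n_cells < 0 or self.n_fibres < 0:
            raise ValueError("structure counts must be non-negative")


@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene."""

    abundance_true: np.ndarray  # (n_fluor, h, w) absolute fractions, sum <= 1
    cell_mask_true: np.ndarray  # int labels, 0 = background
    fibre_mask_true: np.ndarray
    endmembers_true: EndmemberSet
    illumination_true: np.ndarray  # (h, w) spatial field shared by channels
    background_true: np.ndarray  # (h, w, n_channels) additive term
    bad_pixels_true: np.ndarray  # bool (h, w)
    gain: float  # photons-to-intensity gain used for Poisson sampling

    def relative_abundance_true(self) -> np.ndarray:
        """Sum-normalised abundances (what relative unmixing estimates)."""
        s = self.abundance_true.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(s > 0, self.abundance_true / s, 0.0)
        return rel


@dataclass
class GroupEffect:
    """Mean abundance triple and ROI-level coefficient of variation."""

    means: tuple[float, float, float]
    cv: float = 0.12

    def __post_init__(self) -> None:
        if not all(0.0 < m < 1.0 for m in self.means):
            raise ValueError("abundance means must be in (0, 1)")
        if self.cv <= 0:
            raise ValueError("cv must be positive")


@dataclass
class CohortSpec:
    """Study design for a synthetic cohort (defaults mirror the source study)."""

    n_per_group: dict[Group, int] = field(
        default_factory=lambda: {
            Group.IA_LOW: 8,
            Group.IA_MID: 1,
            Group.RA_MID: 4,
            Group.RA_HIGH: 9,
        }
    )
    effect_table: dict[Group, GroupEffect] = field(
        default_factory=lambda: {g: GroupEffect(m) for g, m in DEFAULT_EFFECT_TABLE.items()}
    )
    scene: SceneParams = field(
        default_factory=lambda: SceneParams(size=96, n_cells=12, n_fibres=5, snr_db=25.0)
    )
    patient_cv: float = 0.06
    n_channels: int = DEFAULT_N_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be non-negative")
        missing = [g for g, n in self.n_per_group.items() if n > 0 and g not in self.effect_table]
        if missing:
            raise ValueError(f"effect_table missing populated group(s): {missing}")


@dataclass
class CohortEntry:
    record: PatientRecord
    stack: SpectralStack
    brightfield: BrightField
    truth: SceneTruth


# ---------------------------------------------------------------------------
# group assignment rules

DAS28_ACTIVE_THRESHOLD = 2.6
CRP_ACTIVE_THRESHOLD_MG_L = 8.0


def assign_group(das28: float, vas_pain: float) -> Group:
    """Combine DAS-28 activity and VAS pain bin into a patient group.

    Activity: DAS-28 <= 2.6 is inactive (IA), > 2.6 active (RA). Pain:
    VAS <= 10 low, 11-59 mid, >= 60 high (VAS 0 is mapped into the low
    bin so the function is total). Combinations absent from the study
    cohort (inactive-high, active-low) are returned as valid labels with
    a warning.
    """
    if not (np.isfinite(das28) and np.isfinite(vas_pain)):
        raise ValueError("das28 and vas_pain must be finite")
    if not (0.0 <= vas_pain <= 100.0):
        raise ValueError(f"vas_pain must be in [0, 100], got {vas_pain}")
    active = das28 > DAS28_ACTIVE_THRESHOLD
    if vas_pain <= 10.0:
        pain = "LOW"
    elif vas_pain < 60.0:
        pain = "MID"
    else:
        pain = "HIGH"
    group = Group[f"{'RA' if active else 'IA'}_{pain}"]
    if group in (Group.IA_HIGH, Group.RA_LOW):
        warnings.warn(
            f"group {group.name} was not observed in the study cohort", stacklevel=2
        )
    return group


def classify_crp(crp_mg_per_l: float) -> str:
    """CRP activity class: < 8 mg/L inactive, above active.

    Exactly 8 mg/L falls between the study's strict inequalities; it is
    classed active (flagged with a warning) so the function is total.
    """
    if crp_mg_per_l < 0:
        raise ValueError("CRP cannot be negative")
    if crp_mg_per_l == CRP_ACTIVE_THRESHOLD_MG_L:
        warnings.warn("CRP exactly at the 8 mg/L threshold; classed active", stacklevel=2)
    return "crp_inactive" if crp_mg_per_l < CRP_ACTIVE_THRESHOLD_MG_L else "crp_active"


# ---------------------------------------------------------------------------
# scene geometry


def _place_cells(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Elliptical blobs, rejection-sampled to avoid overlap. Int labels."""
    h = w = params.size
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0
    for k in range(1, params.n_cells + 1):
        ok = False
        for _attempt in range(60):
            a = rng.uniform(*params.cell_radius)
            b = rng.uniform(*params.cell_radius)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + 2, h - a - 2)
            cx = rng.uniform(b + 2, w - b - 2)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            grown = ndimage.binary_dilation(mask, iterations=2)
            if not (grown & occupied).any():
                ok = True
                break
        if not ok:
            warnings.warn("could not place cell without overlap; allowing overlap", stacklevel=2)
            mask = mask & ~occupied
            if not mask.any():
                continue
        labels[mask] = k
        occupied |= grown if ok else mask
        placed += 1
    return labels


def _draw_fibre(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """One smoothed random-walk polyline dilated to the fibre width."""
    h = w = params.size
    canvas = np.zeros((h, w), dtype=bool)
    y = rng.uniform(5, h - 5)
    x = rng.uniform(5, w - 5)
    angle = rng.uniform(0, 2 * np.pi)
    n_steps = int(1.2 * params.size)
    for _ in range(n_steps):
        angle += rng.normal(0.0, 0.15)
        y += np.sin(angle)
        x += np.cos(angle)
        if not (1 <= y < h - 1 and 1 <= x < w - 1):
            break
        canvas[int(round(y)), int(round(x))] = True
    radius = max(1, params.fibre_width // 2)
    struct = ndimage.generate_binary_structure(2, 1)
    return ndimage.binary_dilation(canvas, structure=struct, iterations=radius)


def _place_fibres(
    params: SceneParams, cell_labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    labels = np.zeros_like(cell_labels)
    occupied = cell_labels > 0
    k = 0
    for _ in range(params.n_fibres):
        placed = False
        for _attempt in range(25):
            fib = _draw_fibre(params, rng)
            if fib.sum() < 4 * params.size // 8:
                continue  # too short: walked off the edge early
            if not (fib & occupied).any():
                placed = True
                break
        if not placed:
            fib = fib & ~occupied
            if fib.sum() < 10:
                continue
            warnings.warn("fibre placed with clipping against existing structures", stacklevel=2)
        k += 1
        labels[fib] = k
        occupied |= ndimage.binary_dilation(fib, iterations=1)
    return labels


def _smooth_field(size: int, rng: np.random.Generator, sigma_frac: float = 0.25) -> np.ndarray:
    """Smooth positive random field with spatial mean 1."""
    raw = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_frac * size)
    smooth = smooth - smooth.min()
    rng_span = smooth.max() - smooth.min()
    if rng_span > 0:
        smooth = smooth / rng_span
    field = 0.5 + smooth
    return field / field.mean()


def _illumination_field(size: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order polynomial vignetting-style field, mean 1, range ~ 1 +/- strength."""
    y = np.linspace(-1, 1, size)[:, None]
    x = np.linspace(-1, 1, size)[None, :]
    c = rng.uniform(-1, 1, size=5)
    field = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x**2 + c[4] * y**2
    span = np.abs(field).max()
    if span > 0:
        field = field / span * strength
    field = 1.0 + field
    return field / field.mean()


def _gain_for_snr(mean_signal: float, snr_db: float) -> float:
    """Gain such that Poisson counts at the mean tissue intensity hit the SNR.

    For Poisson counts with mean mu, amplitude SNR is sqrt(mu); solving
    10^(snr_db/20) = sqrt(mean_signal/gain) gives the gain.
    """
    mu = (10.0 ** (snr_db / 20.0)) ** 2
    return mean_signal / mu


def make_scene(
    params: SceneParams,
    endmembers: EndmemberSet,
    group_means: tuple[float, float, float],
    seed: int,
    cv: float = 0.12,
) -> tuple[SpectralStack, BrightField, SceneTruth]:
    """Render one synthetic tissue scene with full ground truth.

    Cells and fibres receive abundance triples drawn around
    ``group_means`` (log-normal, per-structure CV ``cv``, plus per-pixel
    jitter), modulated by structure type (cells NAD(P)H/flavin-rich,
    fibres collagen-rich). Corruption order: + background fluorescence,
    x illumination, Poisson resampling at ``snr_db``, dead/saturated
    pixel injection.
    """
    rng = np.random.default_rng(seed)
    h = w = params.size
    n_fluor, n_chan = endmembers.spectra.shape
    means = np.asarray(group_means, dtype=np.float64)
    if means.shape != (n_fluor,):
        raise ValueError("group_means length must match endmember count")

    cell_labels = _place_cells(params, rng)
    fibre_labels = _place_fibres(params, cell_labels, rng)

    abundance = np.zeros((n_fluor, h, w))
    for labels, modulation in ((cell_labels, _CELL_MODULATION[:n_fluor]), (fibre_labels, _FIBRE_MODULATION[:n_fluor])):
        for lab in range(1, labels.max() + 1):
            mask = labels == lab
            npx = int(mask.sum())
            if npx == 0:
                continue
            struct_mean = means * modulation * rng.lognormal(0.0, cv, size=n_fluor)
            # per-pixel composition ~ Dirichlet around the structure mean
            # composition (so structure means are preserved in expectation,
            # while individual pixels spread towards fluorophore-dominated
            # corners, as in real tissue), per-pixel total ~ log-normal
            total_mean = struct_mean.sum()
            composition = struct_mean / total_mean
            conc = params.composition_concentration
            comp_pix = rng.dirichlet(conc * composition, size=npx).T  # (n_fluor, npx)
            totals = total_mean * rng.lognormal(0.0, params.pixel_cv, size=npx)
            abundance[:, mask] = comp_pix * totals[None, :]
    # keep the non-fluorescent remainder non-negative
    total = abundance.sum(axis=0)
    over = total > 0.97
    if over.any():
        abundance[:, over] *= 0.97 / total[over]

    clean = params.intensity_scale * np.einsum("kij,kc->ijc", abundance, endmembers.spectra)

    # additive background fluorescence: broad smooth spectrum x smooth field
    lam = np.arange(n_chan)
    bg_spectrum = np.exp(-0.5 * ((lam - 0.5 * n_chan) / (0.45 * n_chan)) ** 2)
    bg_field = _smooth_field(params.size, rng)
    background = (
        params.background_amplitude
        * params.intensity_scale
        * bg_field[..., None]
        * bg_spectrum[None, None, :]
    )

    illum = _illumination_field(params.size, params.illumination_range, rng)
    signal = (clean + background) * illum[..., None]

    structure = (cell_labels > 0) | (fibre_labels > 0)
    if np.isfinite(params.snr_db):
        ref = clean[structure].mean() if structure.any() else signal.mean()
        gain = _gain_for_snr(max(ref, 1e-9), params.snr_db)
        noisy = rng.poisson(signal / gain).astype(np.float64) * gain
    else:
        gain = 0.0
        noisy = signal.copy()

    bad = np.zeros((h, w), dtype=bool)
    n_bad = int(round(params.bad_pixel_fraction * h * w))
    if n_bad > 0:
        flat_idx = rng.choice(h * w, size=n_bad, replace=False)
        ys, xs = np.unravel_index(flat_idx, (h, w))
        half = n_bad // 2
        noisy[ys[:half], xs[:half], :] = 0.0  # dead
        noisy[ys[half:], xs[half:], :] = params.saturation_value  # saturated
        bad[ys, xs] = True

    # bright field: illumination-shaded total-intensity image, structures dark
    cell_depth = ndimage.gaussian_filter((cell_labels > 0).astype(float), 0.8)
    fibre_depth = ndimage.gaussian_filter((fibre_labels > 0).astype(float), 0.6)
    bf = illum * (1.0 - 0.45 * np.clip(cell_depth, 0, 1) - 0.25 * np.clip(fibre_depth, 0, 1))
    bf = bf + params.brightfield_noise * rng.standard_normal((h, w))

    from hyperflux.io_core import default_channels

    stack = SpectralStack(data=noisy, channels=default_channels(n_chan))
    truth = SceneTruth(
        abundance_true=abundance,
        cell_mask_true=cell_labels,
        fibre_mask_true=fibre_labels,
        endmembers_true=endmembers,
        illumination_true=illum,
        background_true=background,
        bad_pixels_true=bad,
        gain=gain,
    )
    return stack, BrightField(data=bf), truth


# ---------------------------------------------------------------------------
# cohorts

_CLINICAL_RANGES: dict[Group, tuple[tuple[float, float], tuple[float, float]]] = {
    # group -> ((das28 lo, hi), (vas lo, hi))
    Group.IA_LOW: ((1.0, 2.6), (0.0, 10.0)),
    Group.IA_MID: ((1.0, 2.6), (11.0, 59.0)),
    Group.RA_MID: ((2.8, 6.5), (11.0, 59.0)),
    Group.RA_HIGH: ((2.8, 8.0), (60.0, 100.0)),
}


def make_cohort(spec: CohortSpec) -> list[CohortEntry]:
    """Generate the full synthetic cohort (records, stacks, truths).

    Clinical scalars are sampled consistently with each group's DAS-28 /
    VAS / CRP definition, and each patient's scene abundances are the
    group effect means perturbed by a per-patient random effect.
    """
    rng = np.random.default_rng(spec.seed)
    endmembers = make_endmembers(spec.n_channels, seed=spec.seed)
    entries: list[CohortEntry] = []
    pid = 0
    for group in OBSERVED_GROUPS:
        n = spec.n_per_group.get(group, 0)
        if n == 0:
            continue
        effect = spec.effect_table[group]
        (d_lo, d_hi), (v_lo, v_hi) = _CLINICAL_RANGES[group]
        for _ in range(n):
            pid += 1
            das28 = rng.uniform(d_lo, d_hi)
            vas = rng.uniform(v_lo, v_hi)
            crp = rng.uniform(0.5, 7.0) if not group.active else rng.uniform(9.0, 60.0)
            record = PatientRecord(
                patient_id=f"P{pid:03d}",
                das28=round(float(das28), 2),
                vas_pain=round(float(vas), 1),
                crp_mg_per_l=round(float(crp), 1),
                group=assign_group(das28, vas),
            )
            assert record.group == group, "clinical sampling inconsistent with group"
            patient_means = tuple(
                float(m * f)
                for m, f in zip(effect.means, rng.lognormal(0.0, spec.patient_cv, size=3))
            )
            scene_seed = int(rng.integers(0, 2**31 - 1))
            stack, bf, truth = make_scene(
                spec.scene, endmembers, patient_means, seed=scene_seed, cv=effect.cv
            )
            entries.append(CohortEntry(record=record, stack=stack, brightfield=bf, truth=truth))
    return entries
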