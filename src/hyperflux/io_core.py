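"""Shared domain types and readers/writers for the standard formats.

Stacks travel as multi-page TIFF (one page per spectral channel, page
order = channel order) with an optional CSV sidecar describing the
excitation/emission ladder; cohort tables are plain CSV. On disk the
cube is page-major (lambda outermost); in memory it is presented as a
``(x, y, lambda)`` array, channel-last.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class Group(enum.Enum):
    """Disease-activity / pain-level patient groups.

    Activity (inactive ``IA`` vs active ``RA``) comes from the DAS-28
    threshold, the pain level (low/mid/high) from the VAS bin.
    ``IA_HIGH`` and ``RA_LOW`` are valid combinations of the two axes
    that the default cohort never contains; ``assign_group`` flags them.
    """

    IA_LOW = "IA_LOW"
    IA_MID = "IA_MID"
    IA_HIGH = "IA_HIGH"
    RA_LOW = "RA_LOW"
    RA_MID = "RA_MID"
    RA_HIGH = "RA_HIGH"

    @property
    def active(self) -> bool:
        return self.name.startswith("RA")

    @property
    def pain_level(self) -> str:
        return self.name.split("_")[1].lower()


#: The four groups observed in the default cohort, in display order.
OBSERVED_GROUPS = (Group.IA_LOW, Group.IA_MID, Group.RA_MID, Group.RA_HIGH)


@dataclass(frozen=True)
class ChannelSpec:
    """One excitation/emission channel of the hyperspectral ladder."""

    index: int
    excitation_nm: float
    emission_center_nm: float
    emission_bandwidth_nm: float = 20.0

    def __post_init__(self) -> None:
        if not self.excitation_nm < self.emission_center_nm:
            raise ValueError(
                f"channel {self.index}: excitation ({self.excitation_nm} nm) must be "
                f"below emission centre ({self.emission_center_nm} nm) (Stokes shift)"
            )


def default_channels(n_channels: int) -> list[ChannelSpec]:
    """A plausible excitation/emission ladder when no sidecar exists.

    The pipeline itself only needs channel count and order; physical
    wavelengths matter only for reporting, so an evenly spaced ladder
    spanning the NAD(P)H-to-collagen emission range is used.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    ex = np.linspace(340.0, 490.0, n_channels)
    em = ex + 60.0
    return [
        ChannelSpec(index=i, excitation_nm=float(ex[i]), emission_center_nm=float(em[i]))
        for i in range(n_channels)
    ]


@dataclass
class SpectralStack:
    """An (x, y, lambda) autofluorescence cube.

    ``data`` is channel-last float; ``channels`` is ordered by
    ``ChannelSpec.index`` and must match the lambda extent.
    """

    data: np.ndarray
    channels: list[ChannelSpec] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (x, y, lambda), got {self.data.ndim}-D")
        if not self.channels:
            self.channels = default_channels(self.data.shape[2])
        if len(self.channels) != self.data.shape[2]:
            raise ValueError(
                f"channel metadata count ({len(self.channels)}) does not match "
                f"lambda extent ({self.data.shape[2]})"
            )
        idx = [c.index for c in self.channels]
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        self.channels = sorted(self.channels, key=lambda c: c.index)

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixels(self) -> np.ndarray:
        """Flattened (n_pixels, n_channels) view of the cube."""
        return self.data.reshape(-1, self.n_channels)

    def with_data(self, data: np.ndarray) -> "SpectralStack":
        return SpectralStack(data=data, channels=list(self.channels), pixel_size_um=self.pixel_size_um)


@dataclass
class BrightField:
    """Single-channel bright-field image paired with a stack."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("bright-field image must be 2-D")


@dataclass
class PatientRecord:
    """Clinical scalars for one participant."""

    patient_id: str
    das28: float
    vas_pain: float
    crp_mg_per_l: float
    group: Group | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vas_pain <= 100.0):
            raise ValueError(f"patient {self.patient_id}: VAS pain must be in [0, 100], got {self.vas_pain}")
        if self.das28 < 0:
            raise ValueError(f"patient {self.patient_id}: DAS-28 must be non-negative")
        if self.crp_mg_per_l < 0:
            raise ValueError(f"patient {self.patient_id}: CRP must be non-negative")


# ---------------------------------------------------------------------------
# stack IO


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".channels.csv")


def _write_channel_sidecar(channels: list[ChannelSpec], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "excitation_nm", "emission_center_nm", "emission_bandwidth_nm"])
        for c in channels:
            writer.writerow([c.index, c.excitation_nm, c.emission_center_nm, c.emission_bandwidth_nm])


def _read_channel_sidecar(path: Path) -> list[ChannelSpec]:
    df = pd.read_csv(path)
    return [
        ChannelSpec(
            index=int(r["index"]),
            excitation_nm=float(r["excitation_nm"]),
            emission_center_nm=float(r["emission_center_nm"]),
            emission_bandwidth_nm=float(r.get("emission_bandwidth_nm", 20.0)),
        )
        for _, r in df.iterrows()
    ]


def read_stack(path: str | Path, channels_path: str | Path | None = None) -> SpectralStack:
    """Read a multi-page TIFF as a spectral stack (pages become channels).

    A ``<stem>.channels.csv`` sidecar is used for channel metadata when
    present; otherwise a default ladder is generated. Integer camera
    counts are cast to float.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of shape {pages.shape}")
    data = np.moveaxis(pages.astype(np.float64), 0, -1)
    n = data.shape[2]
    sidecar = Path(channels_path) if channels_path else _sidecar_path(path)
    if sidecar.exists():
        channels = _read_channel_sidecar(sidecar)
        if len(channels) != n:
            raise ValueError(
                f"{sidecar}: {len(channels)} channel rows for a {n}-page stack"
            )
    else:
        channels = default_channels(n)
    if n < 3:
        warnings.warn(
            f"stack has only {n} channel(s); unmixing needs at least as many "
            "channels as fluorophores",
            stacklevel=2,
        )
    return SpectralStack(data=data, channels=channels)


def write_stack(stack: SpectralStack, path: str | Path) -> Path:
    """Write a stack as a float32 multi-page TIFF plus channel sidecar."""
    if stack.n_channels == 0:
        raise ValueError("cannot write a stack with no channels")
    path = Path(path)
    pages = np.moveaxis(stack.data, -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    _write_channel_sidecar(stack.channels, _sidecar_path(path))
    return path


def read_brightfield(path: str | Path) -> BrightField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: bright-field image must be single-page 2-D")
    return BrightField(data=img.astype(np.float64))


def write_brightfield(bf: BrightField, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, bf.data.astype(np.float32))
    return path


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_COLUMNS = ("patient_id", "das28", "vas_pain", "crp_mg_per_l")


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV (patient_id, das28, vas_pain, crp_mg_per_l).

    Groups are left unassigned; use :func:`hyperflux.synth.assign_group`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        try:
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                das28=float(row["das28"]),
                vas_pain=float(row["vas_pain"]),
                crp_mg_per_l=float(row["crp_mg_per_l"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i} ({row['patient_id']!r}): {exc}") from exc
        records.append(rec)
    return records


def write_cohort_table(records: list[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "das28": [r.das28 for r in records],
            "vas_pain": [r.vas_pain for r in records],
            "crp_mg_per_l": [r.crp_mg_per_l for r in records],
            "group": [r.group.name if r.group else "" for r in records],
        }
    )
    df.to_csv(path, index=False)
    return path
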