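"""Per-ROI autofluorescent features and non-parametric group comparisons.

Each segmented cell or fibre ROI yields four features: the mean
relative abundances of NAD(P)H, flavins and collagen, plus the optical
redox ratio (NAD(P)H abundance / flavin abundance), a proxy for
metabolic state. Cells and fibres form separate strata. Group
differences are assessed with the two-sided Mann-Whitney U test at the
ROI level (each cell/fibre is an observation), with an optional
patient-level aggregation; p-values are reported raw, with an optional
Holm correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from hyperflux.io_core import Group
from hyperflux.segment import LabelMask
from hyperflux.unmix import AbundanceMaps

FEATURE_COLUMNS = ("a_nadph", "a_flavins", "a_collagen", "redox_ratio")

#: Significance star thresholds (two-sided p).
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

DEFAULT_REDOX_EPSILON = 1e-3


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """One pairwise Mann-Whitney comparison of a feature between groups."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.u_statistic > self.n_a * self.n_b + 1e-9:
            raise ValueError("U cannot exceed n_a * n_b")


def roi_mean_abundances(abundances: AbundanceMaps, mask: LabelMask) -> pd.DataFrame:
    """Arithmetic mean of each fluorophore's abundance over each ROI.

    Returns a DataFrame indexed by roi_id with one column per
    fluorophore.
    """
    if abundances.maps.shape[1:] != mask.labels.shape:
        raise ValueError("abundance maps and mask shapes differ")
    ids = mask.roi_ids()
    data = {}
    for name, amap in zip(abundances.names, abundances.maps):
        data[name] = ndimage.mean(amap, labels=mask.labels, index=ids) if ids.size else []
    return pd.DataFrame(data, index=pd.Index(ids, name="roi_id"))


def redox_ratio(
    a_nadph: float, a_flavins: float, epsilon: float = DEFAULT_REDOX_EPSILON
) -> tuple[float, bool]:
    """Optical redox ratio NAD(P)H / flavins.

    Returns ``(value, valid)``; when the flavin abundance is below
    ``epsilon`` the ratio is undefined — the record is flagged invalid
    (NaN value) and excluded from ratio-based statistics.
    """
    if a_nadph < 0 or a_flavins < 0:
        raise ValueError("abundances must be non-negative")
    if a_flavins < epsilon:
        return float("nan"), False
    return a_nadph / a_flavins, True


def build_feature_table(
    per_patient: list[tuple[str, Group, AbundanceMaps, dict[str, LabelMask]]],
    epsilon: float = DEFAULT_REDOX_EPSILON,
) -> pd.DataFrame:
    """Assemble the per-ROI feature table for a cohort.

    ``per_patient`` holds ``(patient_id, group, abundances, masks)``
    where ``masks`` maps stratum kind ("cell"/"fibre") to a LabelMask.
    One row per ROI with the four features, stratum kind, and labels.
    """
    rows = []
    for patient_id, group, abundances, masks in per_patient:
        n_rois = sum(m.roi_count for m in masks.values())
        if n_rois == 0:
            warnings.warn(f"patient {patient_id} has no ROIs; skipped", stacklevel=2)
            continue
        for kind, mask in sorted(masks.items()):
            means = roi_mean_abundances(abundances, mask)
            for roi_id, row in means.iterrows():
                a_n = float(row.get("NAD(P)H", row.iloc[0]))
                a_f = float(row.get("flavins", row.iloc[1]))
                a_c = float(row.get("collagen", row.iloc[2]))
                ratio, valid = redox_ratio(a_n, a_f, epsilon)
                rows.append(
                    {
                        "patient_id": patient_id,
                        "roi_id": int(roi_id),
                        "kind": kind,
                        "a_nadph": a_n,
                        "a_flavins": a_f,
                        "a_collagen": a_c,
                        "redox_ratio": ratio,
                        "redox_valid": valid,
                        "group": group.name,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "roi_id",
            "kind",
            "a_nadph",
            "a_flavins",
            "a_collagen",
            "redox_ratio",
            "redox_valid",
            "group",
        ],
    )


def mann_whitney_u(
    values_a: np.ndarray, values_b: np.ndarray, feature: str = "", group_a: str = "A", group_b: str = "B"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full null distribution) for tie-free samples
    with n_a + n_b <= 16, otherwise a normal approximation with
    tie-corrected variance and continuity correction. The complement
    identity U_a + U_b = n_a * n_b is asserted on every call.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    u_b = n_a * n_b - u_a
    assert abs(u_a + u_b - n_a * n_b) < 1e-9, "U complement identity violated"
    has_ties = np.unique(np.concatenate([a, b])).size < n_a + n_b
    method = "exact" if (not has_ties and n_a + n_b <= 16) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    assert abs(float(res.statistic) - u_a) < 1e-9
    u = min(u_a, u_b)
    return GroupComparison(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=u,
        p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
    )


def _group_values(
    table: pd.DataFrame, feature: str, group: str | list[str], patient_level: bool
) -> np.ndarray:
    groups = [group] if isinstance(group, str) else list(group)
    sub = table[table["group"].isin(groups)]
    if feature == "redox_ratio":
        sub = sub[sub["redox_valid"]]
    if patient_level:
        return sub.groupby("patient_id")[feature].mean().to_numpy()
    return sub[feature].to_numpy()


def compare_all_groups(
    table: pd.DataFrame,
    stratum: str,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    patient_level: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise group comparisons for each feature within a stratum.

    Statistics run at the ROI level by default (cells/fibres as
    observations, as in per-cell scatter figures); ``patient_level``
    aggregates to patient means first. ``holm`` applies a Holm
    step-down correction across the comparisons of each feature
    (off by default: significance is declared at raw p < 0.05).
    """
    sub = table[table["kind"] == stratum]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups in stratum {stratum!r}")
    rows = []
    for feature in features:
        comps = []
        for g_a, g_b in itertools.combinations(groups, 2):
            va = _group_values(sub, feature, g_a, patient_level)
            vb = _group_values(sub, feature, g_b, patient_level)
            if va.size == 0 or vb.size == 0:
                continue
            comps.append(mann_whitney_u(va, vb, feature=feature, group_a=g_a, group_b=g_b))
        if holm and comps:
            order = np.argsort([c.p_value for c in comps])
            m = len(comps)
            adj_prev = 0.0
            adjusted = [0.0] * m
            for rank, idx in enumerate(order):
                adj = min(1.0, (m - rank) * comps[idx].p_value)
                adj_prev = max(adj_prev, adj)
                adjusted[idx] = adj_prev
            for c, p_adj in zip(comps, adjusted):
                c.p_value = p_adj
                c.stars = significance_stars(p_adj)
        rows.extend(comps)
    return pd.DataFrame(
        [
            {
                "feature": c.feature,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.u_statistic,
                "p": c.p_value,
                "stars": c.stars,
            }
            for c in rows
        ]
    )
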