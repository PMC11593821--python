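"""End-to-end orchestration: synth -> preprocess -> segment -> unmix ->
features -> discriminate -> encoder, from one config, with a
reproducibility manifest.

A single global seed fans out to per-stage seeds by stable hashing of
the stage name, so any stage can be re-run in isolation and reproduce
its part of a full run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hyperflux import encoder as enc
from hyperflux import features as feat
from hyperflux import preprocess as prep
from hyperflux import segment as seg
from hyperflux.discriminate import evaluate_pairwise
from hyperflux.io_core import Group, write_brightfield, write_cohort_table, write_stack
from hyperflux.synth import CohortEntry, CohortSpec, SceneParams, make_cohort
from hyperflux.unmix import fit_blind_unmixing, unmix_known

IA_GROUPS = [Group.IA_LOW.name, Group.IA_MID.name]
RA_GROUPS = [Group.RA_MID.name, Group.RA_HIGH.name]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    digest = hashlib.blake2b(f"{stage}:{global_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """One-file description of a full synthetic-cohort run."""

    seed: int = 0
    out_dir: str = "results"
    scene_size: int = 96
    n_cells: int = 12
    n_fibres: int = 5
    snr_db: float = 25.0
    n_channels: int = 69
    n_components: int = 3
    unmix_restarts: int = 5
    unmix_max_pixels: int = 15000
    stratum: str = "fibre"
    pair_a: list[str] = field(default_factory=lambda: list(IA_GROUPS))
    pair_b: list[str] = field(default_factory=lambda: list(RA_GROUPS))
    evaluation_mode: str = "resubstitution"
    encoder_pair: list[str] = field(default_factory=lambda: [Group.IA_LOW.name, Group.RA_HIGH.name])
    encoder_epochs: int = 40
    encoder_pixels: int = 6000
    make_plots: bool = True
    save_stacks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        problems = validate_config(raw)
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        return cls(**raw)


_VALID_GROUPS = {g.name for g in Group}


def validate_config(raw: dict) -> list[str]:
    """Return a list of named problems (empty when the config is valid)."""
    problems = []
    known = set(PipelineConfig().__dict__.keys())
    for key in raw:
        if key not in known:
            problems.append(f"unknown key: {key}")
    if "snr_db" in raw and raw["snr_db"] is not None and raw["snr_db"] <= 0:
        problems.append("snr_db must be positive")
    if "scene_size" in raw and raw["scene_size"] < 8:
        problems.append("scene_size must be >= 8")
    if "seed" in raw and not isinstance(raw["seed"], int):
        problems.append("seed must be an integer")
    for key in ("pair_a", "pair_b", "encoder_pair"):
        for g in raw.get(key, []):
            if g not in _VALID_GROUPS:
                problems.append(f"{key}: unknown group {g!r}")
    if "evaluation_mode" in raw and raw["evaluation_mode"] not in (
        "resubstitution",
        "leave-one-patient-out",
    ):
        problems.append("evaluation_mode must be resubstitution or leave-one-patient-out")
    return problems


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict
    qc: dict
    timings_s: dict

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def analyse_cohort(
    entries: list[CohortEntry],
    seed: int,
    n_components: int = 3,
    unmix_restarts: int = 5,
    unmix_max_pixels: int = 15000,
) -> tuple[pd.DataFrame, "np.ndarray", dict]:
    """Preprocess, segment and unmix a cohort; return the feature table.

    Endmembers are fitted blindly once, on pixels pooled across the
    cohort's preprocessed stacks, then abundances come from exact NNLS
    per stack (so all patients share one spectral model).
    Returns (feature_table, endmember spectra, qc dict).
    """
    from hyperflux.io_core import SpectralStack

    rng = np.random.default_rng(seed)
    cleaned = []
    masks_per_patient = []
    qc_all = []
    for entry in entries:
        clean, qc = prep.preprocess_stack(
            entry.stack, entry.brightfield, saturation_value=None
        )
        cells = seg.segment_cells(entry.brightfield)
        fibres = seg.segment_fibres(entry.brightfield, cell_mask=cells)
        cleaned.append(clean)
        masks_per_patient.append({"cell": cells, "fibre": fibres})
        qc_all.append(qc)

    # pool structure pixels across the cohort for one blind endmember fit
    pooled = []
    per_stack_budget = max(500, unmix_max_pixels // max(len(entries), 1))
    for clean, masks in zip(cleaned, masks_per_patient):
        structure = (masks["cell"].labels > 0) | (masks["fibre"].labels > 0)
        px = clean.data[structure]
        if px.shape[0] > per_stack_budget:
            sel = rng.choice(px.shape[0], size=per_stack_budget, replace=False)
            px = px[sel]
        pooled.append(px)
    pool = np.concatenate(pooled, axis=0)
    side = int(np.ceil(np.sqrt(pool.shape[0])))
    pad = np.zeros((side * side - pool.shape[0], pool.shape[1]))
    pool_stack = SpectralStack(
        data=np.concatenate([pool, pad], axis=0).reshape(side, side, -1)
    )
    endmembers, _, unmix_diag = fit_blind_unmixing(
        pool_stack,
        n_components=n_components,
        seed=seed,
        n_restarts=unmix_restarts,
        max_fit_pixels=unmix_max_pixels,
    )

    per_patient = []
    for entry, clean, masks in zip(entries, cleaned, masks_per_patient):
        abundances = unmix_known(clean, endmembers)
        per_patient.append((entry.record.patient_id, entry.record.group, abundances, masks))
    table = feat.build_feature_table(per_patient)
    qc = {
        "per_stack": qc_all,
        "unmix": {k: v for k, v in unmix_diag.items() if k != "restart_losses"},
        "pooled_pixels": int(pool.shape[0]),
    }
    return table, endmembers.spectra, qc


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing every declared output.

    Emits the cohort CSV, per-ROI feature CSV, group-comparison CSVs
    for both strata, a discriminant report (projection CSV, ROC CSV,
    AUC summary JSON, optional plots), CMYK renderings for one patient
    per encoder group, and the run manifest. Any stage failure aborts
    with the stage named.
    """
    state = {"stage": "init"}
    try:
        return _run_pipeline_impl(config, state)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {state['stage']!r} failed: {exc}") from exc


def _run_pipeline_impl(config: PipelineConfig, state: dict) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in ("synth", "unmix", "discriminate", "encoder")}
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    state["stage"] = "synth"
    spec = CohortSpec(
        scene=SceneParams(
            size=config.scene_size,
            n_cells=config.n_cells,
            n_fibres=config.n_fibres,
            snr_db=config.snr_db,
        ),
        n_channels=config.n_channels,
        seed=seeds["synth"],
    )
    entries = make_cohort(spec)
    cohort_csv = out / "cohort.csv"
    write_cohort_table([e.record for e in entries], cohort_csv)
    outputs["cohort_csv"] = str(cohort_csv)
    if config.save_stacks:
        stack_dir = out / "stacks"
        stack_dir.mkdir(exist_ok=True)
        for e in entries:
            write_stack(e.stack, stack_dir / f"{e.record.patient_id}.tif")
            write_brightfield(e.brightfield, stack_dir / f"{e.record.patient_id}_bf.tif")
        outputs["stack_dir"] = str(stack_dir)
    timings["synth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    state["stage"] = "preprocess/segment/unmix"
    table, endmember_spectra, qc = analyse_cohort(
        entries,
        seed=seeds["unmix"],
        n_components=config.n_components,
        unmix_restarts=config.unmix_restarts,
        unmix_max_pixels=config.unmix_max_pixels,
    )
    features_csv = out / "features.csv"
    table.to_csv(features_csv, index=False, float_format="%.10g")
    outputs["features_csv"] = str(features_csv)
    em_csv = out / "endmembers.csv"
    pd.DataFrame(
        endmember_spectra,
        index=["NAD(P)H", "flavins", "collagen"][: len(endmember_spectra)],
    ).to_csv(em_csv, float_format="%.10g")
    outputs["endmembers_csv"] = str(em_csv)
    timings["analyse"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    state["stage"] = "features"
    for stratum in ("cell", "fibre"):
        comp = feat.compare_all_groups(table, stratum)
        comp_csv = out / f"comparisons_{stratum}.csv"
        comp.to_csv(comp_csv, index=False, float_format="%.10g")
        outputs[f"comparisons_{stratum}_csv"] = str(comp_csv)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    state["stage"] = "discriminate"
    projection, roc = evaluate_pairwise(
        table,
        stratum=config.stratum,
        group_a=config.pair_a,
        group_b=config.pair_b,
        mode=config.evaluation_mode,
        seed=seeds["discriminate"],
    )
    proj_csv = out / "projection.csv"
    pd.DataFrame(
        {
            "canonical_1": projection.points[:, 0],
            "canonical_2": projection.points[:, 1],
            "group": projection.labels,
        }
    ).to_csv(proj_csv, index=False, float_format="%.10g")
    roc_csv = out / "roc.csv"
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        roc_csv, index=False, float_format="%.10g"
    )
    summary = {
        "stratum": config.stratum,
        "pair": [projection.group_names[0], projection.group_names[1]],
        "mode": config.evaluation_mode,
        "auc": roc.auc,
        "fisher_ratio": projection.fisher_ratio,
        "ellipses": {
            g: {"center": e.center.tolist(), "radii": e.radii.tolist()}
            for g, e in projection.ellipses.items()
        },
    }
    summary_json = out / "discrimination.json"
    with open(summary_json, "w") as fh:
        json.dump(summary, fh, indent=2)
    outputs.update(
        projection_csv=str(proj_csv), roc_csv=str(roc_csv), discrimination_json=str(summary_json)
    )
    if config.make_plots:
        outputs["plots"] = _plot_discrimination(projection, roc, out)
    timings["discriminate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    state["stage"] = "encoder"
    enc_groups = set(config.encoder_pair)
    train_px, train_groups = [], []
    group_example: dict[str, CohortEntry] = {}
    rng = np.random.default_rng(seeds["encoder"])
    for e in entries:
        gname = e.record.group.name
        if gname not in enc_groups:
            continue
        group_example.setdefault(gname, e)
        structure = (e.truth.cell_mask_true > 0) | (e.truth.fibre_mask_true > 0)
        px = e.stack.data[structure]
        budget = max(200, config.encoder_pixels // max(len(entries), 1))
        if px.shape[0] > budget:
            px = px[rng.choice(px.shape[0], size=budget, replace=False)]
        train_px.append(px)
        train_groups.append(np.full(px.shape[0], gname))
    model = enc.train_encoder(
        np.concatenate(train_px),
        np.concatenate(train_groups),
        enc.EncoderConfig(epochs=config.encoder_epochs, seed=seeds["encoder"]),
    )
    enc.save_model(model, str(out / "encoder_model.npz"))
    outputs["encoder_model"] = str(out / "encoder_model.npz")
    for gname, e in sorted(group_example.items()):
        cmyk = enc.encode_stack(e.stack, model)
        rgb = enc.render_cmyk(cmyk)
        png = out / f"cmyk_{gname}.png"
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            plt.imsave(png, rgb)
            outputs[f"cmyk_{gname}_png"] = str(png)
        except Exception:  # pragma: no cover - display-only artefact
            pass
    timings["encoder"] = time.perf_counter() - t0

    state["stage"] = "manifest"
    manifest = RunManifest(
        config=asdict(config),
        seeds={"global": config.seed, **seeds},
        outputs=outputs,
        qc={"unmix": qc["unmix"], "n_rois": int(len(table)), "auc": roc.auc},
        timings_s={k: round(v, 3) for k, v in timings.items()},
    )
    manifest.save(out / "manifest.json")
    return manifest


def _plot_discrimination(projection, roc, out: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for g in projection.group_names:
        sel = projection.labels == g
        ax1.scatter(projection.points[sel, 0], projection.points[sel, 1], s=10, label=g)
        e = projection.ellipses[g]
        theta = np.linspace(0, 2 * np.pi, 100)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        pts = e.center[:, None] + e.axes @ (e.radii[:, None] * circle)
        ax1.plot(pts[0], pts[1], lw=1)
        ax1.plot(*e.center, marker="+", ms=10, mew=2, color="k")
    ax1.set_xlabel("canonical variable 1")
    ax1.set_ylabel("canonical variable 2")
    ax1.legend(fontsize=7)
    ax2.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
    ax2.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax2.set_xlabel("false positive rate")
    ax2.set_ylabel("true positive rate")
    ax2.legend()
    fig.tight_layout()
    path = out / "discrimination.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
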