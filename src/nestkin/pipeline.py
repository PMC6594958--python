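"""Seeded end-to-end pipeline runs from a single YAML-able config.

A run config selects stages (imaging, cytometry, transcriptome) and carries
every stage parameter plus a global seed.  Each output table is written
with a leading ``# config_hash=...`` comment line so any artifact can be
traced to the exact configuration that produced it, and re-running an
identical config reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import (
    cell_cycle_fractions,
    gate_tdtomato,
    kinetics_table,
    split_egfp_tertiles,
)
from .nests import (
    NestConfig,
    apply_depth_guard,
    call_nests_from_objects,
    scale_total_nests,
    summaries_to_dataframe,
    summarize_nests,
)
from .simulate import (
    ContinuumSimConfig,
    FlowSimConfig,
    SubsetSpec,
    VolumeSimConfig,
    default_class_boundaries,
    simulate_counts,
    simulate_flow_events,
    simulate_testis_volume,
    simulate_unstained_control,
)
from .transcriptome import (
    LibraryFilterSpec,
    ResolutionSelectionError,
    annotate_clusters,
    cluster_graph,
    marker_stats,
    normalize_log,
    qc_filter,
    replicate_rv_table,
    select_germ_cells,
    select_resolution,
    zscore_genes,
)
from .volumes import DetectionConfig, classify_intensity, objects_to_dataframe, segment_objects

__all__ = ["validate_config", "run_pipeline", "config_hash", "write_table"]

KNOWN_STAGES = ("imaging", "cytometry", "transcriptome")


class ConfigError(ValueError):
    """The run config failed validation before any stage ran."""


def config_hash(config: Mapping[str, Any], seed: int) -> str:
    payload = json.dumps({"config": config, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: Path, chash: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_config(config: Mapping[str, Any]) -> None:
    """Schema checks that must pass before any stage executes."""
    unknown = set(config) - set(KNOWN_STAGES) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    if not any(s in config for s in KNOWN_STAGES):
        raise ConfigError("config selects no stage")
    imaging = config.get("imaging", {})
    if imaging.get("scale_totals") and not (
        "fca_table" in imaging or "simulate" in imaging
    ):
        raise ConfigError(
            "imaging.scale_totals requires an FCA table or a simulation "
            "config to supply per-class total cell counts"
        )
    for stage in KNOWN_STAGES:
        section = config.get(stage)
        if section is not None and not isinstance(section, Mapping):
            raise ConfigError(f"section {stage!r} must be a mapping")


def _volume_config(params: Mapping[str, Any]) -> VolumeSimConfig:
    params = dict(params)
    if "nest_size_distribution" in params and isinstance(
        params["nest_size_distribution"], Mapping
    ):
        params["nest_size_distribution"] = {
            int(k): float(v) for k, v in params["nest_size_distribution"].items()
        }
    for key in ("volume_shape_um", "voxel_size_um", "cell_diameter_um"):
        if key in params:
            params[key] = tuple(params[key])
    return VolumeSimConfig(**params)


def _run_imaging(section: Mapping[str, Any], seed: int, out: Path, chash: str) -> dict:
    sim_cfg = _volume_config(section.get("simulate", {}))
    det_cfg = DetectionConfig(**section.get("detection", {}))
    nest_cfg = NestConfig(**section.get("nests", {}))
    sim = simulate_testis_volume(sim_cfg, seed)
    objects = segment_objects(sim.egfp, det_cfg, cochannel=sim.tdtomato)
    boundaries = section.get("class_boundaries") or default_class_boundaries(sim_cfg)
    classify_intensity(objects, tuple(boundaries))

    summaries = []
    nest_rows = []
    partial = sim_cfg.imaged_depth_fraction < 1.0
    for cls in sorted(sim_cfg.n_nests_per_class):
        cls_objects = [o for o in objects if o.label == cls]
        if partial:
            # Edge correction: exclude the truncated bottom sections so nest
            # membership in the analysed region is unbiased before scaling.
            cls_objects = apply_depth_guard(
                cls_objects,
                sim_cfg.imaged_depth_fraction * sim_cfg.volume_shape_um[2],
                guard_um=nest_cfg.reference_cell_diameter_um,
            )
        nests, _ = call_nests_from_objects(cls_objects, nest_cfg)
        for nest in nests:
            nest_rows.append(dict(class_label=cls, nest_id=nest.id,
                                  n_objects=len(nest.member_ids),
                                  estimated_cell_count=nest.estimated_cell_count,
                                  mean_intensity=nest.mean_intensity))
        summary = summarize_nests(nests, cls_objects, nest_cfg, class_label=cls)
        if section.get("scale_totals"):
            truth_cells = sim.truth[
                (sim.truth["kind"] == "cell") & (sim.truth["class_label"] == cls)
            ]
            if summary.n_cells_total > 0:
                summary.scaled_total_nests = scale_total_nests(
                    summary.total_nests, summary.n_cells_total, len(truth_cells)
                )
        summaries.append(summary)

    write_table(objects_to_dataframe(objects), out / "objects.csv", chash)
    write_table(pd.DataFrame(nest_rows), out / "nests.csv", chash)
    write_table(summaries_to_dataframe(summaries), out / "nest_summary.csv", chash)
    return {
        "n_objects": len(objects),
        "n_nests": len(nest_rows),
        "outputs": ["objects.csv", "nests.csv", "nest_summary.csv"],
    }


def _flow_config(params: Mapping[str, Any]) -> FlowSimConfig:
    params = dict(params)
    subsets = {
        age: {name: SubsetSpec(**spec) if isinstance(spec, Mapping) else spec
              for name, spec in by_age.items()}
        for age, by_age in params.pop("subsets").items()
    }
    for key in ("tdtomato_germ_log", "tdtomato_background_log",
                "kit_positive_log", "kit_negative_log"):
        if key in params:
            params[key] = tuple(params[key])
    return FlowSimConfig(ages=list(params.pop("ages")), subsets=subsets, **params)


def _run_cytometry(section: Mapping[str, Any], seed: int, out: Path, chash: str) -> dict:
    sim_cfg = _flow_config(section["simulate"])
    gate_cfg = section.get("gate", {})
    events, _ = simulate_flow_events(sim_cfg, seed)
    control = simulate_unstained_control(sim_cfg, seed=seed + 1)
    egfp_threshold = gate_cfg.get(
        "egfp_positive_threshold", float(10 ** sim_cfg.egfp_log_min)
    )

    gate_rows, count_rows, cycle_rows = [], {}, {}
    for age in sim_cfg.ages:
        sample = events[events["age"] == age]
        germ, td_thr = gate_tdtomato(sample, control,
                                     quantile=gate_cfg.get("quantile", 0.995))
        gate = split_egfp_tertiles(germ, egfp_threshold,
                                   scale=gate_cfg.get("scale", "log"),
                                   tdtomato_threshold=td_thr)
        gate_rows.append(dict(age=age, tdtomato_threshold=td_thr,
                              egfp_threshold=egfp_threshold,
                              cut_dim_mid=gate.tertile_cutpoints[0],
                              cut_mid_bright=gate.tertile_cutpoints[1]))
        count_rows[age] = gate.counts()
        cyc = {}
        for subset, grp in germ.groupby(gate.labels):
            frac = cell_cycle_fractions(grp["dna_content"])
            cyc[subset] = frac["s_g2_m"] if not frac["undefined"] else np.nan
        cycle_rows[age] = cyc

    counts_by_age = pd.DataFrame(count_rows).T.loc[list(sim_cfg.ages)]
    s_by_age = pd.DataFrame(cycle_rows).T.reindex(
        index=list(sim_cfg.ages), columns=counts_by_age.columns
    )
    kin_cfg = section.get("kinetics", {})
    kinetics = kinetics_table(
        counts_by_age,
        cells_per_event=kin_cfg.get("cells_per_event", 1.0),
        plateau_tol=kin_cfg.get("plateau_tol", 0.15),
        plateau_run=kin_cfg.get("plateau_run", 2),
        s_g2_m_by_age=s_by_age,
    )
    write_table(pd.DataFrame(gate_rows), out / "gates.csv", chash)
    counts_out = counts_by_age.reset_index(names="age")
    write_table(counts_out, out / "subset_counts.csv", chash)
    write_table(kinetics, out / "kinetics.csv", chash)
    return {
        "n_events": len(events),
        "outputs": ["gates.csv", "subset_counts.csv", "kinetics.csv"],
    }


def _counts_config(params: Mapping[str, Any]) -> ContinuumSimConfig:
    params = dict(params)
    for key in ("library_size_log", "mito_beta", "rare_u_beta"):
        if key in params:
            params[key] = tuple(params[key])
    if "u_beta" in params:
        params["u_beta"] = {k: tuple(v) for k, v in params["u_beta"].items()}
    return ContinuumSimConfig(**params)


def _run_transcriptome(section: Mapping[str, Any], seed: int, out: Path, chash: str) -> dict:
    sim_cfg = _counts_config(section.get("simulate", {}))
    adata = simulate_counts(sim_cfg, seed)
    qc_cfg = section.get("qc", {})
    default_spec = LibraryFilterSpec(**qc_cfg.get("default", {}))
    specs = {lib: default_spec for lib in adata.obs["library"].unique()}
    for lib, params in qc_cfg.get("per_library", {}).items():
        specs[lib] = LibraryFilterSpec(**params)
    filtered, qc_report = qc_filter(adata, specs)
    germ = select_germ_cells(filtered)
    norm = normalize_log(germ)
    scaled = zscore_genes(norm)

    cl_cfg = section.get("cluster", {})
    n_pcs = cl_cfg.get("n_pcs", 20)
    k = cl_cfg.get("k", 15)
    grid = cl_cfg.get("resolution_grid")
    scan = None
    if grid:
        reference = scaled.obs_names[scaled.obs["rare"].to_numpy(dtype=bool)]
        resolution, result, scan = select_resolution(
            scaled, reference, grid,
            enrichment_min=cl_cfg.get("enrichment_min", 0.5),
            containment_min=cl_cfg.get("containment_min", 0.8),
            n_pcs=n_pcs, k=k, seed=seed,
        )
    else:
        result = cluster_graph(scaled, n_pcs=n_pcs, k=k,
                               resolution=cl_cfg.get("resolution", 0.6), seed=seed)

    stats = marker_stats(norm, result.labels)
    panels = {
        "ssc": list(sim_cfg.ssc_genes),
        "diff": list(sim_cfg.diff_genes),
    }
    scores, ident = annotate_clusters(stats, panels)
    rv = replicate_rv_table(norm)

    write_table(qc_report, out / "qc_report.csv", chash)
    labels_df = pd.DataFrame({"cell": result.labels.index, "cluster": result.labels.values})
    write_table(labels_df, out / "clusters.csv", chash)
    write_table(scores.reset_index(), out / "cluster_scores.csv", chash)
    write_table(rv, out / "replicate_rv.csv", chash)
    outputs = ["qc_report.csv", "clusters.csv", "cluster_scores.csv", "replicate_rv.csv"]
    if scan is not None:
        write_table(scan, out / "resolution_scan.csv", chash)
        outputs.append("resolution_scan.csv")
    return {
        "n_cells_pass_qc": int(qc_report["n_pass"].sum()),
        "n_clusters": int(result.labels.nunique()),
        "resolution": float(result.resolution),
        "ssc_like_cluster": int(ident["ssc_like"]) if "ssc_like" in ident else None,
        "outputs": outputs,
    }


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages in order and write a run manifest.

    ``seed`` overrides ``config['seed']`` (default 0).  Stages run in the
    fixed order imaging -> cytometry -> transcriptome; a stage failure is
    recorded in the manifest and later stages still run, so a partial run
    is auditable.  The manifest (JSON) lists the seed, config hash, package
    version and per-stage summaries.
    """
    validate_config(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config, seed)
    manifest: dict[str, Any] = {
        "seed": seed,
        "config_hash": chash,
        "version": __version__,
        "stages": {},
    }
    runners = {
        "imaging": _run_imaging,
        "cytometry": _run_cytometry,
        "transcriptome": _run_transcriptome,
    }
    for stage in KNOWN_STAGES:
        if stage not in config:
            continue
        try:
            summary = runners[stage](config[stage], seed, out / stage, chash)
            manifest["stages"][stage] = {"status": "ok", **summary}
        except ResolutionSelectionError as exc:
            manifest["stages"][stage] = {
                "status": "failed", "error": str(exc),
                "resolution_scan": exc.table.to_dict(orient="records"),
            }
        except Exception as exc:  # noqa: BLE001 — manifest records partial runs
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
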