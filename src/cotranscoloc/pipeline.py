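"""End-to-end pipeline runs: simulate -> segment -> detect -> enrich / coloc / ripq.

A run is driven by a single config mapping (YAML or JSON on disk). The
config is echoed alongside the outputs, every stage's parameters and
output-file hashes go into a machine-readable report, and one global
seed is split deterministically into per-stage streams, so identical
config + seed reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dualcolor, enrichment, io, ripqpcr, segmentation, spots as spotmod
from .datatypes import CellGeometry, SpotSet
from .synthetic import (
    CpSimParams,
    SceneParams,
    render_stacks,
    simulate_cp_table,
    simulate_scene,
)

STAGES = ("simulate", "segment", "detect", "enrich", "coloc", "ripq")

_TOP_KEYS = {"seed", "out_dir", "stages"} | set(STAGES)


class PipelineConfigError(ValueError):
    pass


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    bad = sorted(set(config) - _TOP_KEYS)
    if bad:
        raise PipelineConfigError(f"unknown config keys: {bad}")
    stages = config.get("stages", ["simulate"])
    bad_stages = [s for s in stages if s not in STAGES]
    if bad_stages:
        raise PipelineConfigError(f"unknown stages: {bad_stages}")
    for stage in STAGES:
        if stage in config and not isinstance(config[stage], dict):
            raise PipelineConfigError(f"stage section {stage!r} must be a mapping")
    scene_keys = {f.name for f in dataclasses.fields(SceneParams)}
    sim = config.get("simulate", {})
    bad_scene = sorted(set(sim.get("scene", {})) - scene_keys)
    if bad_scene:
        raise PipelineConfigError(f"unknown scene parameters: {bad_scene}")
    return config


def _stage_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([int(seed) % (2**31), idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _conditions(config: dict) -> list[dict]:
    conds = config.get("simulate", {}).get("conditions")
    return conds if conds else [{"name": "cond"}]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the requested stages in dependency order and write a report.

    Returns the report dict (also written to ``report.json`` in the output
    directory). Raises on schema violations or a missing upstream stage.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in config.get("stages", ["simulate"])]

    report: dict = {"seed": seed, "stages": [], "config": config, "warnings": []}
    caught: list[str] = []

    scenes: dict[str, object] = {}
    stacks: dict[str, dict] = {}
    geoms: dict[str, CellGeometry] = {}
    detected: dict[str, dict[str, SpotSet]] = {}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        report["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            }
        )

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if "simulate" in requested:
            sim_cfg = config.get("simulate", {})
            files = []
            for i, cond in enumerate(_conditions(config)):
                name = cond.get("name", f"cond{i}")
                overrides = {k: v for k, v in {**sim_cfg.get("scene", {}), **cond}.items()
                             if k != "name"}
                overrides.setdefault("seed", _stage_seed(seed, 100 + i))
                if "shape" in overrides:
                    overrides["shape"] = tuple(overrides["shape"])
                if "cell_radii_px" in overrides:
                    overrides["cell_radii_px"] = tuple(overrides["cell_radii_px"])
                if "nucleus_radii_px" in overrides:
                    overrides["nucleus_radii_px"] = tuple(overrides["nucleus_radii_px"])
                params = SceneParams(**overrides)
                scene = simulate_scene(params)
                chans, _ = render_stacks(scene)
                scenes[name], stacks[name] = scene, chans
                cdir = out / name
                cdir.mkdir(exist_ok=True)
                for cname, img in chans.items():
                    io.write_stack(cdir / f"{cname}.tif", img)
                    files.append(cdir / f"{cname}.tif")
                io.write_labels(cdir / "true_cells.tif", scene.geometry.cell_labels)
                io.write_labels(cdir / "true_nuclei.tif", scene.geometry.nucleus_labels)
                scene.write_ground_truth(cdir / "true_spots.csv")
                files += [cdir / "true_cells.tif", cdir / "true_nuclei.tif",
                          cdir / "true_spots.csv"]
                if "cptable" in sim_cfg:
                    cp_params = CpSimParams(**{**sim_cfg["cptable"],
                                               "seed": _stage_seed(seed, 200 + i)})
                    simulate_cp_table(cp_params).to_csv(cdir / "cp_table.csv", index=False)
                    files.append(cdir / "cp_table.csv")
            record("simulate", sim_cfg, files)

        if "segment" in requested:
            if not stacks:
                raise RuntimeError("segment stage requires outputs of stage 'simulate'")
            seg_cfg = config.get("segment", {})
            files = []
            for name, chans in stacks.items():
                dapi2d, _ = segmentation.focus_projection(
                    chans["dapi"], window=seg_cfg.get("window", 15)
                )
                fish2d, _ = segmentation.focus_projection(
                    chans["fish1"], window=seg_cfg.get("window", 15)
                )
                nuclei = segmentation.segment_nuclei(
                    dapi2d, min_area=seg_cfg.get("min_area", 50)
                )
                cells = segmentation.segment_cells(fish2d, nuclei)
                geoms[name] = segmentation.load_geometry(cells, nuclei)
                cdir = out / name
                io.write_labels(cdir / "seg_cells.tif", geoms[name].cell_labels)
                io.write_labels(cdir / "seg_nuclei.tif", geoms[name].nucleus_labels)
                files += [cdir / "seg_cells.tif", cdir / "seg_nuclei.tif"]
            record("segment", seg_cfg, files)

        if "detect" in requested:
            if not stacks:
                raise RuntimeError("detect stage requires outputs of stage 'simulate'")
            det_cfg = config.get("detect", {})
            files = []
            for name, chans in stacks.items():
                detected[name] = {}
                for chan in ("fish1", "fish2"):
                    if chan not in chans:
                        continue
                    ss = spotmod.detect_spots(
                        chans[chan],
                        sigma_xy=det_cfg.get("sigma_xy", 1.3),
                        sigma_z=det_cfg.get("sigma_z", 1.0),
                        threshold=det_cfg.get("threshold", 40.0),
                    )
                    detected[name][chan] = ss
                    ss.to_csv(out / name / f"spots_{chan}.csv")
                    files.append(out / name / f"spots_{chan}.csv")
            record("detect", det_cfg, files)

        if "enrich" in requested:
            enr_cfg = config.get("enrich", {})
            source = enr_cfg.get("spots", "detected")
            files, per_cond = [], {}
            for name in scenes:
                geom = geoms.get(name) or scenes[name].geometry
                if source == "detected":
                    if name not in detected:
                        raise RuntimeError("enrich stage requires outputs of stage 'detect'")
                    ss = detected[name]["fish1"]
                else:
                    ss = scenes[name].spots["ch1"]
                rows = []
                for cid in geom.analysable_cells():
                    try:
                        res = enrichment.enrichment_ratio(
                            stacks[name]["if"], ss, geom, cid,
                            min_spots=enr_cfg.get("min_spots", 5),
                            norm=enr_cfg.get("norm", "median"),
                        )
                    except enrichment.CellExcluded as exc:
                        caught.append(str(exc))
                        continue
                    rows.append(dataclasses.asdict(res))
                df = pd.DataFrame(rows)
                per_cond[name] = df
                df.to_csv(out / name / "enrichment.csv", index=False)
                files.append(out / name / "enrichment.csv")
            ks_rows = []
            names = list(per_cond)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    ra = per_cond[names[i]]["ratio"].to_numpy()
                    rb = per_cond[names[j]]["ratio"].to_numpy()
                    if len(ra) and len(rb):
                        d, p = enrichment.compare_ks(ra, rb)
                        ks_rows.append(dict(a=names[i], b=names[j], D=d, p=p))
            ks_df = pd.DataFrame(ks_rows)
            ks_df.to_csv(out / "ks_comparisons.csv", index=False)
            files.append(out / "ks_comparisons.csv")
            report["ks_comparisons"] = ks_rows
            record("enrich", enr_cfg, files)

        if "coloc" in requested:
            col_cfg = config.get("coloc", {})
            source = col_cfg.get("spots", "detected")
            d_max = col_cfg.get("d_max_nm", 300.0)
            files = []
            for name in scenes:
                geom = geoms.get(name) or scenes[name].geometry
                if source == "detected":
                    if name not in detected or "fish2" not in detected[name]:
                        raise RuntimeError(
                            "coloc stage requires two detected channels from stage 'detect'"
                        )
                    sa, sb = detected[name]["fish1"], detected[name]["fish2"]
                else:
                    sa, sb = scenes[name].spots["ch1"], scenes[name].spots["ch2"]
                rows = []
                for cid in geom.analysable_cells():
                    fa = spotmod.filter_spots(sa, geom, cid)
                    fb = spotmod.filter_spots(sb, geom, cid)
                    if len(fa) == 0 or len(fb) == 0:
                        continue
                    match = dualcolor.match_clouds(fa, fb, d_max)
                    frac = dualcolor.coloc_fraction(
                        match, reference=col_cfg.get("reference", "a")
                    )
                    row = dict(cell_id=cid, n_a=match.n_a, n_b=match.n_b,
                               n_pairs=match.n_pairs, fraction=frac)
                    if col_cfg.get("null", False):
                        _, p = dualcolor.randomization_null(
                            fa, fb, geom, cid, d_max_nm=d_max,
                            n_perm=col_cfg.get("n_perm", 199),
                            seed=_stage_seed(seed, 300 + cid),
                        )
                        row["null_p"] = p
                    rows.append(row)
                df = pd.DataFrame(rows)
                df.to_csv(out / name / "coloc.csv", index=False)
                files.append(out / name / "coloc.csv")
            record("coloc", col_cfg, files)

        if "ripq" in requested:
            rip_cfg = config.get("ripq", {})
            if "table" in rip_cfg:
                table = pd.read_csv(rip_cfg["table"])
            else:
                found = sorted(out.glob("*/cp_table.csv"))
                if not found:
                    raise RuntimeError(
                        "ripq stage requires a 'table' path or a simulated cp_table "
                        "from stage 'simulate'"
                    )
                table = pd.read_csv(found[0])
            records = ripqpcr.aggregate_replicates(
                table,
                statistic=rip_cfg.get("statistic", "percent_input"),
                reference_gene=rip_cfg.get("reference_gene"),
            )
            df = ripqpcr.records_to_frame(records)
            df.to_csv(out / "ripq_enrichment.csv", index=False)
            record("ripq", rip_cfg, [out / "ripq_enrichment.csv"])

        report["warnings"] = caught + [str(w.message) for w in wlist]

    (out / "config_echo.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
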