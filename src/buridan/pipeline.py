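"""End-to-end orchestration: ingest or simulate fly files, analyse, report.

``run_analysis`` reads every trajectory/metadata pair in a directory,
computes the twelve locomotor parameters per fly, applies the 50 mm/min
outlier filter, builds pooled transition plots per strain x replicate and
runs the PCA / ANOVA / Tukey grouping, writing a reproducible bundle
(metrics.csv, pca.json, anova.json, occupancy maps, boxplot_data.csv,
run.json).  The pipeline is a pure function of (input files, config):
re-running produces byte-identical outputs.

``run_simulate`` expands a YAML study specification into trajectory file
pairs plus a manifest of per-fly seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arena import ArenaConfig
from .errors import BuridanError, UsageError
from .io import (
    metrics_table,
    read_trajectory,
    write_metadata,
    write_metrics_table,
    write_trajectory,
)
from .kinematics import compute_steps, segment_bouts
from .metrics import metrics_from_steps
from .occupancy import occupancy, pool_maps, save_heatmap
from .simulate import FlyModelParams, StrainSpec, plan_study, simulate_study
from .stats import StrainGroupAnalyzer, boxplot_data, filter_outliers

__all__ = ["RunOptions", "run_analysis", "run_simulate"]

logger = logging.getLogger(__name__)


@dataclass
class RunOptions:
    """Tunable knobs of the analysis pipeline, with their canonical defaults."""

    immobility_speed_mm_s: float = 1.0
    min_pause_s: float = 1.0
    smooth_window: int = 0
    min_distance_per_min: float = 50.0
    component: int = 2
    alpha: float = 0.05
    bin_size_mm: float = 2.0
    sigma_bins: float = 1.0
    cap_fraction: float = 0.95
    make_maps: bool = True
    duration_tolerance: float = 0.05
    position_noise_mm: float = 2.0


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _config_hash(arena: ArenaConfig, options: RunOptions) -> str:
    blob = json.dumps(
        {"arena": dataclasses.asdict(arena), "options": dataclasses.asdict(options)},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _discover_pairs(input_dir: Path) -> list[tuple[Path, Path]]:
    pairs = []
    for data_path in sorted(input_dir.glob("*.csv")):
        meta_path = data_path.with_suffix(".yaml")
        if meta_path.exists():
            pairs.append((data_path, meta_path))
    return pairs


def run_analysis(
    input_dir,
    out_dir,
    arena: ArenaConfig | None = None,
    options: RunOptions | None = None,
) -> dict:
    """Run the full analysis over a directory of fly file pairs.

    Files that fail to parse are logged and skipped (and listed in the
    report); they are never silently dropped.  Raises
    :class:`UsageError` when no valid fly remains.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arena = arena or ArenaConfig()
    options = options or RunOptions()

    pairs = _discover_pairs(input_dir)
    if not pairs:
        raise UsageError(f"no trajectory/metadata pairs found in {input_dir}")

    rows = []
    per_fly_maps: dict[tuple[str, str], list] = {}
    skipped = []
    collected_warnings: list[str] = []
    for data_path, meta_path in pairs:
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                traj = read_trajectory(
                    data_path,
                    meta_path,
                    arena,
                    duration_tolerance=options.duration_tolerance,
                    position_noise_mm=options.position_noise_mm,
                )
                steps = compute_steps(
                    traj, options.immobility_speed_mm_s, options.smooth_window
                )
                seg = segment_bouts(steps, options.min_pause_s)
                rows.append(metrics_from_steps(traj.meta, steps, seg, arena))
            collected_warnings.extend(str(w.message) for w in wlist)
        except BuridanError as exc:
            logger.warning("skipping %s: %s", data_path.name, exc)
            skipped.append({"file": data_path.name, "error": str(exc)})
            continue
        if options.make_maps:
            occ = occupancy(
                traj,
                steps,
                arena,
                bin_size_mm=options.bin_size_mm,
                sigma_bins=options.sigma_bins,
                cap_fraction=options.cap_fraction,
            )
            key = (traj.meta.strain, traj.meta.replicate)
            per_fly_maps.setdefault(key, []).append(occ)

    if not rows:
        raise UsageError("no valid flies could be analysed")

    table = metrics_table(rows)
    write_metrics_table(table, out_dir / "metrics.csv")

    kept, excluded = filter_outliers(table, options.min_distance_per_min)
    for _, row in excluded.iterrows():
        collected_warnings.append(
            f"excluded fly {row['fly_id']} ({row['strain']}/{row['replicate']}): "
            f"distance {row['distance_per_min']:.1f} mm/min below "
            f"{options.min_distance_per_min:g} mm/min"
        )

    map_files = []
    if options.make_maps:
        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        for (strain, replicate), maps in sorted(per_fly_maps.items()):
            pooled = pool_maps(maps)
            stem = f"occupancy_{strain or 'NA'}_{replicate or 'NA'}"
            np.savetxt(maps_dir / f"{stem}.csv", pooled.grid, delimiter=",", fmt="%.8g")
            save_heatmap(pooled, maps_dir / f"{stem}.png", arena, f"{strain} {replicate}")
            map_files.append(f"maps/{stem}.png")

    stats_report = None
    analyzer = None
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            analyzer = StrainGroupAnalyzer(
                component=options.component, alpha=options.alpha
            ).fit(kept)
        collected_warnings.extend(str(w.message) for w in wlist)
    except BuridanError as exc:
        collected_warnings.append(f"group statistics skipped: {exc}")
        logger.warning("group statistics skipped: %s", exc)

    if analyzer is not None:
        pca = analyzer.pca_
        _write_json(
            {
                "explained_variance_fraction": pca.explained_variance_ratio_,
                "loadings": {
                    name: pca.loadings_[i].tolist()
                    for i, name in enumerate(pca.feature_names_)
                },
                "dropped_features": pca.dropped_features_,
                "scores": {
                    str(kept.loc[idx, "fly_id"]): analyzer.scores_.loc[idx].tolist()
                    for idx in analyzer.scores_.index
                },
            },
            out_dir / "pca.json",
        )
        stats_report = {
            "component": analyzer.report_.component,
            "shapiro_p": analyzer.shapiro_p_,
            "anova": analyzer.anova_table_.to_dict(orient="records"),
            "tukey": analyzer.tukey_.to_dict(orient="records"),
            "groups": analyzer.groups_,
            "letters": analyzer.letters_,
            "ambiguous_grouping": analyzer.grouping_["ambiguous"],
            "warnings": analyzer.warnings_,
        }
        _write_json(stats_report, out_dir / "anova.json")
        boxplot_data(kept).to_csv(out_dir / "boxplot_data.csv", index=False)

    report = {
        "package_version": __version__,
        "config_hash": _config_hash(arena, options),
        "arena": dataclasses.asdict(arena),
        "options": dataclasses.asdict(options),
        "n_files": len(pairs),
        "n_flies": len(table),
        "n_kept": len(kept),
        "excluded": excluded[["fly_id", "strain", "replicate", "distance_per_min"]].to_dict(
            orient="records"
        ),
        "skipped_files": skipped,
        "maps": map_files,
        "stats": stats_report,
        "warnings": collected_warnings,
    }
    _write_json(report, out_dir / "run.json")
    return report


def _parse_strain_spec(raw: dict, index: int) -> StrainSpec:
    if "name" not in raw:
        raise UsageError(f"strains[{index}] is missing 'name'")
    params_raw = raw.get("params", {})
    if not isinstance(params_raw, dict):
        raise UsageError(f"strains[{index}].params must be a mapping")
    known = set(FlyModelParams.__dataclass_fields__)
    unknown = set(params_raw) - known
    if unknown:
        raise UsageError(f"strains[{index}].params has unknown field(s): {sorted(unknown)}")
    params = FlyModelParams(**params_raw)
    kwargs = {"name": str(raw["name"]), "params": params}
    if "n_flies" in raw:
        kwargs["n_flies"] = int(raw["n_flies"])
    if "replicate_shifts" in raw:
        shifts = raw["replicate_shifts"]
        if not isinstance(shifts, (list, tuple)):
            raise UsageError(f"strains[{index}].replicate_shifts must be a list of mappings")
        kwargs["replicate_shifts"] = tuple(dict(s) for s in shifts)
    return StrainSpec(**kwargs)


def run_simulate(spec_file, out_dir, seed: int, arena: ArenaConfig | None = None) -> dict:
    """Simulate the study described in a YAML spec file and write fly file pairs.

    The manifest records the root seed and each fly's spawn index: fly k is
    reproducible alone via ``SeedSequence(seed, spawn_key=(k,))``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(spec_file) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "strains" not in raw:
        raise UsageError("study spec must be a mapping with a 'strains' list")
    strains = [_parse_strain_spec(s, i) for i, s in enumerate(raw["strains"])]
    replicate_labels = (
        tuple(str(r) for r in raw["replicates"]) if "replicates" in raw else None
    )
    arena = arena or ArenaConfig()

    trajectories = simulate_study(strains, seed, arena, replicate_labels)
    plan = plan_study(strains, replicate_labels)
    manifest = {"seed": int(seed), "n_flies": len(trajectories), "flies": []}
    for k, (traj, (params, _)) in enumerate(zip(trajectories, plan)):
        stem = traj.meta.fly_id
        write_trajectory(traj, out_dir / f"{stem}.csv")
        write_metadata(traj.meta, out_dir / f"{stem}.yaml")
        manifest["flies"].append(
            {
                "fly_id": stem,
                "strain": traj.meta.strain,
                "replicate": traj.meta.replicate,
                "spawn_index": k,
                "params": dataclasses.asdict(params),
            }
        )
    _write_json(manifest, out_dir / "manifest.json")
    return manifest
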