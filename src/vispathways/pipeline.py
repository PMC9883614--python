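"""Configured, seeded, logged orchestration of the full analysis pipeline.

Stages run in a fixed order -- simulate, preprocess, regions, decode,
granger, timegen -- with each stage reading the previous stage's on-disk
outputs, so a run is reproducible from its YAML config and master seed
alone.  Every run writes a JSON manifest recording the config snapshot,
derived per-stage seeds, and SHA-256 hashes of all written artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, decode, preprocess, regions, synthdata, timegen
from .containers import ConfigurationError, load_dataset, save_dataset

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "regions", "decode", "granger", "timegen")
_STAGE_SEED_TAGS = {name: i + 10 for i, name in enumerate(STAGE_ORDER)}

_TOP_KEYS = {
    "generator", "stages", "output_dir", "master_seed", "log_level",
    "preprocess", "regions", "decode", "granger", "timegen",
}
_GENERATOR_KEYS = {
    "n_participants", "n_categories", "n_exemplars", "n_reps", "sampling_rate",
    "epoch_window_ms", "stimulus_duration_ms", "region_signals", "couplings",
    "noise", "exemplar_scale", "pattern_drift", "drift_smooth_ms", "ramp_ms",
    "region_sizes", "seed",
}
_STAGE_KEYS = {
    "preprocess": {"abs_threshold", "baseline"},
    "regions": {"variance_retained"},
    "decode": {"region_pair", "n_folds", "n_boot", "alpha", "consecutive", "control"},
    "granger": {"region_pair", "max_lag_ms", "n_components"},
    "timegen": {"region_a", "region_b", "covariate", "window_ms", "window_increment", "top_k"},
}


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; valid keys: {sorted(allowed)}"
        )


def _generator_from_dict(d: dict) -> synthdata.GeneratorConfig:
    _check_keys(d, _GENERATOR_KEYS, "generator config")
    d = dict(d)
    if "region_signals" in d:
        d["region_signals"] = {
            r: synthdata.RegionSignal(**spec) for r, spec in d["region_signals"].items()
        }
    if "couplings" in d:
        d["couplings"] = tuple(synthdata.Coupling(**c) for c in d["couplings"])
    if "noise" in d:
        d["noise"] = synthdata.NoiseSpec(**d["noise"])
    if "epoch_window_ms" in d:
        d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
    return synthdata.GeneratorConfig(**d)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict keys, per-stage parameter blocks)."""

    generator: synthdata.GeneratorConfig = field(default_factory=synthdata.GeneratorConfig)
    stages: tuple[str, ...] = STAGE_ORDER
    output_dir: str = "vispathways_out"
    master_seed: int = 0
    log_level: str = "INFO"
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, _TOP_KEYS, "pipeline config")
        stages = tuple(d.get("stages", STAGE_ORDER))
        for s in stages:
            if s not in STAGE_ORDER:
                raise ConfigurationError(f"unknown stage {s!r}; valid stages: {STAGE_ORDER}")
        if int(d.get("master_seed", 0)) < 0:
            raise ConfigurationError("master_seed must be a non-negative integer")
        stage_params = {}
        for s, keys in _STAGE_KEYS.items():
            block = d.get(s, {})
            _check_keys(block, keys, f"{s} stage config")
            stage_params[s] = block
        return cls(
            generator=_generator_from_dict(d.get("generator", {})),
            stages=stages,
            output_dir=str(d.get("output_dir", "vispathways_out")),
            master_seed=int(d.get("master_seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
            stage_params=stage_params,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        return int(np.random.default_rng([self.master_seed, _STAGE_SEED_TAGS[stage]]).integers(2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _load_cohort(directory: Path, stage_needed: str):
    if not directory.exists():
        raise ConfigurationError(
            f"missing upstream output {directory}; run the {stage_needed!r} stage first"
        )
    stems = sorted(p.stem for p in directory.glob("*.h5"))
    return [load_dataset(directory, stem) for stem in stems]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "config": {
            "generator": asdict(config.generator) | {
                "region_signals": {r: asdict(s) for r, s in config.generator.region_signals.items()},
                "couplings": [asdict(c) for c in config.generator.couplings],
                "noise": asdict(config.generator.noise),
            },
            "stages": list(config.stages),
            "master_seed": config.master_seed,
            "stage_params": config.stage_params,
        },
        "seeds": {s: config.stage_seed(s) for s in config.stages},
        "stages": {},
    }
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    for stage in ordered:
        outputs = _STAGE_RUNNERS[stage](config, out)
        manifest["stages"][stage] = {
            "outputs": outputs,
            "hashes": {k: _sha256(Path(v)) for k, v in outputs.items() if Path(v).is_file()},
        }
        logger.info("stage %s complete: %s", stage, sorted(outputs))
    _write_json(out / "manifest.json", manifest)
    return manifest


# --------------------------- stage runners ---------------------------------

def _run_simulate(config: PipelineConfig, out: Path) -> dict:
    gen = synthdata.GeneratorConfig(
        **{**asdict(config.generator), "region_signals": config.generator.region_signals,
           "couplings": config.generator.couplings, "noise": config.generator.noise,
           "seed": config.generator.seed if config.generator.seed else config.stage_seed("simulate")},
    )
    cohort = synthdata.simulate_cohort(gen)
    outputs = {}
    for ds in cohort:
        paths = save_dataset(ds, out / "data", ds.participant_id)
        outputs.update({f"{ds.participant_id}_{k}": v for k, v in paths.items()})
    return outputs


def _run_preprocess(config: PipelineConfig, out: Path) -> dict:
    params = config.stage_params.get("preprocess", {})
    cohort = _load_cohort(out / "data", "simulate")
    outputs = {}
    for ds in cohort:
        ds2 = preprocess.reject_epochs_threshold(ds, params.get("abs_threshold", 100.0))
        if params.get("baseline", True):
            ds2 = preprocess.baseline_correct(ds2)
        paths = save_dataset(ds2, out / "preproc", ds2.participant_id)
        outputs.update({f"{ds2.participant_id}_{k}": v for k, v in paths.items()})
    return outputs


def _run_regions(config: PipelineConfig, out: Path) -> dict:
    params = config.stage_params.get("regions", {})
    cohort = _load_cohort(out / "preproc", "preprocess")
    report = regions.functional_distinctness(cohort, params.get("variance_retained", 0.95))
    dist_path = out / "regions_distances.csv"
    pd.DataFrame(
        report.channel_distance_matrix,
        index=cohort[0].montage.channel_ids,
        columns=cohort[0].montage.channel_ids,
    ).to_csv(dist_path)
    snr = {
        region: {
            "timecourse": float(np.mean([regions.snr_timecourse(ds, region) for ds in cohort])),
            "baseline": float(np.mean([regions.snr_baseline(ds, region) for ds in cohort])),
        }
        for region in cohort[0].montage.present_regions()
    }
    json_path = out / "regions_report.json"
    _write_json(json_path, {"purity": report.purity, "snr": snr})
    return {"distances": str(dist_path), "report": str(json_path)}


def _run_decode(config: PipelineConfig, out: Path) -> dict:
    params = config.stage_params.get("decode", {})
    cohort = _load_cohort(out / "preproc", "preprocess")
    pair = tuple(params.get("region_pair", ("dorsal", "ventral")))
    n_folds = params.get("n_folds", 100)
    n_boot = params.get("n_boot", 10000)
    alpha = params.get("alpha", 0.05)
    consecutive = params.get("consecutive", 2)
    seed = config.stage_seed("decode")

    outputs, summary = {}, {}
    onset_dists = {}
    for region in pair:
        res = decode.decode_cohort(cohort, region, n_folds=n_folds, fold_seed=seed)
        dist = decode.bootstrap_onsets(res, n_boot=n_boot, alpha=alpha,
                                       consecutive=consecutive, seed=seed)
        onset_dists[region] = dist
        acc_path = out / f"decode_accuracy_{region}.csv"
        pd.DataFrame(res.accuracy, columns=[f"{t:g}" for t in res.times]).to_csv(acc_path, index=False)
        onset_path = out / f"decode_onsets_{region}.csv"
        pd.DataFrame({"onset_ms": dist.onsets_ms}).to_csv(onset_path, index=False)
        outputs[f"accuracy_{region}"] = str(acc_path)
        outputs[f"onsets_{region}"] = str(onset_path)
        summary[region] = {
            "median_onset_ms": dist.median_onset_ms,
            "detection_rate": dist.detection_rate,
            "chance": res.chance,
        }
    summary["precedence"] = decode.precedence_binomial(
        onset_dists[pair[0]].onsets_ms, onset_dists[pair[1]].onsets_ms
    )
    control = params.get("control", "none")
    if control == "leave-category":
        lco = decode.leave_category_out(cohort, pair, n_resample=min(n_boot, 1000),
                                        seed=seed, n_folds=n_folds)
        summary["leave_category"] = {
            "pooled_precedence": lco["pooled_precedence"],
            "pooled_medians": lco["pooled_medians"],
        }
    elif control == "channel-resample":
        cr = decode.channel_resample(cohort, pair, n_resample=min(n_boot, 1000),
                                     seed=seed, n_folds=n_folds)
        summary["channel_resample"] = {"precedence": cr["precedence"]}
    elif control == "residualize":
        resid = decode.residualize(cohort, pair)
        res_summary = {}
        for region in pair:
            res = decode.decode_cohort(resid, region, n_folds=n_folds, fold_seed=seed)
            dist = decode.bootstrap_onsets(res, n_boot=n_boot, alpha=alpha,
                                           consecutive=consecutive, seed=seed)
            res_summary[region] = {"median_onset_ms": dist.median_onset_ms}
        summary["residualize"] = res_summary
    elif control != "none":
        raise ConfigurationError(f"unknown decode control {control!r}")

    json_path = out / "decode_summary.json"
    _write_json(json_path, summary)
    outputs["summary"] = str(json_path)
    return outputs


def _run_granger(config: PipelineConfig, out: Path) -> dict:
    params = config.stage_params.get("granger", {})
    cohort = _load_cohort(out / "preproc", "preprocess")
    pair = tuple(params.get("region_pair", ("dorsal", "ventral")))
    result = connectivity.group_granger(
        cohort, pair,
        max_lag_ms=params.get("max_lag_ms", 50.0),
        n_components=params.get("n_components", 10),
    )
    json_path = out / "granger_summary.json"
    _write_json(json_path, {
        "region_pair": list(pair),
        "group": result.group,
        "mean_f_difference": result.f_difference,
        "per_participant": [
            {"f_forward": r.f_forward, "f_backward": r.f_backward,
             "lag_forward_ms": r.lag_forward_ms, "lag_backward_ms": r.lag_backward_ms,
             "f_difference": r.f_difference}
            for r in result.per_participant
        ],
    })
    return {"summary": str(json_path)}


def _run_timegen(config: PipelineConfig, out: Path) -> dict:
    params = config.stage_params.get("timegen", {})
    cohort = _load_cohort(out / "preproc", "preprocess")
    region_a = params.get("region_a", "dorsal")
    region_b = params.get("region_b", "ventral")
    window = tuple(params.get("window_ms", (-48.0, 300.0)))

    per = timegen.timegen_cohort(cohort, region_a, region_b, window)
    stat = timegen.mirror_statistic(per)
    avg = timegen.timegen_cohort(cohort, region_a, region_b, window, average_participants=True)
    times = timegen.compute_rdm_series(cohort[0], region_a, window).times
    rr = timegen.rank_and_roll(avg, times,
                               window_increment=params.get("window_increment", 50),
                               top_k=params.get("top_k", 10))
    summary = {
        "mirror": {k: v for k, v in stat.items() if k != "per_participant"},
        "rolling": rr["rolling"][:20],
        "null_proportion": rr["null_proportion"],
        "top_k_forward_count": rr["top_k_forward_count"],
        "mean_delay_ms": rr["mean_delay_ms"],
    }
    covariate = params.get("covariate")
    if covariate:
        mats = []
        for ds in cohort:
            ra = timegen.compute_rdm_series(ds, region_a, window)
            rb = timegen.compute_rdm_series(ds, region_b, window)
            rc = timegen.compute_rdm_series(ds, covariate, window)
            mats.append(timegen.partial_timegen(ra, rb, rc))
        pstat = timegen.mirror_statistic(np.stack(mats))
        summary["partial_mirror"] = {k: v for k, v in pstat.items() if k != "per_participant"}

    mat_path = out / "timegen_matrix.csv"
    pd.DataFrame(avg, index=[f"{t:g}" for t in times], columns=[f"{t:g}" for t in times]).to_csv(mat_path)
    json_path = out / "timegen_summary.json"
    _write_json(json_path, summary)
    return {"matrix": str(mat_path), "summary": str(json_path)}


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "regions": _run_regions,
    "decode": _run_decode,
    "granger": _run_granger,
    "timegen": _run_timegen,
}


def summarize(manifest: dict | str | Path) -> str:
    """Human-readable report of a pipeline run from its manifest."""
    if not isinstance(manifest, dict):
        path = Path(manifest)
        try:
            manifest = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted manifest JSON {path}: {exc}") from exc
    lines = ["vispathways pipeline report", "=" * 28]
    stages = manifest.get("stages", {})

    def _load_stage_json(stage: str, key: str):
        entry = stages.get(stage)
        if not entry or key not in entry.get("outputs", {}):
            return None
        p = Path(entry["outputs"][key])
        if not p.is_file():
            return None
        try:
            return json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted JSON {p}: {exc}") from exc

    dec = _load_stage_json("decode", "summary")
    lines.append("\n[decode]")
    if dec is None:
        lines.append("  absent")
    else:
        for region, vals in dec.items():
            if isinstance(vals, dict) and "median_onset_ms" in vals:
                lines.append(f"  {region}: median onset {vals['median_onset_ms']:.1f} ms")
        if "precedence" in dec:
            pr = dec["precedence"]
            lines.append(
                f"  precedence: {pr['proportion_a_first']:.3f} first, p={pr['p_value']:.3g}"
            )
    gr = _load_stage_json("granger", "summary")
    lines.append("\n[granger]")
    if gr is None:
        lines.append("  absent")
    else:
        g = gr["group"]
        lines.append(
            f"  W={g['W']:.0f}, p={g['p']:.3g}, d={g['d']:.2f}, "
            f"mean F-difference={gr['mean_f_difference']:.4f}"
        )
    tg = _load_stage_json("timegen", "summary")
    lines.append("\n[timegen]")
    if tg is None:
        lines.append("  absent")
    else:
        m = tg["mirror"]
        lines.append(
            f"  mirror statistic: mean={m['mean']:.4f}, t={m['t']:.2f}, "
            f"p={m['p']:.3g}, d={m['d']:.2f}"
        )
        lines.append(f"  top-k mean delay: {tg['mean_delay_ms']:.1f} ms")
    return "\n".join(lines)
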