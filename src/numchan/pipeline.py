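"""End-to-end analysis pipeline and its run configuration.

``run_pipeline`` chains the stages — preprocess, covariance, channel-model
fits, cluster/factor structure, and (when duration trials are present) the
duration control — writing every intermediate artifact plus a JSON
manifest of seeds and parameters, so that any output is re-derivable from
the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channel_model import GridSpec, fit_channel_model
from .covariance import (DistanceBins, binned_correlation_curve,
                         distance_slope, shuffle_null, wf_correlation_matrix)
from .duration_control import (compare_task_precision, derive_duration_targets,
                               simulate_duration_trials)
from .preprocessing import (TRIAL_COLUMNS, WfMatrix, build_wf_matrix,
                            remove_outliers, reproduction_stats)
from .structure import (contiguity_null, factor_solution,
                        hierarchical_clusters, is_contiguous, loggaussian_fit)
from .synthetic_data import (TARGET_SET, ChannelModelConfig,
                             simulate_trial_table)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs, in one serialisable object."""

    condition: str = "fast"
    target_set: tuple[float, ...] = TARGET_SET
    bin_edges: tuple[float, ...] = (0.08, 0.14, 0.21, 0.29, 0.39)
    seed: int = 0
    n_iter_null: int = 10_000
    n_observers: int = 30
    channels: tuple[int, ...] = (1, 2)
    fit_n_experiments: int = 100
    fit_grid: str = "coarse"          # "coarse" | "default"
    mean_wf: float = 0.176
    generator: dict = field(default_factory=dict)  # ChannelModelConfig overrides
    outdir: str = "numchan_run"

    def grid_spec(self) -> GridSpec:
        return GridSpec.coarse() if self.fit_grid == "coarse" else GridSpec.default()

    def generator_config(self) -> ChannelModelConfig:
        """Generative config for 'simulate' input (defaults: two channels
        at the range extremes, study-scale parameters)."""
        base = ChannelModelConfig.two_channel(target_set=self.target_set,
                                              mean_wf=self.mean_wf)
        if self.generator:
            base = ChannelModelConfig.from_dict({**base.to_dict(), **self.generator})
        return base

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("target_set", "bin_edges", "channels"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("target_set", "bin_edges", "channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def run_pipeline(config: RunConfig, trials: str | Path | pd.DataFrame = "simulate",
                 duration_trials: str | Path | pd.DataFrame | None = None) -> dict:
    """Execute preprocess -> covariance -> fit -> structure (-> duration).

    ``trials`` is a CSV path, a trial DataFrame, or the string
    ``"simulate"`` to generate a cohort from ``config.generator_config()``.
    Returns a summary dict; all artifacts land under ``config.outdir``.
    Identical config and seed give identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "numchan_version": __version__,
        "config": _jsonable(asdict(config)),
        "stages": [],
    }
    summary: dict = {}
    bins = DistanceBins(config.bin_edges)

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("input")
        if isinstance(trials, (str, Path)) and str(trials) == "simulate":
            gen = config.generator_config()
            manifest["generator"] = gen.to_dict()
            trials_df = simulate_trial_table(gen, config.n_observers,
                                             seed=config.seed,
                                             condition=config.condition)
            trials_df.to_csv(out / "trials.csv", index=False)
        elif isinstance(trials, pd.DataFrame):
            trials_df = trials
        else:
            trials_df = pd.read_csv(trials)
        missing = [c for c in TRIAL_COLUMNS if c not in trials_df.columns]
        if missing:
            raise ValueError(f"trial table lacks columns {missing}")
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    try:
        stage("preprocess")
        cleaned, report = remove_outliers(trials_df)
        cleaned.to_csv(out / "trials_cleaned.csv", index=False)
        report.to_json(out / "cleaning_report.json")
        stats = reproduction_stats(cleaned)
        stats.to_csv(out / "reproduction_stats.csv", index=False)
        wfm = build_wf_matrix(stats, config.condition)
        wfm.to_csv(out / "wf_matrix.csv")
        summary["n_participants"] = wfm.n_participants
        summary["fraction_removed"] = report.fraction_removed
        summary["grand_mean_wf"] = float(wfm.values.mean())
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    try:
        stage("covariance")
        corr = wf_correlation_matrix(wfm)
        corr.to_csv(out / "corr_matrix.csv")
        curve = binned_correlation_curve(corr, bins)
        curve.to_csv(out / "binned_curve.csv", index=False)
        slope = distance_slope(corr)
        null = shuffle_null(wfm, n_iter=config.n_iter_null,
                            seed=config.seed + 1, bins=bins)
        _write_json(out / "shuffle_null.json", null.to_dict())
        lo, hi = null.slope_band()
        summary["slope"] = slope.slope
        summary["slope_stderr"] = slope.stderr
        summary["null_slope_band_95"] = [lo, hi]
        summary["distance_dependence"] = bool(slope.slope < lo or slope.slope > hi)
        _write_json(out / "slope.json",
                    {"slope": slope.slope, "stderr": slope.stderr,
                     "p_value_ols": slope.p_value,
                     "p_value_permutation": null.p_value})
    except Exception as exc:
        raise PipelineError("covariance", exc) from exc

    try:
        stage("fit")
        fits = {}
        for k in config.channels:
            fit = fit_channel_model(
                corr, mean_wf=config.mean_wf, n_channels=k,
                search=config.grid_spec(), n_observers=wfm.n_participants,
                n_experiments=config.fit_n_experiments,
                seed=config.seed + 2)
            fit.to_json(out / f"fit_{k}channel.json")
            fits[k] = fit
        summary["fit_r2"] = {str(k): f.r2 for k, f in fits.items()}
        if 1 in fits and 2 in fits:
            summary["two_channel_preferred"] = bool(fits[2].r2 > fits[1].r2)
    except Exception as exc:
        raise PipelineError("fit", exc) from exc

    try:
        stage("structure")
        clus = hierarchical_clusters(wfm)
        _write_json(out / "dendrogram.json", clus.merge_records())
        (out / "dendrogram.nwk").write_text(clus.to_newick() + "\n")
        cnull = contiguity_null(wfm, n_iter=config.n_iter_null,
                                seed=config.seed + 3)
        _write_json(out / "contiguity_null.json", cnull.to_dict())
        sol = factor_solution(wfm, rotation="promax")
        sol.to_frame().to_csv(out / "loadings.csv", index=False)
        lg = [loggaussian_fit(sol.loadings[:, k], sol.targets).to_dict()
              for k in range(sol.n_components)]
        _write_json(out / "loggaussian_fits.json", lg)
        summary["clusters"] = clus.clusters()
        summary["clusters_contiguous"] = is_contiguous(clus.labels)
        summary["contiguity_null_proportion"] = cnull.proportion_contiguous
        summary["n_components"] = sol.n_components
        summary["total_variance_explained"] = sol.total_variance_explained
        summary["component_peaks"] = [f["peak"] for f in lg]
    except Exception as exc:
        raise PipelineError("structure", exc) from exc

    if duration_trials is not None or (
            isinstance(trials, (str, Path)) and str(trials) == "simulate"):
        try:
            stage("duration")
            targets_tbl = derive_duration_targets(cleaned)
            targets_tbl.to_csv(out / "duration_targets.csv")
            if duration_trials is None:
                dur_df = simulate_duration_trials(targets_tbl,
                                                  seed=config.seed + 4)
            elif isinstance(duration_trials, pd.DataFrame):
                dur_df = duration_trials
            else:
                dur_df = pd.read_csv(duration_trials)
            dur_clean, dur_report = remove_outliers(
                dur_df, response_col="response_duration")
            dur_stats = reproduction_stats(dur_clean,
                                           response_col="response_duration")
            # duration targets are participant-specific: pair levels by rank
            n_levels = wfm.n_targets
            dur_pids = sorted(
                p for p, sub in dur_stats.groupby("participant_id")
                if len(sub) == n_levels and p in wfm.participants)
            if not dur_pids:
                raise ValueError("no participant has a complete duration set "
                                 "matching the number task")
            ranked = WfMatrix(
                participants=list(dur_pids),
                targets=np.arange(1.0, n_levels + 1),
                values=np.stack([
                    dur_stats.loc[dur_stats["participant_id"] == p]
                    .sort_values("target")["wf"].to_numpy()
                    for p in dur_pids
                ]),
                condition="duration",
            )
            num_sub = WfMatrix(
                participants=list(dur_pids), targets=wfm.targets,
                values=wfm.values[[wfm.participants.index(p)
                                   for p in dur_pids]],
                condition=wfm.condition)
            comp = compare_task_precision(num_sub, ranked)
            _write_json(out / "task_comparison.json", comp.to_dict())
            summary["mean_wf_number"] = comp.mean_wf_number
            summary["mean_wf_duration"] = comp.mean_wf_duration
            summary["duration_minus_number_wf"] = comp.mean_difference
        except Exception as exc:
            raise PipelineError("duration", exc) from exc

    manifest["summary"] = _jsonable(summary)
    _write_json(out / "manifest.json", manifest)
    return summary
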