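"""End-to-end orchestration: metrics -> states -> rates/levels -> active space.

One entry point, :func:`run_pipeline`, chains every stage on a collection
of tag datasets and returns both the result tables (ready for
``io.write_results``) and the fitted model objects for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import active_space as asp
from . import kinematics, states, vocal
from .io import RunConfig, TagDataset

__all__ = ["PipelineResult", "run_pipeline", "collect_dives_with_state"]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    scale: pd.DataFrame
    k_selected: int
    index_votes: dict[str, int]
    solution: states.ClusterSolution
    assignments: pd.DataFrame
    dive_models: list[states.DiveModelResult]
    rates_empirical: pd.DataFrame
    rate_models: list[vocal.RateModelResult]
    level_model: vocal.LevelModelResult | None
    detections: pd.DataFrame
    distance_model: dict | None
    surface: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "metrics": self.metrics,
            "states": self.assignments,
            "dive_models": states.dive_models_table(self.dive_models),
            "rates": self.rates_empirical,
            "rate_model": vocal.rate_tables(self.rate_models),
            "detections": self.detections,
            "distance_surface": self.surface,
        }
        if self.level_model is not None:
            out["level_model"] = self.level_model.contrast.assign(
                resting_mean_db=self.level_model.lsmeans["estimate"].iloc[0],
                travelling_mean_db=self.level_model.lsmeans["estimate"].iloc[1],
            )
        if self.distance_model is not None:
            out["distance_model"] = self.distance_model["contrast"].assign(
                resting_m=self.distance_model["lsmeans"]["distance_m"].iloc[0],
                travelling_m=self.distance_model["lsmeans"]["distance_m"].iloc[1],
            )
        return out


def collect_dives_with_state(
    datasets: list[TagDataset],
    assignments: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Adult-female deep dives, each carrying the state of the bin holding
    its start (dives starting in unlabelled bins are dropped)."""
    bl = config.bin_length_s
    amap = {
        (str(r["tag_id"]), int(r["bin_index"])): r["state"]
        for _, r in assignments.iterrows()
    }
    rows = []
    for ds in datasets:
        t = ds.depth["t_s"].to_numpy(float)
        d = ds.depth["depth_m"].to_numpy(float)
        dives, _ = kinematics.segment_dives(t, d, config)
        for dv in dives:
            b = int(np.floor((dv.t_start - ds.follow_start) / bl))
            state = amap.get((str(ds.tag_id), b))
            rows.append(
                {
                    "tag_id": ds.tag_id,
                    "bin_index": b,
                    "t_start": dv.t_start,
                    "duration": dv.duration,
                    "mean_depth": dv.mean_depth,
                    "max_depth": dv.max_depth,
                    "state": state,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    datasets: list[TagDataset] | dict[str, TagDataset],
    tl_table: pd.DataFrame,
    config: RunConfig | None = None,
    k_override: int | None = None,
    fit_dive_models: bool = True,
) -> PipelineResult:
    """Run the full analysis on a set of tag datasets.

    Stages: per-bin movement metrics; standardization; cluster-count vote
    (unless ``k_override``); k-means with state labelling; binomial dive
    models (k = 2 only); empirical and model-based state call rates per age
    class; the adult-female received-level model; detection distances under
    the supplied transmission-loss table; and the gamma state model of
    detection distance.
    """
    config = config or RunConfig()
    if isinstance(datasets, dict):
        datasets = list(datasets.values())
    metrics = pd.concat(
        [kinematics.build_metric_table(ds, config) for ds in datasets],
        ignore_index=True,
    )
    included = metrics[metrics["excluded"] == 0].reset_index(drop=True)
    std, scale = states.standardize_metrics(included)
    if k_override is None:
        k, votes = states.select_cluster_count(std, seed=config.seed)
    else:
        k, votes = k_override, {}
    solution, assignments = states.cluster_and_label(std, included, k, seed=config.seed)

    dive_models: list[states.DiveModelResult] = []
    rate_models: list[vocal.RateModelResult] = []
    level_model = None
    distance_model = None
    rates_emp = pd.DataFrame()
    detections = pd.DataFrame()
    surface = pd.DataFrame()

    if k == 2:
        state_bins = included[["tag_id", "bin_index", "t_start_s"]].merge(
            assignments[["tag_id", "bin_index", "state"]],
            on=["tag_id", "bin_index"],
        )
        dives = collect_dives_with_state(datasets, assignments, config)
        if fit_dive_models and len(dives) and dives["tag_id"].nunique() >= 2:
            dive_models = states.rank_dive_models(dives)

        all_calls = pd.concat([ds.calls for ds in datasets], ignore_index=True)
        counts = vocal.bin_call_counts(all_calls, state_bins, config)
        rates_emp = vocal.compute_call_rates(counts)
        for ac in vocal.AGE_CLASSES:
            if counts[counts["age_class"] == ac]["count"].sum() > 0:
                rate_models.append(vocal.fit_rate_model(counts, ac))

        # per-call state: state of the bin containing the call
        def call_state(row):
            b = int(np.floor((row["t_s"] - follow_start[str(row["tag_id"])])
                             / config.bin_length_s))
            return amap.get((str(row["tag_id"]), b))

        follow_start = {str(ds.tag_id): ds.follow_start for ds in datasets}
        amap = {
            (str(r["tag_id"]), int(r["bin_index"])): r["state"]
            for _, r in assignments.iterrows()
        }
        calls_state = all_calls.copy()
        if len(calls_state):
            calls_state["state"] = calls_state.apply(call_state, axis=1)
            if (
                calls_state.loc[calls_state["age_class"] == "adult_female", "state"]
                .notna()
                .sum()
                >= 4
            ):
                level_model = vocal.fit_level_model(calls_state)

        det_parts = []
        for ds in datasets:
            if not len(ds.calls):
                continue
            det = asp.estimate_detection_distances(ds.calls, ds.noise, tl_table, config)
            det_parts.append(det)
        if det_parts:
            detections = pd.concat(det_parts, ignore_index=True)
            detections["state"] = detections.apply(call_state, axis=1)
            surface = asp.distance_surface_summary(detections)
            ok = detections.dropna(subset=["distance_m", "state"])
            if len(ok) >= 8 and ok["tag_id"].nunique() >= 2:
                distance_model = asp.fit_detection_distance_model(detections)

    return PipelineResult(
        metrics=metrics,
        scale=scale,
        k_selected=k,
        index_votes=votes,
        solution=solution,
        assignments=assignments,
        dive_models=dive_models,
        rates_empirical=rates_emp,
        rate_models=rate_models,
        level_model=level_model,
        detections=detections,
        distance_model=distance_model,
        surface=surface,
    )
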