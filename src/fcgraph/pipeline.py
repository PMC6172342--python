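"""Survey orchestration: clustering x edge definition x threshold x subgraph.

Runs the full pipeline on a synthetic cohort — simulate, parcellate,
connect, compute graph features per threshold and subgraph, score each
combination by leave-one-out negative surprise — and collects the feature
table, surprise summary and significance scan.  Combinations whose graphs
disconnect (or whose rich club is too small) are skipped and logged, and a
survey writing to an output directory is resumable per combination.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from fcgraph.cohort import (
    SubjectVolume,
    SyntheticConfig,
    make_atlas_labels,
    simulate_cohort,
)
from fcgraph.connectivity import EDGE_PRESETS, build_graph
from fcgraph.errors import EmptyParcellationError
from fcgraph.evaluation import CONDITION_PAIRS, significance_scan, svm_pairwise_loo
from fcgraph.metrics import (
    feature_vector,
    is_connected,
    rich_club_subgraph,
    threshold_graph,
)
from fcgraph.model import Hyperparams, loo_evaluate
from fcgraph.parcellation import (
    atlas_parcellate,
    extract_mean_timeseries,
    parcellation_summary,
    rgs_parcellate,
    ward_parcellate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SurveyResult",
    "run_survey",
    "default_pipeline_config",
    "combination_svm_accuracies",
]

_FAMILY = {"ward": "ward", "rgs": "RGS", "atlas": "atlas"}

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass
class PipelineConfig:
    """Full survey configuration.

    ``clustering_presets`` maps a preset name to its parameters, e.g.
    ``{"method": "ward", "k": 8, "p": 4}``, ``{"method": "atlas",
    "n_regions": 8}`` or ``{"method": "rgs", "T": 0.75, "p": 8}``;
    ``edge_presets`` names entries of EDGE_PRESETS (Table-style variants
    BcorrU1 ... BTED2).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    clustering_presets: dict[str, dict] = field(
        default_factory=lambda: {
            "sward1": {"method": "ward", "k": 8, "p": 4},
            "satlas": {"method": "atlas", "n_regions": 8},
        }
    )
    edge_presets: tuple[str, ...] = ("BcorrU1", "BMITU1")
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    subgraphs: tuple[str, ...] = ("full", "rich")
    rich_fraction: float = 0.1
    nu0: float | None = None
    prior: dict[str, float] | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.clustering_presets or not self.edge_presets:
            raise ValueError("presets must be non-empty")
        names = list(self.clustering_presets) + list(self.edge_presets)
        if len(set(names)) != len(names):
            raise ValueError("preset names must be unique")
        for name in self.edge_presets:
            if name not in EDGE_PRESETS:
                raise ValueError(f"unknown edge preset {name!r}")
        if not self.thresholds:
            raise ValueError("threshold grid must be non-empty")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["synthetic"]["coupling"] = {
            c: np.asarray(m).tolist() for c, m in self.synthetic.coupling.items()
        }
        payload["synthetic"]["grid_shape"] = list(self.synthetic.grid_shape)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        syn = payload.pop("synthetic")
        syn["grid_shape"] = tuple(syn["grid_shape"])
        syn["coupling"] = {c: np.asarray(m) for c, m in syn.get("coupling", {}).items()}
        payload["edge_presets"] = tuple(payload["edge_presets"])
        payload["thresholds"] = tuple(payload["thresholds"])
        payload["subgraphs"] = tuple(payload["subgraphs"])
        return cls(synthetic=SyntheticConfig(**syn), **payload)


def default_pipeline_config(**overrides) -> PipelineConfig:
    """Synthetic-scale default survey that runs in minutes on one CPU."""
    return PipelineConfig(**overrides)


@dataclass
class SurveyResult:
    feature_table: pd.DataFrame
    surprise_table: pd.DataFrame
    significance: pd.DataFrame
    node_stats: pd.DataFrame
    skipped: list[dict]
    config: PipelineConfig

    @property
    def n_requested(self) -> int:
        return len(self.surprise_table) + len(self.skipped)


def _parcellate(
    name: str, params: dict, subject: SubjectVolume, config: PipelineConfig
):
    method = params["method"]
    if method == "ward":
        return ward_parcellate(subject, params["k"], params["p"], method_tag=name)
    if method == "rgs":
        return rgs_parcellate(subject, params["T"], params["p"], method_tag=name)
    if method == "atlas":
        labels = make_atlas_labels(config.synthetic, params.get("n_regions", 8))
        parc = atlas_parcellate(subject, labels)
        parc.method_tag = name
        return parc
    raise ValueError(f"unknown clustering method {method!r}")


def run_survey(config: PipelineConfig) -> SurveyResult:
    """Execute the full survey; returns tables and the skip log.

    Partial failures are isolated per combination: a combination whose
    graphs disconnect after thresholding, or whose rich club is degenerate,
    is marked skipped and the survey continues.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        (out_dir / "combinations").mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(config.synthetic)
    t = config.synthetic.n_timepoints

    rows: list[dict] = []
    surprise_rows: list[dict] = []
    skipped: list[dict] = []
    node_stat_rows: list[dict] = []

    for cl_name, cl_params in config.clustering_presets.items():
        family = _FAMILY[cl_params["method"]]
        parcs = {}
        ts = {}
        for subj in cohort:
            try:
                parc = _parcellate(cl_name, cl_params, subj, config)
            except EmptyParcellationError as exc:
                logger.warning("%s/%s: %s", cl_name, subj.subject_id, exc)
                continue
            parcs[subj.subject_id] = parc
            ts[subj.subject_id] = extract_mean_timeseries(subj, parc)
            stats = parcellation_summary(parc, subj)
            node_stat_rows.append(
                {
                    "clustering": cl_name,
                    "subject": subj.subject_id,
                    "condition": subj.condition,
                    "n_nodes": stats.n_nodes,
                    "mean_voxels_per_node": stats.mean_voxels_per_node,
                    "mean_heterogeneity": stats.mean_heterogeneity,
                }
            )
        for edge_name in config.edge_presets:
            spec = EDGE_PRESETS[edge_name]
            spec_eff = replace(spec, window_length=min(spec.window_length, t))
            graphs = {
                sid: build_graph(series, spec_eff) for sid, series in ts.items()
            }
            for wmin in config.thresholds:
                for subgraph in config.subgraphs:
                    combo = f"{cl_name}_{edge_name}_w{wmin:g}_{subgraph}"
                    cache = (
                        out_dir / "combinations" / f"{combo}.csv" if out_dir else None
                    )
                    combo_rows = None
                    if cache is not None and cache.exists():
                        combo_rows = pd.read_csv(cache).to_dict("records")
                    if combo_rows is None:
                        combo_rows, reason = _compute_combination(
                            cohort, graphs, cl_name, family, edge_name, spec,
                            wmin, subgraph, config,
                        )
                        if reason is not None:
                            skipped.append(
                                {"combination": combo, "reason": reason}
                            )
                            continue
                        if cache is not None:
                            pd.DataFrame(combo_rows).to_csv(cache, index=False)
                    rows.extend(combo_rows)
                    surprise_rows.append(
                        _score_combination(combo_rows, cl_name, family, edge_name,
                                           spec, wmin, subgraph, config)
                    )

    feature_table = pd.DataFrame(rows)
    surprise_table = pd.DataFrame(surprise_rows)
    significance = (
        significance_scan(feature_table) if len(feature_table) else pd.DataFrame()
    )
    node_stats = pd.DataFrame(node_stat_rows)
    result = SurveyResult(
        feature_table=feature_table,
        surprise_table=surprise_table,
        significance=significance,
        node_stats=node_stats,
        skipped=skipped,
        config=config,
    )
    if out_dir:
        feature_table.to_csv(out_dir / "features.csv", index=False)
        surprise_table.to_csv(out_dir / "surprise.csv", index=False)
        significance.to_csv(out_dir / "significance.csv", index=False)
        node_stats.to_csv(out_dir / "node_stats.csv", index=False)
        (out_dir / "skipped.json").write_text(json.dumps(skipped, indent=2))
        config.to_json(out_dir / "config.json")
    return result


def _compute_combination(
    cohort, graphs, cl_name, family, edge_name, spec, wmin, subgraph, config
):
    """Feature rows for one combination, or a skip reason."""
    combo_rows = []
    for subj in cohort:
        if subj.subject_id not in graphs:
            continue
        g = threshold_graph(graphs[subj.subject_id], wmin)
        if subgraph == "rich":
            try:
                g = rich_club_subgraph(g, config.rich_fraction)
            except ValueError as exc:
                return None, f"rich club degenerate: {exc}"
        if not is_connected(g):
            return None, f"graph disconnected for subject {subj.subject_id}"
        fv = feature_vector(g)
        row = {
            "subject": subj.subject_id,
            "condition": subj.condition,
            "clustering": cl_name,
            "clustering_family": family,
            "edge": edge_name,
            "edge_family": spec.family,
            "w_min": wmin,
            "subgraph": subgraph,
        }
        row.update({name: val for name, val in zip(fv.names, fv.values)})
        combo_rows.append(row)
    if not combo_rows:
        return None, "no subject produced features"
    return combo_rows, None


_META_COLS = (
    "subject",
    "condition",
    "clustering",
    "clustering_family",
    "edge",
    "edge_family",
    "w_min",
    "subgraph",
)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def _score_combination(
    combo_rows, cl_name, family, edge_name, spec, wmin, subgraph, config
):
    df = pd.DataFrame(combo_rows)
    feat_cols = feature_columns(df)
    by_condition = {
        cond: chunk[feat_cols].to_numpy(dtype=float)
        for cond, chunk in df.groupby("condition")
    }
    d = len(feat_cols)
    hyper = Hyperparams.default(d, nu0=config.nu0)
    loo = loo_evaluate(by_condition, hyper, config.prior)
    return {
        "clustering": cl_name,
        "clustering_family": family,
        "edge": edge_name,
        "edge_family": spec.family,
        "w_min": wmin,
        "subgraph": subgraph,
        "mean_surprise": loo.mean_surprise,
        "n_subjects": len(loo.surprises),
        "caveat": "statistical-model fit questionable for directed H2"
        if (spec.family == "H2" and spec.directed)
        else "",
    }


def combination_svm_accuracies(
    feature_table: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = CONDITION_PAIRS,
) -> pd.DataFrame:
    """Pairwise leave-one-out SVM accuracy per method combination."""
    feat_cols = feature_columns(feature_table)
    rows = []
    combo_cols = ["clustering", "clustering_family", "edge", "edge_family",
                  "w_min", "subgraph"]
    for combo, chunk in feature_table.groupby(combo_cols):
        for pair in pairs:
            sel = chunk[chunk["condition"].isin(pair)]
            x = sel[feat_cols].to_numpy(dtype=float)
            y = sel["condition"].to_numpy()
            acc, chosen = svm_pairwise_loo(x, y)
            row = dict(zip(combo_cols, combo))
            row.update(
                {"pair": f"{pair[0]}-{pair[1]}", "accuracy": acc,
                 "n_features": len(chosen)}
            )
            rows.append(row)
    return pd.DataFrame(rows)
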