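"""End-to-end orchestration: simulate -> features -> classify -> synapse -> intrinsic.

A :class:`RunConfig` (YAML-serializable) fixes every seed, cohort size,
scenario and analysis window, so a run is reproducible bit-for-bit.  Stages
communicate only through their documented output files / return values, and
each stage failure is reported with the stage name and the offending
cell/pair id.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .classify import classify_cohort, compare_groups, silhouette_diagnostics
from .exceptions import PairclampError
from .features import FEATURE_REGISTRY, build_feature_matrix, extract_features
from .intrinsic import analyze_intrinsic, category_counts, normalized_time_course
from .params import (
    ModulationScenario,
    PairProtocol,
    StepProtocol,
)
from .recordings import write_container, write_ground_truth
from .simulate import simulate_connection_cohort, simulate_step_cohort
from .synapse import (
    cohort_statistics,
    correlate_predictors,
    analyze_connection,
    summaries_to_frame,
)

log = logging.getLogger("pairclamp")


@dataclass
class ScenarioSpec:
    mechanism: str = "none"
    scale_factor: float = 1.0
    leak_scale: float = 1.0
    count: int = 3

    def build(self, onset_time: float, washout_time: Optional[float]) -> ModulationScenario:
        return ModulationScenario(
            mechanism=self.mechanism,
            scale_factor=self.scale_factor if self.mechanism != "none" else 1.0,
            leak_scale=self.leak_scale,
            onset_time=onset_time,
            washout_time=washout_time,
        )


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed_simulation: int = 1
    seed_embedding: int = 42
    seed_clustering: int = 42
    alpha: float = 0.05
    n_fs_cells: int = 12
    n_nonfs_cells: int = 12
    scenarios: list[ScenarioSpec] = field(
        default_factory=lambda: [
            ScenarioSpec("none", count=3),
            ScenarioSpec("presynaptic_p_scale", scale_factor=1.3, count=3),
            ScenarioSpec("postsynaptic_q_scale", scale_factor=1.3, count=3),
            ScenarioSpec("leak_block", leak_scale=0.865, count=3),
        ]
    )
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline": (-200.0, 0.0), "agonist": (60.0, 260.0)}
    )
    washout_time: Optional[float] = None
    step_protocol: StepProtocol = field(default_factory=StepProtocol)
    pair_protocol: PairProtocol = field(default_factory=PairProtocol)

    @property
    def onset_time(self) -> float:
        return self.pair_protocol.n_sweeps_baseline * self.pair_protocol.sweep_period

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "scenarios" in d:
            d["scenarios"] = [ScenarioSpec(**s) for s in d["scenarios"]]
        if "step_protocol" in d and isinstance(d["step_protocol"], dict):
            d["step_protocol"] = StepProtocol(**d["step_protocol"])
        if "pair_protocol" in d and isinstance(d["pair_protocol"], dict):
            d["pair_protocol"] = PairProtocol(**d["pair_protocol"])
        if "windows" in d:
            d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage(name: str):
    """Decorator: annotate stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PairclampError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def _run_simulation(config: RunConfig):
    fs_recs, fs_params = simulate_step_cohort(
        config.n_fs_cells, "FS", config.seed_simulation, config.step_protocol
    )
    non_recs, non_params = simulate_step_cohort(
        config.n_nonfs_cells, "nonFS", config.seed_simulation + 1, config.step_protocol
    )
    pairs = []
    seed = config.seed_simulation + 2
    for spec in config.scenarios:
        def factory(i, rng, _spec=spec):
            return _spec.build(config.onset_time, config.washout_time)

        pairs.extend(
            simulate_connection_cohort(
                spec.count, "FS", factory, seed, protocol=config.pair_protocol
            )
        )
        seed += 1
    # give every pair a unique id (scenario cohorts reuse indices)
    for j, (rec, truth) in enumerate(pairs):
        rec.pair_id = f"pair_{j:03d}"
        truth.pair_id = rec.pair_id
    return fs_recs + non_recs, pairs


@_stage("features")
def _run_features(cells):
    feats = {}
    for rec in cells:
        try:
            feats[rec.cell_id] = extract_features(rec)
        except PairclampError as exc:
            raise RuntimeError(f"feature extraction failed for cell {rec.cell_id}: {exc}")
    return build_feature_matrix(feats)


@_stage("classify")
def _run_classify(matrix, config: RunConfig):
    emb, result = classify_cohort(
        matrix, embed_seed=config.seed_embedding, cluster_seed=config.seed_clustering
    )
    comparison = compare_groups(matrix, result.labels)
    diagnostics = silhouette_diagnostics(emb, seed=config.seed_clustering)
    return emb, result, comparison, diagnostics


@_stage("synapse")
def _run_synapse(pairs, config: RunConfig):
    summaries = []
    for rec, truth in pairs:
        s = analyze_connection(
            rec,
            onset_time=config.onset_time,
            windows=config.windows,
            alpha=config.alpha,
            group=truth.synapse and "FS",
        )
        summaries.append((s, truth))
    only = [s for s, _ in summaries]
    cohort = cohort_statistics(only) if only else {"n": 0, "categories": {}}
    try:
        correlations = correlate_predictors(only) if len(only) >= 3 else {}
    except PairclampError:
        correlations = {}
    return summaries, cohort, correlations


@_stage("intrinsic")
def _run_intrinsic(pairs, config: RunConfig):
    out = []
    for rec, truth in pairs:
        if truth.scenario.mechanism == "none":
            continue  # no defined onset; holding stays baseline throughout
        out.append(analyze_intrinsic(rec, onset=config.onset_time, alpha=config.alpha))
    return out


def run_all(config: RunConfig, out_dir) -> dict[str, Any]:
    """Execute every stage and write the report bundle into ``out_dir``.

    Returns the machine-readable results dictionary (also written as
    ``results.json``).  With zero configured connections the synapse and
    intrinsic stages emit empty tables and a warning, not an error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run_all: seeds sim=%d embed=%d cluster=%d (pairclamp %s)",
             config.seed_simulation, config.seed_embedding, config.seed_clustering,
             _pkg_version)

    cells, pairs = _run_simulation(config)
    write_container(out_dir / "recordings.h5", cells=cells, pairs=[r for r, _ in pairs])
    write_ground_truth(out_dir / "ground_truth.json", [t for _, t in pairs])

    matrix = _run_features(cells)
    matrix.to_csv(out_dir / "features_raw.csv", out_dir / "features_scaled.csv")
    (out_dir / "features_meta.json").write_text(
        json.dumps(
            {"flags": matrix.flags, "bounds": matrix.bounds.to_dict()}, indent=1, default=str
        )
    )

    emb, cls_result, comparison, sil_diag = _run_classify(matrix, config)
    labels_df = pd.DataFrame(
        {
            "cell_id": cls_result.cell_ids,
            "cluster": cls_result.cluster,
            "label": cls_result.labels,
            "silhouette": cls_result.silhouette_per_cell,
            "umap_1": emb.coords[:, 0],
            "umap_2": emb.coords[:, 1],
        }
    )
    labels_df.to_csv(out_dir / "labels.csv", index=False)
    comparison.to_csv(out_dir / "group_comparison.csv")

    if not pairs:
        log.warning("no connections configured; synapse/intrinsic tables are empty")
        summaries, cohort, correlations, intrinsic_summaries = [], {"n": 0, "categories": {}}, {}, []
    else:
        summaries, cohort, correlations = _run_synapse(pairs, config)
        intrinsic_summaries = _run_intrinsic(pairs, config)

    summaries_to_frame([s for s, _ in summaries]).to_csv(
        out_dir / "connection_summaries.csv", index=False
    )
    if intrinsic_summaries:
        pd.DataFrame(
            [
                {
                    "cell_id": s.cell_id,
                    "holding_category": s.holding_category,
                    "holding_p": s.holding_p,
                    "rin_baseline": s.rin_baseline,
                    "rin_agonist": s.rin_agonist,
                    "rin_ratio": s.rin_ratio,
                    "rin_category": s.rin_category,
                }
                for s in intrinsic_summaries
            ]
        ).to_csv(out_dir / "intrinsic_summaries.csv", index=False)
        normalized_time_course(intrinsic_summaries).to_csv(out_dir / "holding_time_course.csv")

    results = {
        "version": _pkg_version,
        "config": config.to_dict(),
        "classification": {
            "labels": dict(zip(cls_result.cell_ids, cls_result.labels)),
            "silhouette_mean": cls_result.silhouette_mean,
            "silhouette_by_k": sil_diag,
            "validated": cls_result.validated,
        },
        "group_comparison": json.loads(comparison.to_json()),
        "synapse": {
            "cohort": cohort,
            "correlations": correlations,
            "categories": {
                s.pair_id: {
                    "category": s.modulation_category,
                    "true_category": t.true_category,
                    "normalized_change": s.normalized_change,
                    "delta_ppr": s.delta_ppr,
                }
                for s, t in summaries
            },
        },
        "intrinsic": {
            "holding_categories": category_counts(intrinsic_summaries, "holding"),
            "rin_categories": category_counts(intrinsic_summaries, "rin"),
        },
    }
    (out_dir / "results.json").write_text(json.dumps(results, indent=1, default=float))

    lines = [
        f"pairclamp {_pkg_version} run summary",
        f"cells: {config.n_fs_cells} FS + {config.n_nonfs_cells} non-FS simulated",
        f"classification silhouette: {cls_result.silhouette_mean:.3f} "
        f"({'validated' if cls_result.validated else 'UNVALIDATED'})",
        f"connections analyzed: {len(summaries)}",
    ]
    for cat, info in cohort.get("categories", {}).items():
        lines.append(f"  {cat}: {info['count']} ({info['percent_int']}%)")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return results
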