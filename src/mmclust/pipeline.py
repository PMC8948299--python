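"""End-to-end orchestration: simulate/load -> cohort -> clusterability ->
cluster -> profile -> sensitivity, with artefact files and a run manifest.

Every stage writes plain CSV/JSON artefacts into the output directory and
records row/column counts in the manifest so conservation can be audited.
All randomness (simulation, Hopkins probes) derives from one top-level seed
via numpy SeedSequence spawning, so stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import load_catalog
from .cluster import select_k, sensitivity_suite
from .cohort import (
    ascertain_conditions,
    assemble_cohort,
    filter_multimorbid,
    find_index_admissions,
    read_episodes,
    summarise_baseline,
)
from .distance import dissimilarity, hopkins_statistic
from .errors import ParameterError, PipelineError
from .profiling import characterise_groups, label_clusters, prevalence_by_group
from .simulate import (
    SimulationConfig,
    default_config,
    generate_population,
    well_separated_profiles,
    write_episodes,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (an episode CSV) or ``simulate`` (keyword
    arguments for the synthetic generator, minimally ``n_patients``) must be
    given.
    """

    outdir: Path
    seed: int = 0
    input_path: Optional[Path] = None
    simulate: Optional[dict] = None
    catalog_path: Optional[Path] = None
    study_year: int = 2014
    lookback_years: int = 5
    min_conditions: int = 2
    include_index_admission: bool = False
    metric: str = "jaccard"
    k_grid: Sequence[int] = tuple(range(2, 16))
    hopkins: dict = field(default_factory=dict)
    bold_threshold: float = 50.0
    feature_min_ratio: float = 1.25
    sensitivity: Sequence[str] = ("hamming", "drop_top_condition", "drop_rare_conditions")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ParameterError(
                "exactly one of input_path or a simulate block must be given"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ParameterError(f"input episode file not found: {self.input_path}")
        if self.catalog_path is not None and not Path(self.catalog_path).exists():
            raise ParameterError(f"catalog file not found: {self.catalog_path}")
        self.outdir = Path(self.outdir)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    counts: dict
    hopkins: Optional[dict] = None
    chosen_k: Optional[int] = None
    avg_silhouette: Optional[float] = None
    labels: Optional[dict] = None
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _simulation_config(block: dict, seed: int) -> SimulationConfig:
    block = dict(block)
    profiles = block.pop("profiles", "default")
    n_patients = block.pop("n_patients")
    if profiles == "default":
        return default_config(n_patients, seed=seed, **block)
    if profiles == "well_separated":
        weights, prof = well_separated_profiles(
            n_groups=int(block.pop("n_groups", 10)),
            within=float(block.pop("within", 0.9)),
            background=float(block.pop("background", 0.05)),
        )
        base = default_config(n_patients, seed=seed)
        demo = {
            "groups": [base.demographics["groups"][i % 10] for i in range(len(weights))],
            "background": base.demographics["background"],
        }
        return SimulationConfig(
            n_patients=n_patients,
            group_weights=weights,
            condition_profiles=prof,
            demographics=demo,
            seed=seed,
            **block,
        )
    raise ParameterError(f"unknown simulate profile set {profiles!r}")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing artefacts under ``config.outdir``.

    Raises PipelineError naming the failing stage; on failure a ``FAILED``
    marker file is left in the output directory so partial artefacts are
    recognisable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()

    ss = np.random.SeedSequence(config.seed)
    sim_seed, hopkins_seed = (
        int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(2)
    )
    seeds = {"top_level": config.seed, "simulate": sim_seed, "hopkins": hopkins_seed}
    counts: dict = {}
    timings: dict = {}
    manifest = RunManifest(
        config={
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        version=__version__,
        seeds=seeds,
        counts=counts,
        timings=timings,
    )

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                marker.write_text(f"stage {name}: {exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            return out

        return deco

    catalog = stage("catalog")(lambda: load_catalog(config.catalog_path))

    def _input():
        if config.simulate is not None:
            sim_cfg = _simulation_config(config.simulate, sim_seed)
            episodes, truth = generate_population(sim_cfg, catalog)
            write_episodes(episodes, outdir / "episodes.csv")
            write_truth(truth, outdir / "truth.csv")
            counts["simulated_patients"] = sim_cfg.n_patients
        else:
            episodes = read_episodes(config.input_path)
        counts["episodes"] = len(episodes)
        return episodes

    episodes = stage("input")(_input)

    def _cohort():
        index = find_index_admissions(episodes, config.study_year)
        matrix = ascertain_conditions(
            episodes,
            index,
            config.lookback_years,
            catalog,
            include_index_admission=config.include_index_admission,
        )
        cohort = assemble_cohort(index, matrix)
        counts.update(index.drop_counts)
        if cohort.empty:
            raise ParameterError("cohort is empty after index identification")
        cohort.to_csv(outdir / "cohort.csv")
        matrix.to_csv(outdir / "condition_matrix.csv")
        summarise_baseline(cohort, config.min_conditions).to_csv(
            outdir / "baseline_summary.csv", index=False
        )
        (outdir / "drop_counts.json").write_text(json.dumps(index.drop_counts, indent=2))
        return cohort, matrix

    cohort, matrix = stage("cohort")(_cohort)

    def _filter():
        mm = filter_multimorbid(matrix, config.min_conditions)
        counts["patients_multimorbid"] = len(mm)
        if mm.empty:
            raise ParameterError("no multimorbid patients after filtering")
        return mm

    mm_matrix = stage("multimorbidity_filter")(_filter)

    def _hopkins():
        hk = dict(config.hopkins)
        res = hopkins_statistic(
            mm_matrix, seed=hopkins_seed, metric=config.metric, **hk
        )
        payload = {
            "statistic": res.statistic,
            "complement": res.complement,
            "n_probes": res.n_probes,
            "n_reps": res.n_reps,
            "reference_scheme": res.reference_scheme,
            "metric": res.metric,
        }
        (outdir / "hopkins.json").write_text(json.dumps(payload, indent=2))
        manifest.hopkins = payload
        return res

    stage("hopkins")(_hopkins)

    def _cluster():
        D = dissimilarity(mm_matrix, metric=config.metric)
        trace = select_k(D, config.k_grid)
        trace.as_frame().to_csv(outdir / "k_selection.csv", index=False)
        best = trace.best
        pd.DataFrame(
            {
                "patient_id": mm_matrix.index,
                "group": best.assignment,
                "silhouette": best.silhouette,
            }
        ).to_csv(outdir / "assignments.csv", index=False)
        manifest.chosen_k = trace.chosen_k
        manifest.avg_silhouette = best.avg_silhouette
        counts["chosen_k"] = trace.chosen_k
        return trace

    trace = stage("cluster")(_cluster)

    def _profile():
        best = trace.best
        prev = prevalence_by_group(mm_matrix, best.assignment)
        out = prev.table.copy()
        out.insert(0, "overall", prev.overall)
        out.round(1).to_csv(outdir / "prevalence_by_group.csv")
        labels = label_clusters(prev, config.bold_threshold, config.feature_min_ratio)
        payload = {
            str(g): {
                "label": labels.labels[g],
                "cluster_conditions": labels.cluster_conditions[g],
                "feature_conditions": labels.feature_conditions[g],
                "n": int(prev.group_sizes[g]),
            }
            for g in prev.table.columns
        }
        (outdir / "cluster_labels.json").write_text(json.dumps(payload, indent=2))
        mm_cohort = cohort.loc[mm_matrix.index]
        chars = characterise_groups(mm_cohort, best.assignment)
        chars.summary.round(1).to_csv(outdir / "group_characteristics.csv", index=False)
        chars.age.to_csv(outdir / "group_age.csv", index=False)
        manifest.labels = {str(g): labels.labels[g] for g in prev.table.columns}
        return labels

    stage("profile")(_profile)

    def _sensitivity():
        if not config.sensitivity:
            return None
        report = sensitivity_suite(
            mm_matrix,
            trace.best,
            k_grid=config.k_grid,
            variants=tuple(config.sensitivity),
        )
        payload = {
            name: {
                "chosen_k": v.chosen_k,
                "ari_vs_baseline": v.ari_vs_baseline,
                "dropped_conditions": v.dropped_conditions,
                "n_rows_dropped": v.n_rows_dropped,
                "crosstab": v.crosstab.to_dict(),
            }
            for name, v in report.variants.items()
        }
        (outdir / "sensitivity.json").write_text(
            json.dumps(payload, indent=2, default=str)
        )
        return report

    stage("sensitivity")(_sensitivity)

    (outdir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %s", outdir)
    return manifest
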