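"""End-to-end study workflow: covariates -> classes -> SIMPER -> networks ->
subset effectiveness, with reproducible seeding and CSV artifacts.

``run_full_analysis`` executes eight stages on a detection dataset:

1. movement covariates for every tag (with reported exclusions);
2. gap-statistic model selection and k-means at the chosen k;
3. a-posteriori class naming and PCA coordinates;
4. SIMPER characterisation (dispersion weighting + log(x+1));
5. relative-movement networks for the Full / IMOS / non-IMOS subsets;
6. gap statistic re-evaluated on covariates recomputed from IMOS-only and
   non-IMOS-only detections;
7. forced-k clustering of those subsets at the Full chosen k, with a
   cluster-overlap summary (contingency, best-match accuracy, silhouettes);
8. one Full network per functional movement class.

Subset covariates are recomputed from the subset's detection stream, not
re-filtered from the Full covariate table: restricting the array changes
consecutive-detection pairs, so the covariates themselves change. Tags
falling below the minimum detection count within a subset are excluded
from that subset's clustering (and reported).

Every stage derives its random seed from the master seed in a fixed order,
so a (dataset seed, analysis seed) pair reproduces all outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from . import __version__
from .cluster import (
    FMCAssignment,
    GapStatisticResult,
    KMeansFit,
    best_match_accuracy,
    gap_statistic,
    kmeans_fit,
    name_clusters,
    pca_project,
)
from .io import installation_types
from .metrics import CovariateMatrix, build_covariate_matrix, compute_covariates
from .network import (
    NetworkSummary,
    RelativeMovementMatrix,
    detect_communities,
    network_metrics,
    per_fmc_networks,
    relative_movement_matrix,
)
from .simper import Simper
from .simulate import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = (
    "covariates",
    "gap_kmeans",
    "assignment",
    "simper",
    "networks",
    "subset_gap",
    "forced_k",
    "fmc_networks",
)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are retained on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Analysis parameters; the seed is mandatory for reproducibility."""

    seed: int
    min_detections: int = 2
    k_max: int = 10
    B: int = 50
    n_init: int = 25
    removal_sizes: tuple[int, ...] = (1, 10, 100)
    iterations: int = 20
    normalization: str = "pooled"  # or "per_individual"

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "min_detections": self.min_detections,
            "k_max": self.k_max,
            "B": self.B,
            "n_init": self.n_init,
            "removal_sizes": list(self.removal_sizes),
            "iterations": self.iterations,
            "normalization": self.normalization,
        }


@dataclass
class SubsetAnalysis:
    """Effectiveness results for one installation subset (IMOS or non-IMOS)."""

    subset: str
    covariates: pd.DataFrame
    excluded: pd.DataFrame
    gap: GapStatisticResult | None
    forced_fit: KMeansFit | None
    overlap_accuracy: float
    silhouette: float
    contingency: pd.DataFrame


@dataclass
class AnalysisResult:
    """All stage outputs of one full run."""

    config: PipelineConfig
    covariates: pd.DataFrame
    excluded: pd.DataFrame
    matrix: CovariateMatrix
    gap: GapStatisticResult
    fit: KMeansFit
    assignment: FMCAssignment
    pca: Any
    simper: Simper
    networks: dict[str, tuple[RelativeMovementMatrix, NetworkSummary, Any]]
    subsets: dict[str, SubsetAnalysis]
    fmc_networks: dict[str, tuple[RelativeMovementMatrix, NetworkSummary, Any]]
    full_silhouette: float
    manifest: dict[str, Any] = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Named per-stage seeds derived from the master seed in a fixed order."""
    rng = np.random.default_rng(seed)
    names = ["gap", "kmeans", "gap_imos", "gap_nonimos", "forced_imos", "forced_nonimos"]
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, size=len(names)))}


def _network_rows(tag: str, M: RelativeMovementMatrix, summary: NetworkSummary) -> pd.DataFrame:
    row = {"network": tag, **summary.network, "total_transitions": M.n_transitions}
    return pd.DataFrame([row])


def run_full_analysis(
    detections: pd.DataFrame,
    installations: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Run the eight-stage analysis; optionally write CSV artifacts + manifest."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "config": config.as_dict(),
        "stage_seeds": seeds,
        "versions": {"fmclass": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "inputs": {
            "n_detections": int(len(detections)),
            "n_receivers": int(installations["receiver_id"].nunique()),
            "detections_hash": int(
                pd.util.hash_pandas_object(
                    detections.astype(str), index=False
                ).sum() % (2**63)
            ),
        },
        "stages": {},
    }

    def finish(stage: str, files: list[str], t0: float, **info):
        manifest["stages"][stage] = {
            "files": files,
            "seconds": round(time.time() - t0, 2),
            **info,
        }
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

    def write(name: str, df: pd.DataFrame, index: bool = False) -> list[str]:
        if out is None:
            return []
        df.to_csv(out / name, index=index, lineterminator="\n")
        return [name]

    # 1 — covariates
    t0 = time.time()
    try:
        cov, excluded = compute_covariates(detections, min_detections=config.min_detections)
        if len(cov) < 2:
            raise ValueError("fewer than two tags with enough detections")
        matrix = build_covariate_matrix(cov)
        files = write("covariates.csv", matrix.raw.join(
            matrix.transformed.add_suffix("_transformed")), index=True)
        files += write("excluded_tags.csv", excluded)
    except Exception as exc:  # noqa: BLE001
        raise StageError("covariates", exc) from exc
    finish("covariates", files, t0, n_tags=len(cov), n_excluded=len(excluded))

    # 2 — gap statistic + k-means at the chosen k
    t0 = time.time()
    try:
        gap = gap_statistic(
            matrix.X, k_max=config.k_max, B=config.B, n_init=config.n_init, seed=seeds["gap"]
        )
        fit = kmeans_fit(matrix.X, gap.chosen_k, n_init=config.n_init, seed=seeds["kmeans"])
        files = write("gap_curve.csv", gap.as_frame())
    except Exception as exc:  # noqa: BLE001
        raise StageError("gap_kmeans", exc) from exc
    finish("gap_kmeans", files, t0, chosen_k=gap.chosen_k)

    # 3 — naming + PCA coordinates
    t0 = time.time()
    try:
        labels = pd.Series(fit.labels, index=matrix.raw.index, name="cluster")
        assignment = name_clusters(labels, matrix.raw)
        pca = pca_project(matrix.X)
        files = write("assignment.csv", assignment.as_frame())
        pca_df = pd.DataFrame(
            pca.coords, index=matrix.raw.index, columns=["pc1", "pc2"]
        )
        pca_df["cluster"] = fit.labels
        files += write("pca_coordinates.csv", pca_df, index=True)
        full_sil = float(silhouette_score(matrix.X, fit.labels)) if gap.chosen_k > 1 else float("nan")
    except Exception as exc:  # noqa: BLE001
        raise StageError("assignment", exc) from exc
    finish("assignment", files, t0,
           class_names=sorted(assignment.names.values()), silhouette=full_sil)

    # 4 — SIMPER
    t0 = time.time()
    try:
        simper = Simper().fit(matrix.raw, assignment.class_labels.to_numpy())
        files = write("simper.csv", simper.results_.as_frame())
    except Exception as exc:  # noqa: BLE001
        raise StageError("simper", exc) from exc
    finish("simper", files, t0)

    # 5 — Full / IMOS / non-IMOS networks
    t0 = time.time()
    try:
        networks = {}
        net_rows, node_rows, comm_rows = [], [], []
        for subset in ("FULL", "IMOS", "NON_IMOS"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                M = relative_movement_matrix(
                    detections, installations, subset=subset,
                    per_individual=config.normalization == "per_individual",
                )
            summary = network_metrics(M)
            comms = detect_communities(M)
            networks[subset] = (M, summary, comms)
            net_rows.append(_network_rows(subset, M, summary))
            nodes = summary.nodes.copy()
            nodes.insert(0, "network", subset)
            node_rows.append(nodes)
            comm_rows.append(pd.DataFrame(
                {"network": subset,
                 "installation_id": list(comms.membership),
                 "community": list(comms.membership.values())}
            ))
        node_rows = [n for n in node_rows if not n.empty] or node_rows[:1]
        files = write("network_metrics.csv", pd.concat(net_rows, ignore_index=True))
        files += write("installation_metrics.csv", pd.concat(node_rows), index=True)
        files += write("communities.csv", pd.concat(comm_rows, ignore_index=True))
    except Exception as exc:  # noqa: BLE001
        raise StageError("networks", exc) from exc
    finish("networks", files, t0)

    # 6 & 7 — subset effectiveness
    types = installation_types(installations)
    subsets: dict[str, SubsetAnalysis] = {}
    t_sub = time.time()
    for subset, wanted, gseed, fseed in (
        ("IMOS", "IMOS", seeds["gap_imos"], seeds["forced_imos"]),
        ("NON_IMOS", "non-IMOS", seeds["gap_nonimos"], seeds["forced_nonimos"]),
    ):
        try:
            keep = types.index[types == wanted]
            det_sub = detections[detections["installation_id"].isin(keep)]
            cov_sub, exc_sub = compute_covariates(det_sub, min_detections=config.min_detections)
            mat_sub = None
            if len(cov_sub) >= max(2, config.k_max):
                try:
                    mat_sub = build_covariate_matrix(cov_sub)
                except ValueError as err:
                    # e.g. a constant covariate within a tiny subset: the
                    # subset cannot support clustering; report and move on
                    logger.warning("subset %s not clusterable: %s", subset, err)
            if mat_sub is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gap_sub = gap_statistic(
                        mat_sub.X, k_max=config.k_max, B=config.B,
                        n_init=config.n_init, seed=gseed,
                    )
                forced = kmeans_fit(mat_sub.X, gap.chosen_k, n_init=config.n_init, seed=fseed)
                common = cov_sub.index.intersection(matrix.raw.index)
                full_labels = pd.Series(fit.labels, index=matrix.raw.index).loc[common]
                sub_labels = pd.Series(forced.labels, index=cov_sub.index).loc[common]
                acc = best_match_accuracy(full_labels.to_numpy(), sub_labels.to_numpy())
                sil = (
                    float(silhouette_score(mat_sub.X, forced.labels))
                    if len(set(forced.labels)) > 1 else float("nan")
                )
                contingency = pd.crosstab(full_labels, sub_labels)
            else:
                gap_sub, forced = None, None
                acc, sil = float("nan"), float("nan")
                contingency = pd.DataFrame()
            subsets[subset] = SubsetAnalysis(
                subset=subset, covariates=cov_sub, excluded=exc_sub, gap=gap_sub,
                forced_fit=forced, overlap_accuracy=acc, silhouette=sil,
                contingency=contingency,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("subset_gap", exc) from exc
    finish(
        "subset_gap", [], t_sub,
        **{
            f"chosen_k_{name}": (None if s.gap is None else s.gap.chosen_k)
            for name, s in subsets.items()
        },
    )

    try:
        t0 = time.time()
        gap_rows = []
        for subset, sub in subsets.items():
            if sub.gap is not None:
                g = sub.gap.as_frame()
                g.insert(0, "subset", subset)
                gap_rows.append(g)
        files = write(
            "effectiveness_gap.csv",
            pd.concat(gap_rows, ignore_index=True) if gap_rows else pd.DataFrame(),
        )
        eff = pd.DataFrame(
            [
                {
                    "subset": "FULL",
                    "n_tags": len(cov),
                    "chosen_k": gap.chosen_k,
                    "forced_k": gap.chosen_k,
                    "silhouette": full_sil,
                    "overlap_accuracy_vs_full": 1.0,
                }
            ]
            + [
                {
                    "subset": s.subset,
                    "n_tags": len(s.covariates),
                    "chosen_k": None if s.gap is None else s.gap.chosen_k,
                    "forced_k": gap.chosen_k,
                    "silhouette": s.silhouette,
                    "overlap_accuracy_vs_full": s.overlap_accuracy,
                }
                for s in subsets.values()
            ]
        )
        files += write("effectiveness_clusters.csv", eff)
    except Exception as exc:  # noqa: BLE001
        raise StageError("forced_k", exc) from exc
    finish("forced_k", files, t0)

    # 8 — per-class networks
    t0 = time.time()
    try:
        fmc_nets = per_fmc_networks(detections, installations, assignment.class_labels)
        rows = [
            _network_rows(name, M, summary) for name, (M, summary, _) in fmc_nets.items()
        ]
        files = write("fmc_network_metrics.csv", pd.concat(rows, ignore_index=True))
    except Exception as exc:  # noqa: BLE001
        raise StageError("fmc_networks", exc) from exc
    finish("fmc_networks", files, t0)

    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    return AnalysisResult(
        config=config, covariates=cov, excluded=excluded, matrix=matrix, gap=gap,
        fit=fit, assignment=assignment, pca=pca, simper=simper, networks=networks,
        subsets=subsets, fmc_networks=fmc_nets, full_silhouette=full_sil,
        manifest=manifest,
    )


def run_simulation(sim_config: SimulationConfig, out_dir: str | Path):
    """Simulate a dataset and write detections/installations/truth CSVs."""
    dataset = generate_dataset(sim_config)
    paths = write_dataset(dataset, out_dir)
    return dataset, paths
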