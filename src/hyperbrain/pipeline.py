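"""End-to-end orchestration: cohort -> hyper-networks -> features ->
kernels -> classification -> report, plus parameter sweeps.

All randomness flows from one master seed through named substreams
(simulation, cross-validation folds), so a rerun with the same config
produces byte-identical outputs.  Every artifact written by
:func:`run_all` carries the config hash so artifacts from different
configurations cannot be silently mixed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hyperbrain import synthetic
from hyperbrain.classification import (CVConfig, CVReport, cross_validate,
                                       DEFAULT_ALPHA_GRID, DEFAULT_COST_GRID)
from hyperbrain.hypernet import (DEFAULT_LAMBDA_GRID, HyperNetwork,
                                 build_hypernetwork, restrict_lambda)
from hyperbrain.region_features import compute_region_features, ks_fdr_select
from hyperbrain.subgraphs import extract_patterns, fsfs_select, score_catalog

logger = logging.getLogger("hyperbrain")

__all__ = ["PipelineConfig", "run_all", "sweep", "build_cohort_networks"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one end-to-end evaluation."""

    simulation: synthetic.SimulationConfig | None = None
    manifest: str | None = None
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    K: float = 0.25
    match: str = "exact"
    q: float = 0.05
    wl_iterations: int = 3
    residualize: bool = False
    n_folds: int = 10
    n_repeats: int = 100
    selection_scope: str = "fold"
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    svm_cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    inner_folds: int = 5
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and self.manifest is None:
            raise ValueError("either a simulation config or a manifest is required")
        if not 0 <= self.K <= 1:
            raise ValueError("K must lie in [0, 1]")
        if self.match not in ("exact", "superset"):
            raise ValueError("match must be 'exact' or 'superset'")
        if self.wl_iterations < 0:
            raise ValueError("wl_iterations must be >= 0")
        grid = np.asarray(self.lambda_grid)
        if grid.size == 0 or np.any(grid <= 0) or np.any(grid > 1) \
                or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda grid must be strictly increasing in (0, 1]")
        self.cv_config().validate()

    def cv_config(self) -> CVConfig:
        return CVConfig(n_folds=self.n_folds, n_repeats=self.n_repeats,
                        selection_scope=self.selection_scope,
                        svm_cost_grid=tuple(self.svm_cost_grid),
                        alpha_grid=tuple(self.alpha_grid),
                        inner_folds=self.inner_folds,
                        seed=_substream(self.seed, "folds"))

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _substream(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def load_cohort(config: PipelineConfig) -> synthetic.CohortDataset:
    if config.manifest is not None:
        return synthetic.read_cohort(config.manifest)
    sim = dataclasses.replace(config.simulation,
                              seed=_substream(config.seed, "simulation")
                              if config.simulation.seed == 0
                              else config.simulation.seed)
    return synthetic.simulate_cohort(sim)


def build_cohort_networks(cohort: synthetic.CohortDataset,
                          lambda_grid=DEFAULT_LAMBDA_GRID) -> list[HyperNetwork]:
    """One hyper-network per subject over the given lambda grid."""
    nets = []
    for subj in cohort.subjects:
        logger.debug("building hyper-network for %s", subj.subject_id)
        nets.append(build_hypernetwork(subj.series, tuple(lambda_grid),
                                       roi_names=cohort.roi_names))
    return nets


def _write_csv(frame: pd.DataFrame, path: str, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=index)


def _report_dict(report: CVReport) -> dict:
    return {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
        "per_repeat_accuracy": report.per_repeat_accuracy,
    }


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline; return (and optionally write) the summary.

    The summary mirrors the three-way comparison central to the method:
    classification with region features only (alpha = 1), subgraph
    features only (alpha = 0), and the combined multi-kernel model.
    """
    config.validate()
    config_hash = config.hash()
    logger.info("pipeline start (config hash %s)", config_hash)

    cohort = load_cohort(config)
    logger.info("cohort: %d subjects, %d ROIs", len(cohort), cohort.n_rois)
    networks = build_cohort_networks(cohort, config.lambda_grid)
    logger.info("hyper-networks built (mean edges %.1f)",
                float(np.mean([len(n.edges) for n in networks])))

    y = cohort.labels
    ids = [s.subject_id for s in cohort.subjects]
    cv = config.cv_config()
    common = dict(covariates=cohort.covariates, subject_ids=ids,
                  roi_names=cohort.roi_names, K=config.K, q=config.q,
                  wl_iterations=config.wl_iterations, match=config.match,
                  residualize=config.residualize)
    reports = {}
    for mode in ("region", "subgraph", "combined"):
        logger.info("cross-validating (%s view)", mode)
        reports[mode] = cross_validate(networks, y, cv, mode=mode, **common)

    summary = {
        "config": {**dataclasses.asdict(config), "hash": config_hash},
        "n_subjects": len(cohort),
        "n_rois": cohort.n_rois,
        "results": {mode: _report_dict(rep) for mode, rep in reports.items()},
    }

    if config.output_dir:
        out = config.output_dir
        os.makedirs(out, exist_ok=True)
        table = compute_region_features(networks, subject_ids=ids, labels=y,
                                        covariates=cohort.covariates,
                                        roi_names=cohort.roi_names)
        table = ks_fdr_select(table, q=config.q)
        _write_csv(table.features, os.path.join(out, "region_features.csv"),
                   config_hash, index=True)
        _write_csv(table.selection, os.path.join(out, "region_selection.csv"),
                   config_hash)
        nets0 = [n for n, lab in zip(networks, y) if lab == 0]
        nets1 = [n for n, lab in zip(networks, y) if lab == 1]
        try:
            catalog = fsfs_select(score_catalog(extract_patterns(nets0, nets1),
                                                nets0, nets1, config.match),
                                  K=config.K)
            _write_csv(catalog.to_frame(),
                       os.path.join(out, "subgraph_catalog.csv"), config_hash)
        except ValueError as exc:
            logger.warning("subgraph catalog not written: %s", exc)
        edges_rows = [
            {"subject_id": sid, "edge_id": f"{e.seed_roi}_{e.lambda_relative:g}",
             "seed_roi": e.seed_roi, "lambda_relative": e.lambda_relative,
             "nodes": ",".join(map(str, sorted(e.nodes)))}
            for sid, net in zip(ids, networks) for e in net.edges
        ]
        _write_csv(pd.DataFrame(edges_rows),
                   os.path.join(out, "hyperedges.csv"), config_hash)
        roc = pd.DataFrame(reports["combined"].roc_points,
                           columns=["fpr", "tpr"])
        _write_csv(roc, os.path.join(out, "roc_combined.csv"), config_hash)
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        logger.info("artifacts written to %s", out)
    return summary


def check_config_hash(path: str, expected: str) -> None:
    """Refuse to consume an artifact produced under a different config."""
    with open(path) as fh:
        first = fh.readline().strip()
    found = first.removeprefix("# config_hash=") if first.startswith("# config_hash=") else None
    if found != expected:
        raise ValueError(
            f"{path} carries config hash {found!r}, expected {expected!r}; "
            "refusing to mix artifacts from different configurations")


def sweep(config: PipelineConfig, parameter: str, values) -> pd.DataFrame:
    """One full combined-view evaluation per parameter value, shared seeds.

    ``parameter`` is one of ``'lambda_grid_prefix'`` (values are prefix
    lengths or max-lambda cutoffs), ``'K'``, or ``'alpha'`` (values pin
    the kernel weight).  Hyper-networks are built once on the full grid
    and restricted per prefix, which is exact because duplicate edges
    keep their smallest lambda.
    """
    values = list(values)
    if not values:
        raise ValueError("empty sweep value list")
    if parameter not in ("lambda_grid_prefix", "K", "alpha"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    config.validate()

    cohort = load_cohort(config)
    networks = build_cohort_networks(cohort, config.lambda_grid)
    y = cohort.labels
    ids = [s.subject_id for s in cohort.subjects]
    cv = config.cv_config()
    common = dict(covariates=cohort.covariates, subject_ids=ids,
                  roi_names=cohort.roi_names, q=config.q,
                  wl_iterations=config.wl_iterations, match=config.match,
                  residualize=config.residualize)

    rows = []
    for value in values:
        if parameter == "lambda_grid_prefix":
            nets = [restrict_lambda(n, float(value)) for n in networks]
            rep = cross_validate(nets, y, cv, K=config.K, mode="combined",
                                 **common)
        elif parameter == "K":
            rep = cross_validate(networks, y, cv, K=float(value),
                                 mode="combined", **common)
        else:  # alpha
            pinned = dataclasses.replace(cv, alpha_grid=(float(value),))
            rep = cross_validate(networks, y, pinned, K=config.K,
                                 mode="combined", **common)
        logger.info("sweep %s=%s -> accuracy %.3f", parameter, value,
                    rep.accuracy)
        rows.append({parameter: value, "accuracy": rep.accuracy,
                     "sensitivity": rep.sensitivity,
                     "specificity": rep.specificity, "auc": rep.auc})
    return pd.DataFrame(rows)
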