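"""Synthetic cohorts of ROI time series with planted group differences.

The generator emulates the kind of data the downstream pipeline consumes:
one multivariate time series per subject (timepoints x ROIs), a binary
group label, and demographic covariates.  Group structure is planted in
the covariance: a baseline block-modular covariance is shared by both
groups, and group-1 subjects additionally receive a common latent
component loading on a chosen subset of ROIs, which raises the pairwise
correlations among those "perturbed" regions by an amount controlled by
``effect_size``.  Temporal smoothness is introduced by AR(1) filtering,
and every ROI series is z-scored so that the downstream sparse
regressions see comparable scales.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "Subject",
    "CohortDataset",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

COVARIATE_NAMES = ("age", "sex", "education")

# Magnitude of the shared latent loading per unit of effect_size.  At
# effect_size=2 the loading variance equals the baseline ROI variance,
# roughly doubling the correlation among perturbed pairs.
_LOADING_SCALE = 0.5

_PD_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution parameters for the age / sex / education covariates.

    ``label_shift`` adds a constant to group-1 subjects' age and education
    (and shifts the sex probability), so confound regression can be tested
    in both the independent and the confounded regime.  Defaults keep the
    covariates independent of the label.
    """

    age_mean: float = 70.0
    age_sd: float = 5.0
    sex_p: float = 0.5
    education_mean: float = 12.0
    education_sd: float = 3.0
    label_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions under which a synthetic cohort is generated."""

    n_group0: int
    n_group1: int
    n_rois: int = 90
    n_timepoints: int = 238
    n_perturbed_rois: int = 4
    effect_size: float = 0.0
    ar_coefficient: float = 0.3
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_group0 < 1 or self.n_group1 < 1:
            raise ValueError("each group needs at least one subject")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be > 2")
        if not 0 <= self.n_perturbed_rois <= self.n_rois:
            raise ValueError(
                f"n_perturbed_rois={self.n_perturbed_rois} exceeds n_rois={self.n_rois}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")


@dataclass
class Subject:
    subject_id: str
    label: int
    covariates: np.ndarray  # (age, sex, education)
    series: np.ndarray  # timepoints x ROIs, z-scored per ROI


@dataclass
class CohortDataset:
    """An ordered cohort of subjects with shared ROI naming.

    ``ground_truth_perturbed`` records which ROIs carry the planted group
    difference; it is populated only for simulated cohorts.
    """

    subjects: list[Subject]
    roi_names: list[str]
    ground_truth_perturbed: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        shapes = {s.series.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError(f"all series must share dimensions, got {shapes}")
        labels = {s.label for s in self.subjects}
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {labels}")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def covariates(self) -> np.ndarray:
        return np.array([s.covariates for s in self.subjects], dtype=float)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def __len__(self) -> int:
        return len(self.subjects)


def _block_modular_covariance(n_rois: int, block_size: int = 5,
                              partial_corr: float = 0.2) -> np.ndarray:
    """Baseline covariance from a block-diagonal precision matrix.

    Within each block of ROIs the precision carries negative off-diagonal
    entries (positive partial correlations), so every ROI's series is
    genuinely predictable from its block partners — structure the sparse
    regression stage can recover.
    """
    precision = np.eye(n_rois)
    for start in range(0, n_rois, block_size):
        stop = min(start + block_size, n_rois)
        blk = slice(start, stop)
        width = stop - start
        if width > 1:
            off = -partial_corr / max(width - 1, 1) * 2.0
            precision[blk, blk] += off * (1 - np.eye(width))
    cov = np.linalg.inv(precision)
    return cov


def _ensure_pd(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and add ridge jitter until strictly positive definite."""
    cov = (cov + cov.T) / 2.0
    jitter = 0.0
    for _ in range(60):
        eigmin = float(np.linalg.eigvalsh(cov + jitter * np.eye(len(cov)))[0])
        if eigmin > _PD_EIG_FLOOR:
            return cov + jitter * np.eye(len(cov))
        jitter = max(2 * jitter, 1e-10)
    raise np.linalg.LinAlgError("covariance not positive definite after jitter")


def _draw_series(rng: np.random.Generator, chol: np.ndarray, d: int,
                 rho: float) -> np.ndarray:
    """Draw one subject's timepoints x ROIs matrix: MVN innovations + AR(1)."""
    m = chol.shape[0]
    innov = rng.standard_normal((d, m)) @ chol.T
    if rho > 0:
        series = np.empty_like(innov)
        series[0] = innov[0]
        scale = np.sqrt(1.0 - rho * rho)
        for t in range(1, d):
            series[t] = rho * series[t - 1] + scale * innov[t]
    else:
        series = innov
    return series


def _zscore(series: np.ndarray) -> np.ndarray:
    mu = series.mean(axis=0)
    sd = series.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (series - mu) / sd


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a two-group cohort with a planted covariance difference.

    Deterministic given ``config.seed``.  With ``effect_size=0`` the two
    groups are drawn from the identical distribution (label-exchangeable).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cov0 = _block_modular_covariance(config.n_rois)
    perturbed = rng.choice(config.n_rois, size=config.n_perturbed_rois,
                           replace=False)
    perturbed = frozenset(int(i) for i in perturbed)

    loading = np.zeros(config.n_rois)
    if config.effect_size > 0 and perturbed:
        amp = np.sqrt(config.effect_size * _LOADING_SCALE)
        for i in perturbed:
            loading[i] = amp
    cov1 = cov0 + np.outer(loading, loading)

    chol0 = np.linalg.cholesky(_ensure_pd(cov0))
    chol1 = np.linalg.cholesky(_ensure_pd(cov1))

    spec = config.covariate_spec
    subjects: list[Subject] = []
    n_total = config.n_group0 + config.n_group1
    width = len(str(n_total))
    for idx in range(n_total):
        label = 0 if idx < config.n_group0 else 1
        chol = chol0 if label == 0 else chol1
        series = _zscore(_draw_series(rng, chol, config.n_timepoints,
                                      config.ar_coefficient))
        shift = spec.label_shift if label == 1 else (0.0, 0.0, 0.0)
        age = rng.normal(spec.age_mean + shift[0], spec.age_sd)
        sex = float(rng.random() < min(max(spec.sex_p + shift[1], 0.0), 1.0))
        edu = rng.normal(spec.education_mean + shift[2], spec.education_sd)
        subjects.append(Subject(
            subject_id=f"sub-{idx + 1:0{width}d}",
            label=label,
            covariates=np.array([age, sex, edu]),
            series=series,
        ))

    roi_names = [f"ROI{j + 1:03d}" for j in range(config.n_rois)]
    return CohortDataset(subjects=subjects, roi_names=roi_names,
                         ground_truth_perturbed=perturbed)


def write_cohort(dataset: CohortDataset, directory: str | os.PathLike) -> str:
    """Write a cohort as per-subject TSV matrices plus a manifest CSV.

    Returns the manifest path.  Validation (unique ids, shared shapes)
    runs before any file is written.
    """
    # CohortDataset.__post_init__ enforces the invariants; re-run them in
    # case the caller mutated the subject list in place.
    CohortDataset(dataset.subjects, dataset.roi_names,
                  dataset.ground_truth_perturbed)
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for subj in dataset.subjects:
        rel = f"{subj.subject_id}.tsv"
        frame = pd.DataFrame(subj.series, columns=dataset.roi_names)
        frame.to_csv(os.path.join(directory, rel), sep="\t", index=False,
                     float_format="%.17g")
        rows.append({
            "subject_id": subj.subject_id,
            "label": subj.label,
            "age": subj.covariates[0],
            "sex": subj.covariates[1],
            "education": subj.covariates[2],
            "path": rel,
        })
    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(directory, "manifest.csv")
    manifest.to_csv(manifest_path, index=False, float_format="%.17g")
    return manifest_path


def read_cohort(manifest_path: str | os.PathLike) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = str(manifest_path)
    directory = os.path.dirname(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "label", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns {required - set(manifest.columns)}")

    subjects: list[Subject] = []
    roi_names: list[str] | None = None
    shape: tuple[int, int] | None = None
    for row in manifest.itertuples(index=False):
        path = os.path.join(directory, str(row.path))
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"time-series file for subject {row.subject_id!r} not found: {path}"
            )
        frame = pd.read_csv(path, sep="\t")
        if roi_names is None:
            roi_names = list(frame.columns)
            shape = frame.shape
        elif frame.shape != shape or list(frame.columns) != roi_names:
            raise ValueError(
                f"subject {row.subject_id!r}: matrix shape/columns do not match the cohort"
            )
        covs = np.array([
            getattr(row, "age", np.nan),
            getattr(row, "sex", np.nan),
            getattr(row, "education", np.nan),
        ], dtype=float)
        subjects.append(Subject(
            subject_id=str(row.subject_id),
            label=int(row.label),
            covariates=covs,
            series=frame.to_numpy(dtype=float),
        ))
    return CohortDataset(subjects=subjects, roi_names=roi_names or [])
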