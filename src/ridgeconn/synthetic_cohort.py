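"""Two-group synthetic cohorts with planted partial-correlation differences.

The generator emulates a case/control resting-state study design at the ROI
time-series level: every subject's signal is a stationary zero-mean Gaussian
multivariate time series whose precision (inverse covariance) matrix comes
from a shared sparse backbone. The two groups differ only on a configured
set of planted edges, each shifted by a signed *partial-correlation* delta,
so every downstream stage (connectivity estimation, network statistics,
classification) has exact ground truth.

Temporal smoothness is injected by passing each node's innovations through
an AR(1) filter with innovation variance scaled by ``1 - phi^2``, which
leaves the stationary contemporaneous covariance equal to the target
covariance exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import TimeSeriesMatrix, tikhonov_partial_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedEdge",
    "CovariateSpec",
    "ClinicalSpec",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "build_group_precisions",
    "simulate_subject",
    "simulate_cohort",
    "partial_correlations_from_precision",
]

# Covariate distributions loosely matched to an adult male clinical sample:
# age in years, education in years, and a nicotine-dependence score.
DEFAULT_COVARIATES: dict[str, tuple[float, float]] = {
    "age": (34.4, 8.8),
    "education": (13.3, 3.9),
    "ftnd": (6.0, 2.7),
}

# Clinical scores as (intercept, coefficient on the standardized network
# summary, residual sd); scales sized like anxiety / psychiatric ratings.
DEFAULT_CLINICAL: dict[str, tuple[float, float, float]] = {
    "hama": (22.4, 0.0, 8.6),
    "bprs": (39.1, 0.0, 11.1),
}


@dataclass(frozen=True)
class PlantedEdge:
    """One edge (i, j) whose group-2 partial correlation is shifted by delta."""

    i: int
    j: int
    delta: float


@dataclass(frozen=True)
class CovariateSpec:
    """Gaussian nuisance covariates shared by both groups (matched design)."""

    distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )


@dataclass(frozen=True)
class ClinicalSpec:
    """Clinical scores as linear functions of a network summary plus noise.

    Each entry maps a score name to ``(intercept, coefficient, noise_sd)``;
    the coefficient multiplies the cohort-standardized network summary
    (mean ridge partial correlation over the planted edges, or over all
    edges if none are planted).
    """

    scores: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL)
    )
    summary_alpha: float = 0.1


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 20
    n_nodes: int = 60
    n_timepoints: int = 196
    base_density: float = 0.1
    planted_edges: tuple[PlantedEdge, ...] = ()
    ar_coeff: float = 0.3
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    clinical_spec: ClinicalSpec = field(default_factory=ClinicalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_edges", tuple(
            e if isinstance(e, PlantedEdge) else PlantedEdge(*e)
            for e in self.planted_edges
        ))
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must be in [0, 1)")
        if not (0 <= self.base_density <= 1):
            raise ValueError("base_density must be in [0, 1]")
        seen = set()
        for e in self.planted_edges:
            if not (0 <= e.i < self.n_nodes and 0 <= e.j < self.n_nodes) or e.i == e.j:
                raise ValueError(f"planted edge ({e.i}, {e.j}) is invalid")
            key = (min(e.i, e.j), max(e.i, e.j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)


@dataclass(frozen=True)
class GroundTruth:
    precision_group1: np.ndarray
    precision_group2: np.ndarray
    planted_edges: tuple[PlantedEdge, ...]
    seed: int


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[TimeSeriesMatrix, ...]
    phenotypes: pd.DataFrame
    ground_truth: GroundTruth
    config: CohortConfig


def partial_correlations_from_precision(theta: np.ndarray) -> np.ndarray:
    """Closed-form partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj)."""
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def _backbone_precision(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Sparse random backbone precision, diagonally loaded to SPD.

    Off-diagonal support is an Erdos-Renyi pattern at ``base_density`` with
    constant magnitude and random signs; the diagonal is set by a
    diagonal-dominance margin so the matrix is SPD by construction.
    """
    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < config.base_density
    signs = rng.choice([-1.0, 1.0], size=len(iu))
    mag = 0.2
    vals = np.where(present, signs * mag, 0.0)
    theta = np.zeros((n, n))
    theta[iu, ju] = vals
    theta += theta.T
    # strict diagonal dominance => SPD for a symmetric matrix
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 1.0)
    return theta


def build_group_precisions(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Construct the two SPD group precision matrices.

    The group-2 partial correlation on each planted edge equals group 1's
    plus the configured delta (exact by construction); all other entries,
    including the diagonal, are identical between groups. If the edited
    matrix loses positive definiteness, both matrices are diagonally loaded
    by the same amount and the planted entries re-solved, so the off-planted
    partial correlations remain identical across groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    theta1 = _backbone_precision(config, rng)

    for e in config.planted_edges:
        r1 = -theta1[e.i, e.j] / np.sqrt(theta1[e.i, e.i] * theta1[e.j, e.j])
        if abs(r1 + e.delta) >= 1.0:
            raise ValueError(
                f"planted edge ({e.i}, {e.j}): target partial correlation "
                f"{r1 + e.delta:.3f} is outside (-1, 1)"
            )

    def _plant(theta_base: np.ndarray) -> np.ndarray:
        theta2 = theta_base.copy()
        d = np.sqrt(np.diag(theta_base))
        for e in config.planted_edges:
            if e.delta == 0:
                continue
            r1 = -theta_base[e.i, e.j] / (d[e.i] * d[e.j])
            target = r1 + e.delta
            theta2[e.i, e.j] = theta2[e.j, e.i] = -target * d[e.i] * d[e.j]
        return theta2

    load = 0.0
    eye = np.eye(config.n_nodes)
    for _ in range(60):
        t1 = theta1 + load * eye
        t2 = _plant(t1)
        w = np.linalg.eigvalsh(t2)[0]
        if w > 1e-8:
            return t1, t2
        load = max(2 * load, 1e-3) if load else abs(w) + 1e-3
    raise RuntimeError(
        "could not reach a positive-definite group-2 precision after "
        "maximum diagonal loading; reduce planted deltas"
    )


def simulate_subject(
    precision: np.ndarray,
    n_timepoints: int,
    ar_coeff: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Sample a stationary Gaussian time series with the given precision.

    Rows are timepoints; the stationary covariance equals ``inv(precision)``
    exactly for any ``ar_coeff`` in [0, 1): each node's series obeys
    ``x_t = phi * x_{t-1} + sqrt(1 - phi^2) * e_t`` with correlated
    innovations ``e_t ~ N(0, Sigma)`` and a stationary start.
    """
    if not (0 <= ar_coeff < 1):
        raise ValueError("ar_coeff must be in [0, 1)")
    precision = np.asarray(precision, dtype=float)
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as err:
        raise ValueError("precision matrix is not symmetric positive-definite") from err
    sigma = np.linalg.inv(precision)
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((n_timepoints, precision.shape[0])) @ L.T
    if ar_coeff == 0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - ar_coeff**2)
    for t in range(1, n_timepoints):
        out[t] = ar_coeff * out[t - 1] + scale * innov[t]
    return out


def _network_summary(ts: np.ndarray, config: CohortConfig) -> float:
    """Per-subject scalar feeding the clinical-score model."""
    labels = tuple(f"roi{k}" for k in range(ts.shape[1]))
    rho = tikhonov_partial_correlation(
        TimeSeriesMatrix(ts, labels, "tmp"), config.clinical_spec.summary_alpha
    )
    if config.planted_edges:
        return float(np.mean([rho[e.i, e.j] for e in config.planted_edges]))
    iu, ju = np.triu_indices(ts.shape[1], k=1)
    return float(np.mean(np.abs(rho[iu, ju])))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort described by ``config``.

    Returns per-subject time series, a phenotype table (group label,
    covariates, clinical scores) and the ground-truth precisions. Clinical
    scores are linear in the cohort-standardized network summary so a zero
    coefficient yields scores independent of the connectome.
    """
    root = np.random.SeedSequence(config.seed)
    ss_struct, ss_subjects, ss_cov, ss_clin = root.spawn(4)
    theta1, theta2 = build_group_precisions(config)

    n_total = 2 * config.n_per_group
    labels = tuple(f"roi{k}" for k in range(config.n_nodes))
    subject_seeds = ss_subjects.spawn(n_total)
    subjects: list[TimeSeriesMatrix] = []
    groups: list[str] = []
    for idx in range(n_total):
        group2 = idx >= config.n_per_group
        theta = theta2 if group2 else theta1
        ts = simulate_subject(theta, config.n_timepoints, config.ar_coeff, subject_seeds[idx])
        sid = f"sub-{idx + 1:03d}"
        subjects.append(TimeSeriesMatrix(ts, labels, sid))
        groups.append("patient" if group2 else "control")

    rng_cov = np.random.default_rng(ss_cov)
    pheno = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "group": groups,
    })
    for name, (mu, sd) in config.covariate_spec.distributions.items():
        pheno[name] = mu + sd * rng_cov.standard_normal(n_total)

    if config.clinical_spec.scores:
        summaries = np.array([_network_summary(s.values, config) for s in subjects])
        sd = summaries.std(ddof=1)
        zsum = (summaries - summaries.mean()) / sd if sd > 0 else np.zeros(n_total)
        rng_clin = np.random.default_rng(ss_clin)
        for name, (intercept, coef, noise_sd) in config.clinical_spec.scores.items():
            pheno[name] = intercept + coef * zsum + noise_sd * rng_clin.standard_normal(n_total)

    gt = GroundTruth(
        precision_group1=theta1,
        precision_group2=theta2,
        planted_edges=config.planted_edges,
        seed=config.seed,
    )
    return Cohort(subjects=tuple(subjects), phenotypes=pheno, ground_truth=gt, config=config)
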