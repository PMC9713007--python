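"""Group inference on AUC features and clinical association.

Two-sided mass-univariate GLM over the AUC feature table with family-wise
error control by the permutation distribution of the maximum |t| within
each feature family (each global attribute is its own family; each nodal
attribute forms one family spanning all ROIs). Clinical association is
Pearson partial correlation controlling nuisance covariates, Bonferroni
adjusted over the grid of (attribute, clinical variable) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import FreedmanLane, perm_pvalue
from .nbs import Design

__all__ = [
    "PermGLMResult",
    "maxstat_perm_glm",
    "default_families",
    "partial_correlation",
    "bonferroni",
    "clinical_correlations",
]


@dataclass(frozen=True)
class PermGLMResult:
    feature_names: tuple[str, ...]
    t_observed: np.ndarray
    p_perm: np.ndarray
    families: dict[str, tuple[str, ...]]
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        fam_of = {f: name for name, members in self.families.items() for f in members}
        return pd.DataFrame({
            "feature": self.feature_names,
            "family": [fam_of[f] for f in self.feature_names],
            "t": self.t_observed,
            "p_perm": self.p_perm,
        })


def default_families(feature_names: list[str]) -> dict[str, tuple[str, ...]]:
    """Default family partition of an AUC feature table.

    Global attributes (no ``:`` in the name) each form a singleton family;
    nodal columns named ``attribute:ROI`` are grouped per attribute, so the
    maximum statistic is taken across all ROIs of that attribute.
    """
    fams: dict[str, list[str]] = {}
    for name in feature_names:
        key = name.split(":", 1)[0] if ":" in name else name
        fams.setdefault(key, []).append(name)
    return {k: tuple(v) for k, v in fams.items()}


def maxstat_perm_glm(
    features: pd.DataFrame,
    design: Design,
    families: dict[str, tuple[str, ...]] | None = None,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    paper_convention: bool = False,
) -> PermGLMResult:
    """Max-statistic Freedman-Lane permutation GLM over feature columns.

    For each permutation the maximum |t| within every family is recorded;
    a feature's FWE-corrected p-value is the fraction of permutations whose
    family maximum reaches its observed |t|.
    """
    names = list(features.columns)
    if families is None:
        families = default_families(names)
    members_idx: dict[str, np.ndarray] = {}
    covered: set[str] = set()
    for fam, members in families.items():
        unknown = [m for m in members if m not in names]
        if unknown:
            raise ValueError(f"family {fam!r} references unknown features {unknown}")
        members_idx[fam] = np.array([names.index(m) for m in members])
        covered.update(members)
    if covered != set(names):
        raise ValueError("families must cover every feature exactly once")

    Y = features.to_numpy(dtype=float)
    if design.matrix.shape[0] != Y.shape[0]:
        raise ValueError("design rows must align with feature rows")
    fl = FreedmanLane(Y, design.matrix, design.contrast)
    t_obs, _ = fl.observed()
    abs_obs = np.abs(t_obs)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_sub = Y.shape[0]
    counts = np.zeros(Y.shape[1], dtype=np.intp)
    for _ in range(n_perm):
        perm = rng.permutation(n_sub)
        abs_t = np.abs(fl.permuted(perm))
        for fam, idx in members_idx.items():
            fam_max = abs_t[idx].max()
            counts[idx] += fam_max >= abs_obs[idx]

    p = np.array([perm_pvalue(int(c), n_perm, paper_convention) for c in counts])
    # degenerate (t = 0) features carry no evidence
    p[abs_obs == 0] = 1.0
    seed_int = int(ss.generate_state(1)[0] % 2**31) if isinstance(seed, np.random.SeedSequence) else int(seed)
    return PermGLMResult(
        feature_names=tuple(names),
        t_observed=t_obs,
        p_perm=p,
        families={k: tuple(v) for k, v in families.items()},
        n_perm=n_perm,
        seed=seed_int,
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson partial correlation of x and y controlling covariates.

    Both variables are residualized on ``[intercept | covariates]``; the
    p-value uses the t distribution with ``n - k - 2`` degrees of freedom
    where k is the number of covariates.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        Z = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match x length")
        Z = np.hstack([np.ones((n, 1)), cov])
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - Z @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    sx, sy = rx.std(), ry.std()
    # residuals collinear with the covariates leave only round-off noise
    if sx <= 1e-10 * max(x.std(), 1.0) or sy <= 1e-10 * max(y.std(), 1.0):
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) with m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def clinical_correlations(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    attributes: list[str],
    clinical_vars: list[str],
    control: list[str] | None = None,
) -> pd.DataFrame:
    """Partial correlations of each attribute with each clinical variable.

    ``features`` rows must align with ``phenotypes`` rows (both indexed or
    ordered by subject). Bonferroni correction spans all
    attribute x clinical-variable tests.
    """
    control = control or []
    cov = phenotypes[control].to_numpy(dtype=float) if control else None
    rows = []
    for attr in attributes:
        for clin in clinical_vars:
            r, p = partial_correlation(
                features[attr].to_numpy(dtype=float),
                phenotypes[clin].to_numpy(dtype=float),
                cov,
            )
            rows.append({"attribute": attr, "clinical": clin, "r": r, "p": p})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p"].to_numpy())
    table["controlled"] = ",".join(control)
    return table
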