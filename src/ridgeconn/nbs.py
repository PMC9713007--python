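"""Network-based statistic (NBS) on unthresholded connectivity matrices.

Edge-wise GLM t-maps are computed across subjects, thresholded at a
one-sided primary p-value, and the connected components formed by the
suprathreshold edges are tested against a family-wise null distribution of
the maximum component size (in edges) obtained by Freedman-Lane
permutation of the subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glm import FreedmanLane, check_design, glm_tstats, perm_pvalue
from .connectome import ConnectivityMatrix

__all__ = ["Design", "TStatMatrix", "Component", "NBSResult",
           "edgewise_glm", "suprathreshold_components", "nbs_test"]


@dataclass(frozen=True)
class Design:
    """Design matrix (with intercept and optional nuisance covariates) plus
    the contrast vector selecting the effect of interest."""

    matrix: np.ndarray
    contrast: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "contrast", c)
        check_design(X, c)

    @classmethod
    def two_group(
        cls,
        group_indicator: np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> "Design":
        """Intercept + group-indicator (+ covariates) design; the contrast
        picks the group column."""
        g = np.asarray(group_indicator, dtype=float).reshape(-1, 1)
        cols = [np.ones_like(g), g]
        if covariates is not None and np.size(covariates):
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cols.append(cov)
        X = np.hstack(cols)
        c = np.zeros(X.shape[1])
        c[1] = 1.0
        return cls(matrix=X, contrast=c)


@dataclass(frozen=True)
class TStatMatrix:
    t_values: np.ndarray
    df: int
    node_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class Component:
    """One suprathreshold connected component."""

    edges: tuple[tuple[int, int], ...]
    p_perm: float | None = None
    mass: float = 0.0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted({n for e in self.edges for n in e}))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class NBSResult:
    direction: str
    p_primary: float
    t_critical: float
    components: tuple[Component, ...]
    null_max_component: np.ndarray
    null_max_mass: np.ndarray
    n_perm: int
    seed: int
    node_labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def significant(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.p_perm is not None and c.p_perm < 0.05)


def _stack_edges(stack: list[ConnectivityMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    labels = stack[0].node_labels
    for cm in stack[1:]:
        if cm.node_labels != labels:
            raise ValueError("all connectivity matrices must share node labels")
    n = stack[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    Y = np.stack([cm.z_values[iu, ju] for cm in stack])
    return Y, iu, ju, labels


def edgewise_glm(stack: list[ConnectivityMatrix], design: Design) -> TStatMatrix:
    """Per-edge OLS t-statistics for the design's contrast."""
    Y, iu, ju, labels = _stack_edges(stack)
    if design.matrix.shape[0] != Y.shape[0]:
        raise ValueError("design rows must match the subject stack")
    t, df = glm_tstats(Y, design.matrix, design.contrast)
    n = stack[0].n_nodes
    T = np.zeros((n, n))
    T[iu, ju] = t
    T += T.T
    return TStatMatrix(t_values=T, df=df, node_labels=labels)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _components_from_edges(ei: np.ndarray, ej: np.ndarray) -> list[list[tuple[int, int]]]:
    if len(ei) == 0:
        return []
    uf = _UnionFind(int(max(ei.max(), ej.max())) + 1)
    for a, b in zip(ei.tolist(), ej.tolist()):
        uf.union(a, b)
    groups: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(ei.tolist(), ej.tolist()):
        groups.setdefault(uf.find(a), []).append((a, b))
    return sorted(groups.values(), key=len, reverse=True)


def suprathreshold_components(t: TStatMatrix, t_crit: float) -> list[Component]:
    """Connected components of edges with t > t_crit, largest (by edge
    count) first."""
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    iu, ju = np.triu_indices(t.t_values.shape[0], k=1)
    mask = t.t_values[iu, ju] > t_crit
    comps = _components_from_edges(iu[mask], ju[mask])
    return [Component(edges=tuple(sorted(c))) for c in comps]


def _component_mass(edges, tvec_lookup, t_crit: float) -> float:
    return sum(tvec_lookup[e] - t_crit for e in edges)


def _max_component_stat(
    tvec: np.ndarray, iu: np.ndarray, ju: np.ndarray, t_crit: float
) -> tuple[int, float]:
    """(edge count, mass) of the largest suprathreshold component.

    Among equally sized components the one with the larger mass (summed
    t excess over the threshold) wins; the pair is compared
    lexicographically against the observed component, which removes the
    heavy ties of a purely integer-valued extent statistic.
    """
    mask = tvec > t_crit
    if not mask.any():
        return 0, 0.0
    ei, ej = iu[mask], ju[mask]
    excess = tvec[mask] - t_crit
    lookup = {(a, b): x for a, b, x in zip(ei.tolist(), ej.tolist(), excess.tolist())}
    comps = _components_from_edges(ei, ej)
    best = len(comps[0])
    mass = max(
        sum(lookup[e] for e in c) for c in comps if len(c) == best
    )
    return best, mass


def nbs_test(
    stack: list[ConnectivityMatrix],
    design: Design,
    p_primary: float = 0.001,
    n_perm: int = 5000,
    direction: str = "positive",
    seed: int | np.random.SeedSequence = 0,
    paper_convention: bool = False,
) -> NBSResult:
    """Run the NBS for one contrast direction.

    ``direction='negative'`` negates the contrast, testing for edges where
    the effect runs the other way. The family-wise null is the maximum
    suprathreshold component size (edge count) over Freedman-Lane
    permutations; each observed component's ``p_perm`` is the fraction of
    permutations whose maximum is at least as large (+1-corrected unless
    ``paper_convention``).
    """
    if not (0 < p_primary <= 0.5):
        raise ValueError("p_primary must be in (0, 0.5]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")

    contrast = design.contrast if direction == "positive" else -design.contrast
    Y, iu, ju, labels = _stack_edges(stack)
    fl = FreedmanLane(Y, design.matrix, contrast)
    t_obs, df = fl.observed()
    t_crit = float(stats.t.ppf(1 - p_primary, df))
    mask = t_obs > t_crit
    obs_lookup = {
        (a, b): float(x) - t_crit
        for a, b, x in zip(iu[mask].tolist(), ju[mask].tolist(), t_obs[mask].tolist())
    }
    observed = [
        Component(
            edges=tuple(sorted(c)),
            mass=float(sum(obs_lookup[e] for e in c)),
        )
        for c in _components_from_edges(iu[mask], ju[mask])
    ]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_sub = Y.shape[0]
    null_size = np.empty(n_perm, dtype=np.intp)
    null_mass = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_sub)
        null_size[b], null_mass[b] = _max_component_stat(fl.permuted(perm), iu, ju, t_crit)

    scored = tuple(
        Component(
            edges=c.edges,
            mass=c.mass,
            p_perm=perm_pvalue(
                int((
                    (null_size > c.n_edges)
                    | ((null_size == c.n_edges) & (null_mass >= c.mass))
                ).sum()),
                n_perm,
                paper_convention,
            ),
        )
        for c in observed
    )
    seed_int = int(ss.generate_state(1)[0] % 2**31) if isinstance(seed, np.random.SeedSequence) else int(seed)
    return NBSResult(
        direction=direction,
        p_primary=p_primary,
        t_critical=t_crit,
        components=scored,
        null_max_component=null_size,
        null_max_mass=null_mass,
        n_perm=n_perm,
        seed=seed_int,
        node_labels=labels,
    )
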