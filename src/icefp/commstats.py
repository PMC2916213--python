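"""Community-level statistics on presence/absence fingerprint matrices.

Sørensen similarity (Cs = 2C/(A+B)), similarity-to-reference time series,
Pearson and partial Pearson temporal trend tests, group-average (UPGMA)
clustering on the similarity scale, and the SIMPROF permutation test for
internal structure within a group of samples.

All tests are two-sided at alpha = 0.05 unless stated otherwise; SIMPROF
uses 999 permutations for the expected profile and 999 for the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import PresenceMatrix

__all__ = [
    "SimilarityMatrix",
    "TrendResult",
    "ClusterNode",
    "ClusterResult",
    "sorensen",
    "similarity_matrix",
    "similarity_to_reference",
    "pearson_trend",
    "partial_pearson_trend",
    "group_average_cluster",
    "simprof",
    "simprof_tree",
    "richness",
    "ALPHA",
    "SIMPROF_N_PERM",
]

#: two-sided significance level for all trend and SIMPROF tests
ALPHA = 0.05
#: SIMPROF permutation counts (expected profile, p-value round)
SIMPROF_N_PERM = (999, 999)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Sørensen coefficients with unit diagonal."""

    values: pd.DataFrame
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")


@dataclass
class TrendResult:
    """A (partial) Pearson correlation against time."""

    statistic_name: str
    pearson_r: float
    p_value: float
    n: int
    controlled_covariate: str | None = None
    undefined: bool = False

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p_value < ALPHA


@dataclass
class ClusterNode:
    """One node of the group-average dendrogram (leaf or merge)."""

    samples: tuple[str, ...]
    merge_similarity: float | None  # None for leaves
    children: tuple["ClusterNode", ...] = ()
    simprof_pi: float | None = None
    simprof_p: float | None = None
    simprof_tested: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterResult:
    root: ClusterNode
    merges: list[tuple[frozenset, frozenset, float]] = field(
        default_factory=list
    )

    def nodes(self) -> list[ClusterNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def significant_nodes(self) -> list[ClusterNode]:
        return [
            n for n in self.nodes()
            if n.simprof_tested and n.simprof_p is not None
            and n.simprof_p < ALPHA
        ]

    def to_newick(self) -> str:
        def fmt(node: ClusterNode, parent_h: float) -> str:
            h = 1.0 if node.merge_similarity is None else node.merge_similarity
            # branch length on the (1 - similarity) scale
            bl = max(h - parent_h, 0.0)
            if node.is_leaf:
                return f"{node.samples[0]}:{bl:.6g}"
            inner = ",".join(fmt(c, h) for c in node.children)
            return f"({inner}):{bl:.6g}"

        root_h = (
            0.0 if self.root.merge_similarity is None
            else self.root.merge_similarity
        )
        if self.root.is_leaf:
            return f"{self.root.samples[0]};"
        inner = ",".join(fmt(c, root_h) for c in self.root.children)
        return f"({inner});"


def sorensen(set_a: Iterable, set_b: Iterable) -> float:
    """Sørensen's similarity Cs = 2C/(A+B) on two presence sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Sørensen similarity undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def _pairwise_sorensen(mat: np.ndarray) -> np.ndarray:
    """Vectorised pairwise Cs for a boolean samples x OTUs matrix.

    Pairs of all-empty rows get Cs = 0 (only reachable inside permutation
    nulls; the public API rejects empty sets).
    """
    m = mat.astype(float)
    shared = m @ m.T
    sizes = m.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(denom > 0, 2.0 * shared / denom, 0.0)
    return cs


def similarity_matrix(
    matrix: PresenceMatrix | pd.DataFrame,
    reference_sample: str | None = None,
) -> SimilarityMatrix:
    """All pairwise Sørensen coefficients of a presence/absence matrix."""
    df = matrix.presence if isinstance(matrix, PresenceMatrix) else matrix
    cs = _pairwise_sorensen(df.to_numpy(dtype=bool))
    np.fill_diagonal(cs, 1.0)
    values = pd.DataFrame(cs, index=df.index, columns=df.index)
    return SimilarityMatrix(values=values, reference_sample=reference_sample)


def similarity_to_reference(
    matrix: PresenceMatrix | pd.DataFrame, reference_sample_id: str
) -> pd.Series:
    """Cs of every other sample relative to one reference sample.

    The reference's self-similarity (1 by definition) is excluded; trend
    tests run on the returned series therefore never see it.
    """
    df = matrix.presence if isinstance(matrix, PresenceMatrix) else matrix
    if reference_sample_id not in df.index:
        raise KeyError(f"unknown reference sample {reference_sample_id!r}")
    ref = frozenset(df.columns[df.loc[reference_sample_id].to_numpy(bool)])
    out = {}
    for s in df.index:
        if s == reference_sample_id:
            continue
        other = frozenset(df.columns[df.loc[s].to_numpy(bool)])
        out[s] = sorensen(ref, other)
    return pd.Series(out, name=f"Cs_vs_{reference_sample_id}")


def _t_p_value(r: float, df: int) -> float:
    """Two-sided p from the t transform of a correlation coefficient."""
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson_trend(
    values: Sequence[float], days: Sequence[float],
    statistic_name: str = "similarity",
) -> TrendResult:
    """Pearson correlation of a community statistic against sampling day."""
    x = np.asarray(values, dtype=float)
    d = np.asarray(days, dtype=float)
    if x.size != d.size:
        raise ValueError("values and days differ in length")
    if x.size < 3:
        raise ValueError("trend test requires n >= 3")
    if np.std(x) == 0 or np.std(d) == 0:
        return TrendResult(statistic_name, float("nan"), float("nan"),
                           int(x.size), undefined=True)
    r = float(np.corrcoef(x, d)[0, 1])
    return TrendResult(statistic_name, r, _t_p_value(r, x.size - 2),
                       int(x.size))


def partial_pearson_trend(
    values: Sequence[float], days: Sequence[float],
    covariate: Sequence[float],
    statistic_name: str = "richness",
    covariate_name: str = "cumulative_height",
    log_covariate: bool = False,
) -> TrendResult:
    """First-order partial Pearson correlation of ``values`` with ``days``,
    controlling for a nuisance covariate (e.g. profile cumulative height).

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with the
    two-sided p-value from the t transform at n - 3 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    d = np.asarray(days, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.size == d.size == z.size):
        raise ValueError("values, days and covariate differ in length")
    if x.size < 4:
        raise ValueError("partial trend test requires n >= 4")
    if log_covariate:
        z = np.log(z)
    if np.std(x) == 0 or np.std(d) == 0 or np.std(z) == 0:
        return TrendResult(statistic_name, float("nan"), float("nan"),
                           int(x.size), covariate_name, undefined=True)
    r_xy = float(np.corrcoef(x, d)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(d, z)[0, 1])
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        return TrendResult(statistic_name, float("nan"), float("nan"),
                           int(x.size), covariate_name, undefined=True)
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return TrendResult(statistic_name, float(r), _t_p_value(r, x.size - 3),
                       int(x.size), covariate_name)


def group_average_cluster(similarities: SimilarityMatrix) -> ClusterResult:
    """Agglomerative group-average (UPGMA) clustering on similarities.

    At each step the pair of clusters with the highest average between-
    cluster similarity (mean over the original pairwise coefficients) is
    merged; ties are broken toward the lexicographically smallest pair of
    smallest member ids, so the result is deterministic.
    """
    df = similarities.values
    ids = list(df.index)
    if len(ids) < 2:
        raise ValueError("clustering requires at least 2 samples")
    sim = df.to_numpy()
    idx = {s: i for i, s in enumerate(ids)}

    clusters: dict[tuple[str, ...], ClusterNode] = {
        (s,): ClusterNode(samples=(s,), merge_similarity=None) for s in ids
    }
    merges: list[tuple[frozenset, frozenset, float]] = []

    def avg_sim(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        block = sim[np.ix_([idx[s] for s in a], [idx[s] for s in b])]
        return float(block.mean())

    while len(clusters) > 1:
        keys = sorted(clusters)  # lexicographic over member tuples
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                s = avg_sim(ka, kb)
                cand = (-s, min(ka[0], kb[0]), max(ka[0], kb[0]))
                if best is None or cand < best[0]:
                    best = (cand, ka, kb, s)
        _, ka, kb, s = best
        na, nb = clusters.pop(ka), clusters.pop(kb)
        merged = tuple(sorted(ka + kb))
        clusters[merged] = ClusterNode(
            samples=merged, merge_similarity=s, children=(na, nb)
        )
        merges.append((frozenset(ka), frozenset(kb), s))
    root = next(iter(clusters.values()))
    return ClusterResult(root=root, merges=merges)


def _permute_columns(
    mat: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Stack of matrices with each column independently permuted over rows."""
    n, m = mat.shape
    keys = rng.random((n_perm, n, m))
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(
        np.broadcast_to(mat, (n_perm, n, m)), order, axis=1
    )


def _sorted_profiles(stack: np.ndarray) -> np.ndarray:
    """Ordered pairwise-similarity profiles for a stack of presence
    matrices, shape (k, n_pairs)."""
    k, n, _ = stack.shape
    m = stack.astype(float)
    shared = np.einsum("kim,kjm->kij", m, m)
    sizes = m.sum(axis=2)
    denom = sizes[:, :, None] + sizes[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(denom > 0, 2.0 * shared / denom, 0.0)
    iu = np.triu_indices(n, k=1)
    profiles = cs[:, iu[0], iu[1]]
    profiles.sort(axis=1)
    return profiles


def simprof(
    matrix: PresenceMatrix | pd.DataFrame,
    samples: Sequence[str] | None = None,
    n_perm_expected: int = SIMPROF_N_PERM[0],
    n_perm_p: int = SIMPROF_N_PERM[1],
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Similarity-profile permutation test on one group of samples.

    pi = sum over the ordered pairwise similarities of |observed - mean
    permuted|, where permutations shuffle each OTU column independently
    across the group's samples. The p-value is the add-one fraction of
    second-round permuted pi statistics >= the observed pi. Returns
    (pi, p); a group of identical rows yields p = 1 by convention.
    """
    df = matrix.presence if isinstance(matrix, PresenceMatrix) else matrix
    if samples is not None:
        df = df.loc[list(samples)]
    if len(df) < 3:
        raise ValueError("SIMPROF requires at least 3 samples")
    mat = df.to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)

    obs = _sorted_profiles(mat[None, :, :])[0]
    exp = _sorted_profiles(_permute_columns(mat, n_perm_expected, rng)).mean(
        axis=0
    )
    pi_obs = float(np.abs(obs - exp).sum())
    perm_profiles = _sorted_profiles(_permute_columns(mat, n_perm_p, rng))
    pi_perm = np.abs(perm_profiles - exp).sum(axis=1)
    p = float((1 + np.sum(pi_perm >= pi_obs - 1e-12)) / (n_perm_p + 1))
    return pi_obs, min(p, 1.0)


def simprof_tree(
    matrix: PresenceMatrix | pd.DataFrame,
    cluster: ClusterResult,
    n_perm_expected: int = SIMPROF_N_PERM[0],
    n_perm_p: int = SIMPROF_N_PERM[1],
    seed: int = 0,
    confidence: float = 0.95,
) -> ClusterResult:
    """SIMPROF over the dendrogram, PRIMER-style.

    The root is tested first; only when a node shows significant internal
    structure (p < 1 - confidence) are its children examined in turn.
    Annotates the nodes in place and returns the same ClusterResult.
    """
    alpha = 1.0 - confidence
    rng = np.random.default_rng(seed)

    def visit(node: ClusterNode) -> None:
        if len(node.samples) < 3:
            return
        pi, p = simprof(
            matrix, samples=node.samples,
            n_perm_expected=n_perm_expected, n_perm_p=n_perm_p,
            seed=int(rng.integers(2**31 - 1)), confidence=confidence,
        )
        node.simprof_pi, node.simprof_p = pi, p
        node.simprof_tested = True
        if p < alpha:
            for child in node.children:
                visit(child)

    visit(cluster.root)
    return cluster


def richness(row: Sequence[bool] | pd.Series) -> int:
    """Number of OTUs scored present in one sample."""
    return int(np.asarray(row, dtype=bool).sum())
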