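"""Clone-library analysis.

Phylotype clustering of aligned 16S sequences at a fixed identity threshold
(complete linkage; >98% for bacterial, >99% for archaeal libraries), subtype
designation by predicted fingerprint-fragment length, alpha-diversity
estimates (observed richness, Chao1, Shannon, Good's coverage), the LIBSHUFF
Monte-Carlo two-library comparison, in-silico prediction of ARISA and T-RFLP
fragment lengths, and fingerprint <-> clone cross-matching including the
maximum-covariance dye-offset estimate.

Input sequences must be pre-aligned (equal length, gaps as '-'); de-novo
alignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synth import CloneSequence

__all__ = [
    "Phylotype",
    "Subtype",
    "DiversityEstimate",
    "FragmentPrediction",
    "OffsetEstimate",
    "LibshuffResult",
    "pairwise_identity",
    "identity_distance_matrix",
    "cluster_phylotypes",
    "chao1",
    "shannon",
    "goods_coverage",
    "diversity_estimate",
    "delta_c",
    "libshuff",
    "predict_fragment_length",
    "designate_subtypes",
    "estimate_dye_offset",
    "match_subtypes_to_otus",
    "PHYLOTYPE_THRESHOLDS",
]

#: identity thresholds for phylotype definition, by domain
PHYLOTYPE_THRESHOLDS = {"bacteria": 0.98, "archaea": 0.99}
#: subtype match tolerances against fingerprint OTU lengths (bp)
MATCH_TIGHT_BP = 1.0
MATCH_LOOSE_BP = 2.5


@dataclass
class Phylotype:
    """A cluster of clones above the identity threshold."""

    id: str
    member_ids: tuple[str, ...]
    representative_id: str
    library_counts: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class Subtype:
    """Members of one phylotype sharing a predicted fragment length."""

    phylotype_id: str
    predicted_fragment_length: float
    member_ids: tuple[str, ...]


@dataclass
class DiversityEstimate:
    observed_richness: int
    chao1: float
    shannon_h: float
    goods_coverage: float

    def __post_init__(self) -> None:
        if self.chao1 < self.observed_richness - 1e-9:
            raise ValueError("Chao1 cannot be below observed richness")
        if not 0.0 <= self.goods_coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


@dataclass
class FragmentPrediction:
    """Predicted fingerprint fragment length for one clone."""

    clone_id: str
    length_bp: float
    uncut: bool = False  # T-RFLP only: no recognition site found


@dataclass
class OffsetEstimate:
    offset_bp: int
    covariance: float
    flat: bool = False  # no structure in the covariance profile


@dataclass
class LibshuffResult:
    delta_c_xy: float
    delta_c_yx: float
    p_xy: float
    p_yx: float
    n_perm: int


# ---------------------------------------------------------------------------
# identity and clustering
# ---------------------------------------------------------------------------


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical bases over comparable alignment columns.

    Columns containing a gap ('-') or an N in either sequence are excluded
    from the comparison.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = _seq_array(seq_a), _seq_array(seq_b)
    bad = np.frombuffer(b"-N", dtype=np.uint8)
    valid = ~np.isin(a, bad) & ~np.isin(b, bad)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable columns between the two sequences")
    return float(np.sum(a[valid] == b[valid])) / n


def identity_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Square matrix of identity-based distances (1 - fractional identity).

    Raw identity distance is the package default; an externally computed
    evolutionary-distance matrix may be supplied wherever a distance matrix
    is accepted.
    """
    n = len(sequences)
    arrs = [_seq_array(s) for s in sequences]
    bad = np.frombuffer(b"-N", dtype=np.uint8)
    valids = [~np.isin(a, bad) for a in arrs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = valids[i] & valids[j]
            nv = int(v.sum())
            if nv == 0:
                raise ValueError(
                    f"no comparable columns between sequences {i} and {j}"
                )
            ident = float(np.sum(arrs[i][v] == arrs[j][v])) / nv
            d[i, j] = d[j, i] = 1.0 - ident
    return d


def cluster_phylotypes(
    clones: Sequence[CloneSequence],
    threshold: float = PHYLOTYPE_THRESHOLDS["bacteria"],
    distances: np.ndarray | None = None,
) -> list[Phylotype]:
    """Cluster clones into phylotypes at a strict identity threshold.

    Furthest-neighbour (complete-linkage) agglomeration on the gene-region
    identity distances, stopped so that every intra-phylotype pair exceeds
    ``threshold`` similarity (pairs at exactly the threshold are NOT
    merged). Phylotype ids are assigned by decreasing size, ties by the
    smallest member id; the representative is the lexicographically first
    member.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    genes = [c.gene_region for c in clones]
    if len({len(g) for g in genes}) > 1:
        raise ValueError("gene regions are not aligned (unequal lengths)")
    if distances is None:
        distances = identity_distance_matrix(genes)
    if len(clones) == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(distances, checks=False), method="complete")
        cut = np.nextafter(1.0 - threshold, 0.0)  # strictly below 1-threshold
        labels = fcluster(z, t=cut, criterion="distance")

    groups: dict[int, list[CloneSequence]] = {}
    for clone, lab in zip(clones, labels):
        groups.setdefault(int(lab), []).append(clone)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(c.id for c in g))
    )
    phylotypes = []
    for i, g in enumerate(ordered):
        ids = tuple(sorted(c.id for c in g))
        counts: dict[str, int] = {}
        for c in g:
            counts[c.library_id] = counts.get(c.library_id, 0) + 1
        phylotypes.append(
            Phylotype(
                id=f"P{i+1:03d}", member_ids=ids,
                representative_id=ids[0], library_counts=counts,
            )
        )
    return phylotypes


# ---------------------------------------------------------------------------
# diversity estimates
# ---------------------------------------------------------------------------


def _check_counts(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty library: no phylotype counts")
    if np.any(c <= 0) or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("phylotype counts must be positive integers")
    return c


def chao1(counts: Sequence[int]) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), with the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when no doubletons exist."""
    c = _check_counts(counts)
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts: Sequence[int]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    c = _check_counts(counts).astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage 1 - F1/N, F1 = number of singleton phylotypes."""
    c = _check_counts(counts)
    return 1.0 - float(np.sum(c == 1)) / float(c.sum())


def diversity_estimate(counts: Sequence[int]) -> DiversityEstimate:
    c = _check_counts(counts)
    return DiversityEstimate(
        observed_richness=int(c.size),
        chao1=chao1(c),
        shannon_h=shannon(c),
        goods_coverage=goods_coverage(c),
    )


# ---------------------------------------------------------------------------
# LIBSHUFF
# ---------------------------------------------------------------------------


def _coverage_curves(
    dmat: np.ndarray, x_idx: np.ndarray, y_idx: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """C_XY(D): fraction of X clones with a Y clone (other than themselves)
    within distance D, for each D on the grid. X == Y gives the homologous
    curve C_X(D)."""
    sub = dmat[np.ix_(x_idx, y_idx)].astype(float).copy()
    self_pairs = x_idx[:, None] == y_idx[None, :]
    sub[self_pairs] = np.inf
    mins = sub.min(axis=1)
    return (mins[:, None] <= grid[None, :] + 1e-12).mean(axis=0)


def _delta_c(
    dmat: np.ndarray, x_idx: np.ndarray, y_idx: np.ndarray, grid: np.ndarray
) -> float:
    cx = _coverage_curves(dmat, x_idx, x_idx, grid)
    cxy = _coverage_curves(dmat, x_idx, y_idx, grid)
    return float(np.sum((cx - cxy) ** 2))


def delta_c(
    distances: np.ndarray,
    x_idx: Sequence[int],
    y_idx: Sequence[int],
    grid_step: float = 0.01,
) -> float:
    """LIBSHUFF Delta C between two index sets over a pooled distance
    matrix. Comparing a library with itself (identical index sets) gives 0
    exactly, because the heterologous search also excludes each clone
    itself."""
    dmat = np.asarray(distances, dtype=float)
    grid = np.arange(0.0, float(dmat.max()) + grid_step, grid_step)
    return _delta_c(dmat, np.asarray(x_idx), np.asarray(y_idx), grid)


def libshuff(
    distances: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    grid_step: float = 0.01,
) -> LibshuffResult:
    """Two-library LIBSHUFF comparison on a pooled distance matrix.

    For each direction, Delta C = sum over the distance grid of
    (C_X(D) - C_XY(D))^2, comparing each library's homologous coverage with
    its heterologous coverage of the other library; significance by
    permuting library labels over the pooled clones (add-one p-values).
    """
    dmat = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    if dmat.shape[0] != dmat.shape[1] or dmat.shape[0] != labels.size:
        raise ValueError("distance matrix and labels are inconsistent")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    libs = sorted(set(labels.tolist()))
    if len(libs) != 2:
        raise ValueError(f"exactly two libraries required, got {libs}")
    x_idx = np.flatnonzero(labels == libs[0])
    y_idx = np.flatnonzero(labels == libs[1])
    if x_idx.size < 2 or y_idx.size < 2:
        raise ValueError("each library needs at least 2 clones")

    dmax = float(dmat.max())
    grid = np.arange(0.0, dmax + grid_step, grid_step)
    obs_xy = _delta_c(dmat, x_idx, y_idx, grid)
    obs_yx = _delta_c(dmat, y_idx, x_idx, grid)

    rng = np.random.default_rng(seed)
    n = labels.size
    ge_xy = ge_yx = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        px, py = perm[: x_idx.size], perm[x_idx.size:]
        if _delta_c(dmat, px, py, grid) >= obs_xy - 1e-12:
            ge_xy += 1
        if _delta_c(dmat, py, px, grid) >= obs_yx - 1e-12:
            ge_yx += 1
    return LibshuffResult(
        delta_c_xy=obs_xy, delta_c_yx=obs_yx,
        p_xy=(1 + ge_xy) / (n_perm + 1), p_yx=(1 + ge_yx) / (n_perm + 1),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# fragment-length prediction and cross-matching
# ---------------------------------------------------------------------------


def predict_fragment_length(
    clone: CloneSequence,
    assay: str,
    primer_pair: tuple[str, str] | None = None,
    enzyme: str = "HpyCH4III",
) -> FragmentPrediction:
    """Predict the fingerprint fragment length of one clone in silico.

    ARISA: length from the labelled forward primer's annealing position to
    the end of the reverse-primer site, inclusive. T-RFLP: distance from the
    labelled primer's 5' end to the first restriction cut position; a clone
    without a recognition site is flagged ``uncut`` and reported at the full
    amplicon length.
    """
    from Bio.Seq import Seq

    if primer_pair is None:
        from .synth import FORWARD_PRIMER, REVERSE_PRIMER

        primer_pair = (FORWARD_PRIMER, REVERSE_PRIMER)
    fwd, rev = primer_pair
    seq = clone.amplicon
    start = seq.find(fwd)
    if start < 0:
        raise ValueError(f"{clone.id}: forward primer not found")
    if assay == "ARISA":
        rev_site = str(Seq(rev).reverse_complement())
        end = seq.rfind(rev_site)
        if end < 0:
            raise ValueError(f"{clone.id}: reverse primer site not found")
        return FragmentPrediction(clone.id, float(end + len(rev_site) - start))
    if assay == "TRFLP":
        from Bio import Restriction

        enz = getattr(Restriction, enzyme)
        cuts = enz.search(Seq(seq[start:]))  # 1-based first base after cut
        if not cuts:
            return FragmentPrediction(
                clone.id, float(len(seq) - start), uncut=True
            )
        return FragmentPrediction(clone.id, float(min(cuts) - 1))
    raise ValueError(f"unknown assay {assay!r}")


def designate_subtypes(
    phylotypes: Sequence[Phylotype],
    predictions: Mapping[str, FragmentPrediction],
    length_tol: float = 0.5,
) -> list[Subtype]:
    """Split each phylotype into subtypes by predicted fragment length.

    Members whose predicted lengths differ by more than ``length_tol`` bp
    fall into distinct subtypes; a phylotype with a single length class
    yields a single subtype.
    """
    subtypes: list[Subtype] = []
    for ph in phylotypes:
        preds = sorted(
            (predictions[mid].length_bp, mid)
            for mid in ph.member_ids if mid in predictions
        )
        if not preds:
            continue
        group: list[tuple[float, str]] = [preds[0]]
        groups = [group]
        for item in preds[1:]:
            if item[0] - group[-1][0] > length_tol:
                group = [item]
                groups.append(group)
            else:
                group.append(item)
        for g in groups:
            subtypes.append(
                Subtype(
                    phylotype_id=ph.id,
                    predicted_fragment_length=float(
                        np.mean([x[0] for x in g])
                    ),
                    member_ids=tuple(x[1] for x in g),
                )
            )
    return subtypes


def _binned_histogram(
    lengths: np.ndarray, weights: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    edges = np.arange(lo, hi + 2) - 0.5  # 1-bp bins centred on integers
    h, _ = np.histogram(lengths, bins=edges, weights=weights)
    return h


def estimate_dye_offset(
    otu_lengths_with_heights: Sequence[tuple[float, float]],
    predicted_lengths_with_frequencies: Sequence[tuple[float, float]],
    search_range: tuple[int, int] = (-15, 15),
) -> OffsetEstimate:
    """Integer-bp shift of the OTU length histogram that maximises its
    covariance with the clone-library predicted-length histogram.

    Returns the shift to ADD to observed OTU lengths (a -7 bp result means
    the sample dye ran 7 bp long relative to the ladder dye). Ties are
    broken toward the smaller absolute offset; a flat covariance profile is
    flagged and reported as offset 0.
    """
    if not otu_lengths_with_heights or not predicted_lengths_with_frequencies:
        raise ValueError("both length histograms must be non-empty")
    ol = np.array([x[0] for x in otu_lengths_with_heights], dtype=float)
    oh = np.array([x[1] for x in otu_lengths_with_heights], dtype=float)
    pl = np.array([x[0] for x in predicted_lengths_with_frequencies],
                  dtype=float)
    pf = np.array([x[1] for x in predicted_lengths_with_frequencies],
                  dtype=float)
    lo_shift, hi_shift = int(search_range[0]), int(search_range[1])
    lo = int(np.floor(min(ol.min(), pl.min()))) + lo_shift - 1
    hi = int(np.ceil(max(ol.max(), pl.max()))) + hi_shift + 1
    h_otu = _binned_histogram(ol, oh, lo, hi)
    h_pred = _binned_histogram(pl, pf, lo, hi)

    best: tuple[float, int] | None = None
    covs = {}
    for k in sorted(range(lo_shift, hi_shift + 1), key=lambda k: (abs(k), k)):
        shifted = np.roll(h_otu, k)  # shift by +k bp
        cov = float(np.cov(shifted, h_pred)[0, 1])
        covs[k] = cov
        if best is None or cov > best[0] + 1e-12:
            best = (cov, k)
    if np.ptp(list(covs.values())) < 1e-12:
        return OffsetEstimate(offset_bp=0, covariance=best[0], flat=True)
    return OffsetEstimate(offset_bp=best[1], covariance=best[0])


def match_subtypes_to_otus(
    subtypes: Sequence[Subtype],
    otu_lengths: Sequence[float],
    tight_tol: float = MATCH_TIGHT_BP,
    loose_tol: float = MATCH_LOOSE_BP,
) -> pd.DataFrame:
    """Match each subtype's predicted length to the nearest fingerprint OTU.

    Distances <= tight_tol are 'tight' matches, those in (tight_tol,
    loose_tol] 'putative', the rest 'unmatched'. Offset correction must be
    applied to the OTU lengths beforehand. One OTU may match several
    subtypes.
    """
    otus = np.asarray(otu_lengths, dtype=float)
    if otus.size == 0:
        raise ValueError("no OTU lengths to match against")
    rows = []
    for st in subtypes:
        d = np.abs(otus - st.predicted_fragment_length)
        k = int(np.argmin(d))
        dist = float(d[k])
        if dist <= tight_tol:
            klass = "tight"
        elif dist <= loose_tol:
            klass = "putative"
        else:
            klass = "unmatched"
        rows.append(
            {
                "phylotype_id": st.phylotype_id,
                "predicted_length_bp": st.predicted_fragment_length,
                "nearest_otu_bp": float(otus[k]),
                "distance_bp": dist,
                "match": klass,
                "n_clones": len(st.member_ids),
            }
        )
    return pd.DataFrame(rows)
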