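"""Per-taxon kernel matrices from OTU counts and a phylogenetic tree.

The pipeline turns one OTU count table plus one rooted tree into one
positive semidefinite, unit-Frobenius-norm kernel matrix per taxonomic
cluster (typically a genus, with an ``Others`` catch-all):

1. partition OTUs into clusters by their taxon label,
2. for each cluster, prune the tree to the cluster's OTUs and compute a
   pairwise UniFrac-family distance between samples,
3. convert the squared distances to a kernel by Gower double-centering,
   clip negative eigenvalues, and scale to unit Frobenius norm.

Supported distance variants: unweighted, weighted (normalized),
variance-adjusted weighted, and generalized UniFrac with exponent
``alpha`` in [0, 1] (``alpha=1`` reproduces the normalized weighted
variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

__all__ = [
    "OTUTable",
    "DistanceMatrix",
    "KernelMatrix",
    "group_by_taxonomy",
    "unifrac_distance",
    "distance_to_kernel",
    "impute_missing_distances",
    "kernels_from_table",
    "UNIFRAC_VARIANTS",
]

UNIFRAC_VARIANTS = ("unweighted", "weighted", "variance_adjusted", "generalized")

OTHERS_LABEL = "Others"


@dataclass
class OTUTable:
    """Sample-by-OTU count matrix with an optional OTU→cluster map.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique row / column labels.
    taxon_of
        Map ``otu_id -> cluster label``. OTUs missing from the map fall
        into the ``Others`` catch-all during :func:`group_by_taxonomy`.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxon_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x OTUs)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        n, k = self.counts.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != k:
            raise ValueError("label lengths do not match count matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != k:
            raise ValueError("duplicate OTU ids")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                i, j = np.argwhere(self.counts != np.round(self.counts))[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def slice_otus(self, otu_ids: list[str]) -> "OTUTable":
        """Column subset preserving sample order."""
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = None
        if self.taxon_of is not None:
            tax = {o: self.taxon_of[o] for o in otu_ids if o in self.taxon_of}
        return OTUTable(self.counts[:, idx], list(self.sample_ids), list(otu_ids), tax)


@dataclass
class DistanceMatrix:
    """Pairwise sample distances for one cluster.

    ``values`` is symmetric with zero diagonal, entries in [0, 1] for the
    UniFrac family. Samples with no reads in the cluster have undefined
    distances: the corresponding rows/columns are NaN and flagged in
    ``missing``.
    """

    values: np.ndarray
    variant: str
    sample_ids: list[str]
    alpha: float | None = None
    missing: np.ndarray | None = None


@dataclass
class KernelMatrix:
    """Symmetric PSD sample-similarity matrix for one taxon cluster."""

    values: np.ndarray
    cluster_label: str = ""
    frobenius_normalized: bool = True
    n_clipped: int = 0
    clipped_magnitude: float = 0.0
    scale_factor: float = 1.0
    sample_ids: list[str] | None = None


def group_by_taxonomy(
    table: OTUTable,
    taxonomy: dict[str, str] | None = None,
    others_label: str = OTHERS_LABEL,
) -> dict[str, OTUTable]:
    """Partition an OTU table into per-cluster slices.

    OTUs with no cluster label (or mapped to a falsy value) are collected
    into ``others_label``. The slices partition the OTU set, so column
    sums are conserved. Empty clusters (possible when a taxonomy names a
    cluster with no OTUs in the table) are dropped with a warning.
    """
    mapping = taxonomy if taxonomy is not None else table.taxon_of
    if mapping is None:
        raise ValueError("no taxonomy mapping available")
    clusters: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        label = mapping.get(otu) or others_label
        clusters.setdefault(label, []).append(otu)
    out: dict[str, OTUTable] = {}
    for label, otus in clusters.items():
        if not otus:
            warnings.warn(f"cluster {label!r} is empty; excluded", stacklevel=2)
            continue
        out[label] = table.slice_otus(otus)
    return out


def _tree_edge_structure(tree: TreeNode, otu_ids: list[str]):
    """Prune ``tree`` to ``otu_ids`` and return (branch lengths, membership).

    ``membership`` is a (n_edges, n_otus) 0/1 matrix: entry (e, j) is 1
    when OTU j descends through edge e. Edge order is postorder; the root
    edge is excluded (it carries no between-sample information).
    """
    names = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in names]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:5]}")
    pruned = tree.shear(otu_ids) if len(names) != len(otu_ids) else tree.copy()
    col = {o: j for j, o in enumerate(otu_ids)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    # postorder accumulation of descendant-leaf membership
    memb: dict[int, np.ndarray] = {}
    for node in pruned.postorder(include_self=True):
        if node.is_tip():
            v = np.zeros(len(otu_ids))
            v[col[node.name]] = 1.0
        else:
            v = np.zeros(len(otu_ids))
            for child in node.children:
                v += memb[id(child)]
        memb[id(node)] = v
        if node.parent is not None:  # root edge excluded
            bl = node.length
            if bl is None:
                bl = 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            lengths.append(float(bl))
            rows.append(v)
    return np.asarray(lengths), np.asarray(rows)


def _pairwise_abs_diff(P: np.ndarray, w: np.ndarray, chunk: int = 64) -> np.ndarray:
    """sum_e w_e |P[a,e] - P[b,e]| for all sample pairs, chunked over rows."""
    n = P.shape[0]
    out = np.empty((n, n))
    Pw = P  # weights applied via dot below
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        diff = np.abs(Pw[start:stop, None, :] - Pw[None, :, :])
        out[start:stop] = diff @ w
    return out


def unifrac_distance(
    table: OTUTable,
    tree: TreeNode,
    variant: str = "weighted",
    alpha: float = 0.5,
    warn_missing: bool = True,
) -> DistanceMatrix:
    """Pairwise UniFrac-family distance between samples of one cluster.

    Proportions are computed within the cluster slice (each sample's
    counts divided by its cluster total), then accumulated down every
    branch of the tree pruned to the cluster's OTUs. With branch lengths
    ``b_e`` and descending proportions ``p_A, p_B``:

    - ``unweighted``: presence contrast, ``sum b 1[xor] / sum b 1[or]``;
    - ``weighted``: normalized weighted UniFrac,
      ``sum b |p_A - p_B| / sum b (p_A + p_B)``;
    - ``generalized``: ``sum b (p_A+p_B)^(alpha-1) |p_A-p_B| /
      sum b (p_A+p_B)^alpha`` (``alpha=1`` equals ``weighted``);
    - ``variance_adjusted``: weighted contrast with branch weights
      ``b / sqrt((p_A+p_B)(2-p_A-p_B))``.

    Samples with zero cluster total have undefined distances; their
    rows/columns are NaN and flagged in ``missing``.
    """
    if variant not in UNIFRAC_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {UNIFRAC_VARIANTS}")
    if variant == "generalized" and not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    b, M = _tree_edge_structure(tree, table.otu_ids)
    totals = table.counts.sum(axis=1).astype(float)
    empty = totals == 0
    rel = np.zeros_like(table.counts, dtype=float)
    nz = ~empty
    rel[nz] = table.counts[nz] / totals[nz, None]
    P = rel @ M.T  # (n_samples, n_edges) descending proportions

    n = table.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "unweighted":
            pres = (P > 0).astype(float)
            xor = _pairwise_abs_diff(pres, b)
            either = pres[:, None, :] + pres[None, :, :] > 0
            union = either @ b
            D = np.where(union > 0, xor / np.where(union > 0, union, 1.0), 0.0)
        elif variant == "weighted" or (variant == "generalized" and alpha == 1.0):
            num = _pairwise_abs_diff(P, b)
            s = P @ b
            den = s[:, None] + s[None, :]
            D = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        elif variant == "generalized":
            D = _generalized_pairwise(P, b, alpha)
        else:  # variance_adjusted
            D = _vaw_pairwise(P, b)

    D = np.asarray(D, dtype=float)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # enforce exact symmetry against roundoff
    if empty.any():
        if warn_missing:
            warnings.warn(
                f"{int(empty.sum())} sample(s) have zero counts in this cluster; "
                "their distances are undefined (NaN)",
                stacklevel=2,
            )
        D[empty, :] = np.nan
        D[:, empty] = np.nan
    return DistanceMatrix(
        values=D,
        variant=variant,
        sample_ids=list(table.sample_ids),
        alpha=alpha if variant == "generalized" else None,
        missing=empty,
    )


def _generalized_pairwise(P: np.ndarray, b: np.ndarray, alpha: float, chunk: int = 64):
    n = P.shape[0]
    D = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        s = P[start:stop, None, :] + P[None, :, :]
        d = np.abs(P[start:stop, None, :] - P[None, :, :])
        pos = s > 0
        num = np.where(pos, s, 1.0) ** (alpha - 1.0) * d
        num[~pos] = 0.0
        den = np.where(pos, s, 1.0) ** alpha
        den[~pos] = 0.0
        denom = den @ b
        numer = num @ b
        D[start:stop] = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return D


def _vaw_pairwise(P: np.ndarray, b: np.ndarray, chunk: int = 64):
    n = P.shape[0]
    D = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        s = P[start:stop, None, :] + P[None, :, :]
        d = np.abs(P[start:stop, None, :] - P[None, :, :])
        var = s * (2.0 - s)
        ok = var > 0
        w = np.where(ok, 1.0 / np.sqrt(np.where(ok, var, 1.0)), 0.0)
        numer = (w * d) @ b
        denom = (w * s) @ b
        D[start:stop] = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return D


def impute_missing_distances(D: DistanceMatrix) -> DistanceMatrix:
    """Resolve undefined distances of samples with zero cluster counts.

    The convention: two empty samples are identical (distance 0); an empty
    sample is completely separated from any sample with reads (distance 1,
    the UniFrac maximum). This is one documented caller-side policy for
    the flagged missing values; dropping the samples is the other.
    """
    if D.missing is None or not D.missing.any():
        return D
    vals = D.values.copy()
    miss = D.missing
    vals[miss, :] = 1.0
    vals[:, miss] = 1.0
    both = np.ix_(miss, miss)
    vals[both] = 0.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(
        values=vals,
        variant=D.variant,
        sample_ids=list(D.sample_ids),
        alpha=D.alpha,
        missing=np.zeros_like(miss),
    )


def distance_to_kernel(
    D: DistanceMatrix | np.ndarray,
    cluster_label: str = "",
    eig_tol: float = 0.0,
) -> KernelMatrix:
    """Gower-center squared distances into a PSD, unit-Frobenius kernel.

    K = -1/2 (I - 11'/n) D∘2 (I - 11'/n) with D∘2 the elementwise square,
    followed by clipping negative eigenvalues at ``eig_tol`` and scaling
    the reconstruction to unit Frobenius norm. An all-zero distance matrix
    yields the zero matrix with ``frobenius_normalized=False``.
    """
    if isinstance(D, DistanceMatrix):
        values = D.values
        sample_ids = D.sample_ids
        if D.missing is not None and D.missing.any():
            raise ValueError(
                "distance matrix contains undefined entries (all-zero samples); "
                "drop or impute those samples before kernel conversion"
            )
    else:
        values = np.asarray(D, dtype=float)
        sample_ids = None
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise ValueError("distance matrix must have zero diagonal")

    n = values.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * J @ (values**2) @ J
    K = 0.5 * (K + K.T)

    evals, evecs = np.linalg.eigh(K)
    neg = evals < eig_tol
    n_clipped = int(neg.sum())
    clipped_magnitude = float(-evals[neg].sum()) if n_clipped else 0.0
    if n_clipped:
        evals = np.clip(evals, 0.0, None)
        K = (evecs * evals) @ evecs.T
        K = 0.5 * (K + K.T)

    fro = float(np.linalg.norm(K, "fro"))
    if fro == 0.0:
        warnings.warn(
            f"cluster {cluster_label!r}: zero kernel, Frobenius normalization skipped",
            stacklevel=2,
        )
        return KernelMatrix(
            values=K,
            cluster_label=cluster_label,
            frobenius_normalized=False,
            n_clipped=n_clipped,
            clipped_magnitude=clipped_magnitude,
            scale_factor=1.0,
            sample_ids=sample_ids,
        )
    return KernelMatrix(
        values=K / fro,
        cluster_label=cluster_label,
        frobenius_normalized=True,
        n_clipped=n_clipped,
        clipped_magnitude=clipped_magnitude,
        scale_factor=1.0 / fro,
        sample_ids=sample_ids,
    )


def kernels_from_table(
    table: OTUTable,
    tree: TreeNode,
    variant: str = "weighted",
    alpha: float = 0.5,
    taxonomy: dict[str, str] | None = None,
    missing: str = "error",
) -> dict[str, KernelMatrix]:
    """Full pipeline: cluster partition → UniFrac distance → kernel.

    Clusters in which some sample has zero counts yield undefined
    distances for those samples. ``missing`` controls the policy:
    ``"error"`` (default) raises; ``"impute"`` applies
    :func:`impute_missing_distances` (empty-vs-empty 0, empty-vs-present
    1); ``"skip"`` drops the whole cluster with a warning.
    """
    if missing not in ("error", "impute", "skip"):
        raise ValueError("missing must be 'error', 'impute' or 'skip'")
    kernels: dict[str, KernelMatrix] = {}
    for label, piece in sorted(group_by_taxonomy(table, taxonomy).items()):
        D = unifrac_distance(
            piece, tree, variant=variant, alpha=alpha,
            warn_missing=(missing == "error"),
        )
        if D.missing is not None and D.missing.any():
            if missing == "skip":
                warnings.warn(
                    f"cluster {label!r} skipped: samples with zero cluster counts",
                    stacklevel=2,
                )
                continue
            if missing == "error":
                raise ValueError(
                    f"cluster {label!r}: samples with zero counts make distances "
                    "undefined; pass missing='impute' or missing='skip'"
                )
            D = impute_missing_distances(D)
        kernels[label] = distance_to_kernel(D, cluster_label=label)
    return kernels
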