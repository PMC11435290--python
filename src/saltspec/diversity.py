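"""Marker-based diversity: Jaccard dissimilarity, UPGMA trees, Mantel test.

The SSR panel is a binary band-presence matrix (genotypes x loci). Pairwise
genetic dissimilarity is the Jaccard coefficient ``1 - a/(a+b+c)`` (shared
bands ``a``, one-sided bands ``b``/``c``; joint absences carry no information
and are excluded). Phenotype-side distances are Euclidean on column
z-scores so that traits and indices on different scales contribute equally.

Trees come from unweighted pair-group average (UPGMA) clustering — the
arithmetic cross-pair mean linkage whose output is ultrametric — with
deterministic lexicographic tie-breaking, Newick serialization, cophenetic
distances, and a ``cut_tree`` that returns exactly k groups.

Congruence between a phenotype distance matrix and the marker distance matrix
is tested with the Mantel permutation test (Pearson r of the upper triangles;
null by simultaneous row/column permutation of the second matrix).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import AlignmentError, ConfigurationError, FormatError, SaltspecError


def read_marker_csv(path) -> pd.DataFrame:
    """Load a genotype x marker 0/1 band matrix.

    First column is the genotype label. Non-binary cells are rejected naming
    the genotype and marker; monomorphic (all-0 or all-1) columns are kept but
    flagged with a warning and listed in ``DataFrame.attrs['monomorphic']``.
    """
    raw = pd.read_csv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a genotype column plus marker columns")
    matrix = raw.set_index(raw.columns[0])
    matrix.index.name = "genotype"
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate genotype labels {dupes}")
    for col in matrix.columns:
        values = pd.to_numeric(matrix[col], errors="coerce")
        ok = values.isin([0, 1])
        if not ok.all():
            genotype = matrix.index[(~ok).argmax()]
            raise FormatError(
                f"{path}: non-binary cell for genotype {genotype!r}, marker {col!r}")
        matrix[col] = values.astype(int)
    monomorphic = [c for c in matrix.columns if matrix[c].nunique() == 1]
    if monomorphic:
        warnings.warn(f"monomorphic marker(s) kept: {monomorphic}", RuntimeWarning,
                      stacklevel=2)
    matrix.attrs["monomorphic"] = monomorphic
    return matrix


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with genotype labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise FormatError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise FormatError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def jaccard_distance_matrix(markers: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity of the band matrix rows.

    ``d(i, j) = 1 - a/(a+b+c)``; a pair with no bands at all (a+b+c = 0) gets
    distance 0 with a warning, keeping the matrix well defined.
    """
    if len(markers) < 2:
        raise SaltspecError("need at least two genotypes")
    bands = markers.to_numpy()
    if not np.isin(bands, (0, 1)).all():
        raise FormatError("marker matrix must be 0/1")
    union_empty = [
        (i, j)
        for i, j in itertools.combinations(range(len(markers)), 2)
        if not (bands[i].any() or bands[j].any())
    ]
    if union_empty:
        warnings.warn(f"{len(union_empty)} genotype pair(s) share no bands at all; "
                      "distance set to 0", RuntimeWarning, stacklevel=2)
    condensed = pdist(bands.astype(bool), metric="jaccard")
    return DistanceMatrix(list(markers.index), squareform(condensed))


def standardized_euclidean_distance(features: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance after z-scoring every column (sample SD, ddof=1).

    Zero-variance columns carry no contrast and are dropped with a warning;
    missing cells are rejected.
    """
    numeric = features.select_dtypes("number")
    if numeric.isna().any().any():
        raise SaltspecError("feature table contains missing cells")
    sd = numeric.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"zero-variance column(s) dropped: {constant}", RuntimeWarning,
                      stacklevel=2)
        numeric = numeric.drop(columns=constant)
        sd = sd.drop(constant)
    if numeric.shape[1] == 0:
        raise SaltspecError("no non-constant feature columns left")
    z = (numeric - numeric.mean()) / sd
    condensed = pdist(z.to_numpy(), metric="euclidean")
    return DistanceMatrix(list(features.index), squareform(condensed))


@dataclass
class Tree:
    """UPGMA merge history. Leaves are nodes 0..n-1; merge m creates node n+m.

    ``merges`` holds ``(left_node, right_node, height)`` in merge order; the
    tree is ultrametric, so every leaf sits at distance ``height`` below the
    node created at that height.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + m: (l, r) for m, (l, r, _) in enumerate(self.merges)}

    def _heights(self) -> dict[int, float]:
        n = self.n_leaves
        h = {i: 0.0 for i in range(n)}
        h.update({n + m: hm for m, (_, _, hm) in enumerate(self.merges)})
        return h

    def leaves_under(self, node: int) -> list[int]:
        children = self._children()
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(children[v])
        return sorted(out)

    def to_newick(self, digits: int = 6) -> str:
        """Newick string with branch lengths (leaf-to-root distances equal).

        Children are ordered by their smallest leaf label, so the string is a
        canonical serialization of the tree.
        """
        children, heights = self._children(), self._heights()

        def min_label(node: int) -> str:
            return min(self.labels[i] for i in self.leaves_under(node))

        def render(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < self.n_leaves:
                return f"{self.labels[node]}:{length:.{digits}g}"
            kids = sorted(children[node], key=min_label)
            inner = ",".join(render(c, heights[node]) for c in kids)
            return f"({inner}):{length:.{digits}g}"

        root = self.n_leaves + len(self.merges) - 1
        kids = sorted(children[root], key=min_label)
        inner = ",".join(render(c, heights[root]) for c in kids)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise tree distances: twice the height of the joining node."""
        n = self.n_leaves
        out = np.zeros((n, n))
        membership = {i: [i] for i in range(n)}
        for m, (l, r, h) in enumerate(self.merges):
            for i in membership[l]:
                for j in membership[r]:
                    out[i, j] = out[j, i] = 2.0 * h
            membership[n + m] = membership.pop(l) + membership.pop(r)
        return DistanceMatrix(list(self.labels), out)

    def cut(self, k: int) -> pd.Series:
        """Group labels from cutting the tree into exactly ``k`` clusters.

        Applies the first ``n - k`` merges (earliest-merge convention on tied
        heights); groups are numbered 1..k in first-leaf order.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ConfigurationError(f"k must lie in [1, {n}]")
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        roots = {i: i for i in range(n)}  # node id -> union-find root
        for m, (l, r, _) in enumerate(self.merges[: n - k]):
            rl, rr = find(roots[l]), find(roots[r])
            parent[rr] = rl
            roots[n + m] = rl
        groups: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            root = find(i)
            if root not in groups:
                groups[root] = len(groups) + 1
            labels[i] = groups[root]
        return pd.Series(labels, index=self.labels, name="cluster")


def upgma(d: DistanceMatrix) -> Tree:
    """Agglomerative UPGMA clustering of a distance matrix.

    Repeatedly merges the closest pair of clusters at height ``d/2``; the
    distance from a merged cluster to any other is the size-weighted mean of
    its parts (i.e. the plain average over all cross pairs). Ties are broken
    by the lexicographically smallest pair of cluster leader labels.
    """
    n = d.n
    if n < 2:
        raise SaltspecError("need at least two leaves")
    active: dict[int, int] = {i: 1 for i in range(n)}  # node -> cluster size
    leader = {i: d.labels[i] for i in range(n)}  # lexicographic tie-break key
    dist = {frozenset((i, j)): d.values[i, j]
            for i, j in itertools.combinations(range(n), 2)}
    tree = Tree(list(d.labels))
    next_node = n
    while len(active) > 1:
        best = min(
            itertools.combinations(sorted(active), 2),
            key=lambda pair: (dist[frozenset(pair)],
                              *sorted((leader[pair[0]], leader[pair[1]]))),
        )
        a, b = best
        height = dist[frozenset((a, b))] / 2.0
        na, nb = active.pop(a), active.pop(b)
        for other in active:
            dist[frozenset((next_node, other))] = (
                na * dist.pop(frozenset((a, other)))
                + nb * dist.pop(frozenset((b, other)))
            ) / (na + nb)
        dist.pop(frozenset((a, b)))
        tree.merges.append((a, b, height))
        leader[next_node] = min(leader[a], leader[b])
        active[next_node] = na + nb
        next_node += 1
    return tree


def cut_tree(tree: Tree, k: int) -> pd.Series:
    """Module-level alias for :meth:`Tree.cut`."""
    return tree.cut(k)


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix-correlation statistic and its permutation p-value."""

    r: float
    p: float
    n_perm: int
    alternative: str

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm,
                "alternative": self.alternative}


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    ``r`` is the Pearson correlation of the upper-triangle entries; the null
    distribution permutes the rows and columns of ``d2`` simultaneously.
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` for the one-sided
    "greater" default; "two-sided" compares absolute values.
    """
    if d1.labels != d2.labels:
        raise AlignmentError("distance matrices have different labels/order")
    if alternative not in ("greater", "two-sided"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v1c = v1 - v1.mean()
    denom1 = np.sqrt(np.sum(v1c ** 2))
    if denom1 == 0:
        raise SaltspecError("first matrix has zero variance in its distances")

    def corr(mat: np.ndarray) -> float:
        v2 = mat[iu]
        v2c = v2 - v2.mean()
        denom2 = np.sqrt(np.sum(v2c ** 2))
        if denom2 == 0:
            return 0.0
        return float(np.dot(v1c, v2c) / (denom1 * denom2))

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr(d2.values[np.ix_(perm, perm)])
        if alternative == "greater":
            exceed += r_perm >= r_obs - 1e-12
        else:
            exceed += abs(r_perm) >= abs(r_obs) - 1e-12
    p = (1 + exceed) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, alternative)
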