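"""Hierarchical clustering of per-gene epistasis-score profiles.

Genes are clustered on a correlation-based dissimilarity between the rows
of the gene x gene S-score matrix (d = 1 - Pearson r), with average-linkage
agglomeration.  Correlations are computed pairwise-complete over the
partners both genes share; the mutual cell of a pair is excluded so the
dissimilarity is driven by third-party profiles.  Optional bootstrap
support resamples profile columns with replacement and reports, per
internal node, the fraction of resampled trees reproducing that node's
leaf set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import ValidationError

log = logging.getLogger(__name__)

__all__ = ["ScoreProfileMatrix", "Dendrogram", "build_profile_matrix", "cluster_profiles"]


@dataclass
class ScoreProfileMatrix:
    """Symmetric gene x gene epsilon matrix with a missing-value mask.

    The diagonal is always masked (a gene's self-interaction is not a
    measurement); off-diagonal cells are masked for pairs not assayed.
    """

    genes: list[str]
    values: np.ndarray
    mask: np.ndarray  # True where missing

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValidationError("profile matrix shape must match the gene list")

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=self.genes, columns=self.genes)


def build_profile_matrix(scores: pd.DataFrame, family: str = "S") -> ScoreProfileMatrix:
    """Assemble the profile matrix from tidy pairwise scores.

    Duplicate conflicting entries for a pair raise; genes with zero scored
    partners are excluded with a warning.
    """
    sub = scores[(scores["family"] == family) & (scores["gene2"] != "")]
    seen: dict[tuple[str, str], float] = {}
    for r in sub.itertuples():
        key = tuple(sorted((r.gene1, r.gene2)))
        if key in seen and not np.isclose(seen[key], r.epsilon):
            raise ValidationError(f"conflicting duplicate scores for pair {key}")
        seen[key] = float(r.epsilon)
    genes = sorted({g for key in seen for g in key})
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    values = np.zeros((n, n))
    mask = np.ones((n, n), dtype=bool)
    for (g1, g2), eps in seen.items():
        i, j = index[g1], index[g2]
        values[i, j] = values[j, i] = eps
        mask[i, j] = mask[j, i] = False
    counts = (~mask).sum(axis=1)
    keep = counts > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        log.warning("genes with zero scored partners excluded: %s", dropped)
        values = values[np.ix_(keep, keep)]
        mask = mask[np.ix_(keep, keep)]
        genes = [g for g, k in zip(genes, keep) if k]
    return ScoreProfileMatrix(genes=genes, values=values, mask=mask)


@dataclass
class Dendrogram:
    genes: list[str]
    linkage: np.ndarray
    support: dict[int, float] | None = None  # internal node id -> support
    unstable_pairs: list[tuple[str, str]] | None = None

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {g: int(c) for g, c in zip(self.genes, labels)}

    def leaf_partitions(self) -> list[frozenset]:
        """Leaf-name set of every internal node."""
        n = len(self.genes)
        sets: dict[int, frozenset] = {i: frozenset({self.genes[i]}) for i in range(n)}
        out = []
        for i, (a, b, *_rest) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + i] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.genes[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            label = ""
            if self.support is not None and node.id in self.support:
                label = f"{self.support[node.id]:.2f}"
            return f"({left},{right}){label}:{length:.6g}"

        root = tree
        inner = ",".join(walk(c, root.dist) for c in (root.left, root.right))
        label = ""
        if self.support is not None and root.id in self.support:
            label = f"{self.support[root.id]:.2f}"
        return f"({inner}){label};"


def _dissimilarity(matrix: ScoreProfileMatrix, min_common: int = 3):
    """Condensed 1 - Pearson distance; flags unstable pairs (< min_common
    shared partners) and raises when a correlation is undefined."""
    n = len(matrix.genes)
    vals, mask = matrix.values, matrix.mask
    d = np.zeros(n * (n - 1) // 2)
    unstable = []
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            common = ~mask[i] & ~mask[j]
            common[i] = common[j] = False  # exclude the mutual cell
            k = int(common.sum())
            if k < 2:
                raise ValidationError(
                    f"dissimilarity undefined for pair ({matrix.genes[i]}, {matrix.genes[j]}): "
                    f"{k} shared partners"
                )
            if k < min_common:
                unstable.append((matrix.genes[i], matrix.genes[j]))
            a, b = vals[i, common], vals[j, common]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                raise ValidationError(
                    f"dissimilarity undefined for pair ({matrix.genes[i]}, {matrix.genes[j]}): "
                    "constant profile over shared partners"
                )
            r = float(np.corrcoef(a, b)[0, 1])
            d[idx] = 1.0 - r
            idx += 1
    return d, unstable


def cluster_profiles(matrix: ScoreProfileMatrix, n_bootstrap: int = 0, seed: int | None = None) -> Dendrogram:
    """Average-linkage tree on the correlation dissimilarity.

    With ``n_bootstrap > 0``, per-node support is the fraction of
    column-resampled trees containing the node's exact leaf set (plain
    bootstrap, no multiscale correction).
    """
    if len(matrix.genes) < 3:
        raise ValidationError("clustering needs at least 3 genes")
    d, unstable = _dissimilarity(matrix)
    if unstable:
        log.warning("unstable correlations (few shared partners): %s", unstable)
    link = hierarchy.linkage(np.clip(d, 0.0, None), method="average")
    dendro = Dendrogram(genes=list(matrix.genes), linkage=link, unstable_pairs=unstable)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(matrix.genes)
        targets = dendro.leaf_partitions()
        counts = np.zeros(len(targets))
        n_ok = 0
        for _ in range(n_bootstrap):
            cols = rng.integers(0, n, size=n)
            boot = ScoreProfileMatrix(
                genes=list(matrix.genes),
                values=matrix.values[:, cols],
                mask=matrix.mask[:, cols],
            )
            try:
                db, _ = _dissimilarity(boot)
            except ValidationError:
                # a resample can leave a profile constant; skip it
                continue
            n_ok += 1
            lb = hierarchy.linkage(np.clip(db, 0.0, None), method="average")
            parts = set(Dendrogram(genes=list(matrix.genes), linkage=lb).leaf_partitions())
            for t, target in enumerate(targets):
                if target in parts:
                    counts[t] += 1
        if n_ok == 0:
            raise ValidationError("every bootstrap resample was degenerate")
        dendro.support = {n + t: counts[t] / n_ok for t in range(len(targets))}
    return dendro
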