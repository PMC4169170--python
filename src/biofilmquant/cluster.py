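"""Hierarchical clustering of strains by normalized phenotype vectors.

Strains are represented as vectors of phenotype values on the common
[0, 5] scale, compared by Euclidean distance and clustered
agglomeratively (average linkage by default). Outputs are written in the
tab-delimited CDT/GTR dialect that Java TreeView loads, plus Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .panel import aggregate_replicates, linear_normalize

LINKAGES = {"average", "complete", "single"}


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Strain x phenotype matrix on the normalized [0, 5] scale."""

    strains: tuple[str, ...]
    phenotypes: tuple[str, ...]
    values: np.ndarray
    niche_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.strains), len(self.phenotypes)):
            raise ValidationError("matrix shape does not match labels")
        if np.any(~np.isfinite(vals)):
            bad = [self.strains[i] for i in np.unique(np.nonzero(~np.isfinite(vals))[0])]
            raise ValidationError(f"missing phenotype values for strains {bad}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "strains", tuple(self.strains))
        object.__setattr__(self, "phenotypes", tuple(self.phenotypes))

    def sorted_by_strain(self) -> "PhenotypeMatrix":
        """Rows reordered lexicographically by strain id (canonical order)."""
        order = np.argsort(np.asarray(self.strains))
        niches = (
            tuple(np.asarray(self.niche_labels)[order]) if self.niche_labels else None
        )
        return PhenotypeMatrix(
            strains=tuple(np.asarray(self.strains)[order]),
            phenotypes=self.phenotypes,
            values=self.values[order],
            niche_labels=niches,
        )


def matrix_from_panel(
    panel: pd.DataFrame,
    ploidy: str = "haploid",
    phenotypes: Sequence[str] | None = None,
    normalize: bool = True,
) -> PhenotypeMatrix:
    """Build a clustering matrix from a long-format panel.

    Technical replicates are averaged, one ploidy stratum is selected and
    each phenotype is linearly normalized to [0, 5] across strains.
    Strains missing any phenotype are dropped (not imputed).
    """
    agg = aggregate_replicates(panel, "technical")
    sub = agg[agg["ploidy"] == ploidy]
    wide = sub.pivot_table(index="strain", columns="phenotype", values="value",
                           aggfunc="mean")
    if phenotypes is not None:
        wide = wide[list(phenotypes)]
    wide = wide.dropna(axis=0)
    if wide.shape[0] < 2:
        raise ValidationError("need at least two complete strains to cluster")
    vals = wide.to_numpy(dtype=float)
    if normalize:
        vals = np.column_stack([linear_normalize(vals[:, j]) for j in range(vals.shape[1])])
    return PhenotypeMatrix(
        strains=tuple(wide.index), phenotypes=tuple(wide.columns), values=vals
    )


def euclidean_distances(matrix: PhenotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise Euclidean distance table between strains."""
    if len(matrix.strains) < 2:
        raise ValidationError("need at least two strains")
    dm = squareform(pdist(matrix.values, metric="euclidean"))
    return pd.DataFrame(dm, index=list(matrix.strains), columns=list(matrix.strains))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result.

    ``linkage_matrix`` follows the SciPy convention (rows of
    ``[node_a, node_b, height, size]``); ``labels`` index the leaves in
    the canonical (lexicographic) strain order used for clustering.
    """

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix
        ]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return tuple(self.labels[i] for i in order)

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment for the top ``n_clusters`` split."""
        flat = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return {s: int(c) for s, c in zip(self.labels, flat)}


def hcluster(matrix: PhenotypeMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of strains by Euclidean distance.

    Rows are put in lexicographic strain order before clustering so the
    result is invariant to the input row order (deterministic
    tie-breaking).
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {sorted(LINKAGES)}")
    if len(matrix.strains) < 2:
        raise ValidationError("need at least two strains")
    canon = matrix.sorted_by_strain()
    z = hierarchy.linkage(pdist(canon.values), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=canon.strains)


# ---------------------------------------------------------------------------
# TreeView / Newick output
# ---------------------------------------------------------------------------


def to_newick(tree: Dendrogram) -> str:
    """Newick string with branch lengths (parent height - child height)."""
    root = hierarchy.to_tree(tree.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(root, root.dist) + ";"


def write_treeview(
    matrix: PhenotypeMatrix, tree: Dendrogram, outdir: str | Path, stem: str = "phenotypes"
) -> dict[str, Path]:
    """Write TreeView-compatible CDT/GTR files plus Newick and leaf order.

    The CDT holds the data matrix with rows in dendrogram leaf order and
    the GID/ORF/NAME/GWEIGHT header TreeView expects; the GTR stores each
    merge on a similarity scale (1 - height/max_height), since TreeView
    node values are correlations rather than distances.
    """
    if set(matrix.strains) != set(tree.labels):
        raise ValidationError("matrix and tree leaf sets differ")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    canon = matrix.sorted_by_strain()
    index = {s: i for i, s in enumerate(canon.strains)}
    gid = {s: f"GENE{index[s]}X" for s in canon.strains}
    niche = dict(zip(canon.strains, canon.niche_labels or canon.strains))

    cdt_path = outdir / f"{stem}.cdt"
    with open(cdt_path, "w", newline="\n") as fh:
        header = ["GID", "ORF", "NAME", "GWEIGHT", *canon.phenotypes]
        fh.write("\t".join(header) + "\n")
        for strain in tree.leaf_order:
            row = canon.values[index[strain]]
            fields = [gid[strain], strain, str(niche[strain]), "1.0"]
            fields += [f"{v:.6g}" for v in row]
            fh.write("\t".join(fields) + "\n")

    heights = tree.linkage_matrix[:, 2]
    d_max = heights.max() if heights.max() > 0 else 1.0
    n = len(tree.labels)
    gtr_path = outdir / f"{stem}.gtr"
    with open(gtr_path, "w", newline="\n") as fh:
        for k, (a, b, h, _) in enumerate(tree.linkage_matrix):
            def node_name(i: int) -> str:
                return (
                    gid[tree.labels[int(i)]] if i < n else f"NODE{int(i) - n + 1}X"
                )
            sim = 1.0 - h / d_max
            fh.write(
                f"NODE{k + 1}X\t{node_name(a)}\t{node_name(b)}\t{sim:.6f}\n"
            )

    nwk_path = outdir / f"{stem}.nwk"
    nwk_path.write_text(to_newick(tree) + "\n")
    order_path = outdir / f"{stem}.leaf_order.txt"
    order_path.write_text("\n".join(tree.leaf_order) + "\n")
    return {"cdt": cdt_path, "gtr": gtr_path, "nwk": nwk_path, "leaf_order": order_path}
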