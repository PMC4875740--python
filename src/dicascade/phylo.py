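"""Ultrametric phylogenies and the scaled phylogenetic covariance matrix.

Under Brownian-motion trait evolution on an ultrametric tree, the expected
covariance between two species is proportional to the root-to-MRCA path
length they share.  Dividing by tree height gives the scaled matrix ``Sigma``
with unit diagonal used by the phylogenetic random effect of the mixed
models, which in turn makes the phylogenetic variance component directly
comparable with the species-level and residual components in Pagel's

    lambda = sigma2_p / (sigma2_p + sigma2_s + sigma2_e).

Tree I/O is delegated to dendropy (Newick and NEXUS).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "VarianceComponents",
    "parse_newick",
    "covariance_from_tree",
    "pagels_lambda",
    "normalize_label",
    "match_taxa",
]

#: Residual variance of the latent logistic scale for Bernoulli models.
LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3.0

ULTRAMETRIC_RTOL = 1e-6


def normalize_label(label: str) -> str:
    """Canonical taxon label: stripped, single-spaced, underscores as spaces."""
    return re.sub(r"\s+", " ", str(label).replace("_", " ").strip())


@dataclass
class Phylogeny:
    """An ultrametric tree with branch lengths, wrapping a dendropy Tree."""

    tree: dendropy.Tree

    @classmethod
    def from_string(cls, text: str, schema: str = "newick") -> "Phylogeny":
        tree = dendropy.Tree.get(data=text, schema=schema)
        return cls(tree)._validate()

    @classmethod
    def from_file(cls, path, schema: str | None = None) -> "Phylogeny":
        path = str(path)
        if schema is None:
            schema = "nexus" if path.lower().endswith((".nex", ".nexus")) else "newick"
        tree = dendropy.Tree.get(path=path, schema=schema)
        return cls(tree)._validate()

    def _validate(self) -> "Phylogeny":
        labels = self.taxa
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
        depths = self._tip_depths()
        h = max(depths.values())
        if h <= 0:
            raise ValueError("tree has zero height")
        for label, d in depths.items():
            if abs(d - h) > ULTRAMETRIC_RTOL * h:
                raise ValueError(
                    f"tree is not ultrametric: tip {label!r} at depth {d:.6g} "
                    f"vs height {h:.6g}"
                )
        return self

    def _tip_depths(self) -> dict[str, float]:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = getattr(node.parent_node, "_depth", 0.0) if node.parent_node else 0.0
            node._depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[normalize_label(node.taxon.label)] = node._depth
        return depths

    @property
    def taxa(self) -> list[str]:
        return [
            normalize_label(leaf.taxon.label)
            for leaf in self.tree.leaf_node_iter()
        ]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def height(self) -> float:
        return max(self._tip_depths().values())

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def prune_to(self, labels) -> "Phylogeny":
        """Subtree spanning ``labels``, re-rooted at their MRCA."""
        wanted = {normalize_label(l) for l in labels}
        missing = wanted - set(self.taxa)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        keep = [
            t.label
            for t in self.tree.taxon_namespace
            if normalize_label(t.label) in wanted
        ]
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        # fresh namespace: never mutate the namespace shared with self.tree
        sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
        # drop any stem above the MRCA of the retained taxa
        while (
            sub.seed_node.num_child_nodes() == 1
            and not sub.seed_node.is_leaf()
        ):
            child = sub.seed_node.child_nodes()[0]
            child.edge.length = None
            sub.seed_node = child
            child.parent_node = None
        sub.seed_node.edge.length = None
        return Phylogeny(sub)._validate()


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated ultrametric phylogeny."""
    return Phylogeny.from_string(text, schema="newick")


@dataclass
class PhyloCovariance:
    """Scaled phylogenetic covariance matrix with its taxon ordering.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of taxa i and j
    divided by tree height: unit diagonal, off-diagonals in [0, 1].
    """

    matrix: np.ndarray
    taxa: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix order must match taxa list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.matrix).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"covariance matrix not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )

    def reorder(self, labels) -> "PhyloCovariance":
        """Covariance restricted/permuted to ``labels`` order."""
        want = [normalize_label(l) for l in labels]
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [l for l in want if l not in index]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = np.array([index[l] for l in want])
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], want)


def covariance_from_tree(tree: Phylogeny) -> PhyloCovariance:
    """Scaled Brownian covariance from an ultrametric tree.

    Uses patristic distances: for an ultrametric tree of height H,
    shared(i, j) = H - d(i, j)/2, so Sigma = 1 - D/(2H).
    """
    taxa = tree.taxa
    h = tree.height
    if h <= 0:
        raise ValueError("tree has zero height")
    pdm = tree.tree.phylogenetic_distance_matrix()
    leaves = {
        normalize_label(t.label): t
        for t in tree.tree.taxon_namespace
    }
    n = len(taxa)
    sigma = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[taxa[i]], leaves[taxa[j]])
            sigma[i, j] = sigma[j, i] = 1.0 - d / (2.0 * h)
    np.clip(sigma, 0.0, 1.0, out=sigma)
    np.fill_diagonal(sigma, 1.0)
    return PhyloCovariance(sigma, taxa)


@dataclass(frozen=True)
class VarianceComponents:
    """Phylogenetic, species-i.i.d. and residual variance components."""

    sigma2_p: float
    sigma2_s: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if min(self.sigma2_p, self.sigma2_s, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")


def pagels_lambda(vc: VarianceComponents) -> float:
    """Phylogenetic signal: fraction of total variance that is phylogenetic.

    For Bernoulli models the residual component is the fixed logistic
    variance pi^2/3 and must be supplied as such in ``vc``.
    """
    total = vc.sigma2_p + vc.sigma2_s + vc.sigma2_e
    if total <= 0:
        raise ValueError("lambda undefined when all variance components are zero")
    return vc.sigma2_p / total


def match_taxa(cov_taxa, data_species) -> dict[str, str]:
    """Map data species names onto covariance taxa (normalised exact match).

    Raises with a full listing of unmatched names; name matching failures
    should never pass silently into a fit.
    """
    lookup = {normalize_label(t): t for t in cov_taxa}
    mapping, missing = {}, []
    for sp in data_species:
        key = normalize_label(sp)
        if key in lookup:
            mapping[sp] = lookup[key]
        else:
            missing.append(sp)
    if missing:
        raise KeyError(
            f"{len(missing)} species absent from the phylogeny: {sorted(missing)}"
        )
    return mapping
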