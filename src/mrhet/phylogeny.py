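"""Tumor phylogeny reconstruction from binary mutation presence/absence.

Each tumor region (plus the mutation-free matched normal) is a taxon and each
mutated gene (or individual variant) is a binary character. Pairwise genetic
distances are either the raw mismatch fraction (p-distance) or its
Cavender–Farris–Neyman correction d = -0.5*ln(1 - 2p), the two-state
analogue of corrected nucleotide distances. Trees are built by Saitou–Nei
neighbor joining, optionally refined by maximum likelihood under the
symmetric two-state Markov model (Felsenstein pruning, coordinate-wise
branch-length optimization, optional NNI topology search), and branch
support is estimated by nonparametric bootstrap over characters. Rooting at
the normal sample orients the tree from the germline state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .heterogeneity import GeneRegionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CharacterMatrix",
    "build_character_matrix",
    "variant_character_matrix",
    "DistanceMatrix",
    "pairwise_distance",
    "cfn_distance",
    "PhyloTree",
    "neighbor_joining",
    "log_likelihood",
    "ml_optimize",
    "bootstrap_support",
    "root_at_normal",
    "robinson_foulds",
]

Bipartition = frozenset  # frozenset({frozenset(side_a), frozenset(side_b)})


# ---------------------------------------------------------------------------
# character matrices and distances
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Binary presence/absence characters for taxa (regions + optional normal)."""

    taxa: list[str]
    data: np.ndarray  # bool, shape (n_taxa, n_sites)
    site_ids: list[str]
    normal: str | None = None  # taxon name of the all-absent normal, if any

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != (len(self.taxa), len(self.site_ids)):
            raise ValueError("character matrix shape mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.normal is not None:
            if self.normal not in self.taxa:
                raise ValueError(f"normal taxon {self.normal!r} not present")
            if self.data[self.taxa.index(self.normal)].any():
                raise ValueError("normal taxon row must be all-absent")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def resample_sites(self, site_idx: Sequence[int]) -> "CharacterMatrix":
        idx = np.asarray(site_idx)
        return CharacterMatrix(
            taxa=list(self.taxa),
            data=self.data[:, idx],
            site_ids=[self.site_ids[i] for i in idx],
            normal=self.normal,
        )


def build_character_matrix(
    m: GeneRegionMatrix,
    include_normal: bool = True,
    normal_name: str = "N",
) -> CharacterMatrix:
    """One binary site per mutated gene; the normal is an all-absent row.

    Constant (all-present) sites are retained; they carry no topological
    signal but are flagged in the log.
    """
    if m.n_regions < 2:
        raise ValueError("need >= 2 tumor regions to build characters")
    taxa = m.region_ids()
    data = m.present.T.copy()
    normal = None
    if include_normal:
        if normal_name in taxa:
            raise ValueError(f"normal name {normal_name!r} clashes with a region id")
        taxa = taxa + [normal_name]
        data = np.vstack([data, np.zeros((1, m.n_genes), dtype=bool)])
        normal = normal_name
    n_constant = int((data.all(axis=0) | (~data).all(axis=0)).sum())
    if n_constant:
        logger.info("character matrix contains %d constant site(s)", n_constant)
    return CharacterMatrix(taxa=taxa, data=data, site_ids=list(m.genes), normal=normal)


def variant_character_matrix(
    variants,
    regions,
    classes=None,
    include_normal: bool = True,
    normal_name: str = "N",
) -> CharacterMatrix:
    """One binary site per distinct variant (gene, chrom, pos, ref, alt).

    The variant-level alternative to gene-level characters: a gene hit by
    several independent mutations contributes one site per mutation, so the
    site count is always >= the gene-level count over the same calls.
    """
    from .heterogeneity import classify_consequence

    tumor_regions = [r for r in regions if not r.is_normal]
    if len(tumor_regions) < 2:
        raise ValueError("need >= 2 tumor regions to build characters")
    region_index = {r: i for i, r in enumerate(tumor_regions)}
    presence: dict[tuple, np.ndarray] = {}
    for v in variants:
        if v.region.is_normal:
            continue
        if v.region not in region_index:
            raise ValueError(f"variant region {v.region} not in region list")
        if classes is not None and classify_consequence(v) not in classes:
            continue
        key = (v.gene, v.chrom, v.pos, v.ref, v.alt)
        row = presence.setdefault(key, np.zeros(len(tumor_regions), dtype=bool))
        row[region_index[v.region]] = True
    keys = sorted(presence)
    data = (
        np.array([presence[k] for k in keys], dtype=bool).T
        if keys
        else np.zeros((len(tumor_regions), 0), dtype=bool)
    )
    taxa = [r.region_id for r in tumor_regions]
    normal = None
    if include_normal:
        taxa = taxa + [normal_name]
        data = np.vstack([data, np.zeros((1, data.shape[1]), dtype=bool)])
        normal = normal_name
    site_ids = [f"{g}:{c}:{p}:{ref}>{alt}" for g, c, p, ref, alt in keys]
    return CharacterMatrix(taxa=taxa, data=data, site_ids=site_ids, normal=normal)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")


#: p-distance cap for the CFN correction; p >= 0.5 has no finite distance.
P_CAP = 0.49
D_MAX = -0.5 * math.log(1.0 - 2.0 * P_CAP)


def cfn_distance(p: float) -> float:
    """Two-state (CFN) distance correction d = -0.5*ln(1-2p), capped at the
    distance of p = 0.49 for saturated comparisons."""
    if p >= 0.5:
        logger.info("p-distance %.3f saturated; capped at d=%.4f", p, D_MAX)
        return D_MAX
    return -0.5 * math.log(1.0 - 2.0 * p)


def pairwise_distance(c: CharacterMatrix, model: str = "cfn") -> DistanceMatrix:
    """Pairwise distances between taxa from binary characters.

    ``p_distance``: mismatch fraction over sites. ``cfn``: its CFN
    correction (see :func:`cfn_distance`).
    """
    if c.n_sites == 0:
        raise ValueError("cannot compute distances with zero sites")
    if model not in ("p_distance", "cfn"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(c.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float((c.data[i] != c.data[j]).mean())
            dij = p if model == "p_distance" else cfn_distance(p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=list(c.taxa), d=d)


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted (optionally rooted) tree with branch lengths and supports.

    Stored as an undirected adjacency map over integer node ids; leaves carry
    taxon names. Bootstrap supports live in a bipartition-keyed dict so they
    survive rerooting unchanged.
    """

    def __init__(
        self,
        adjacency: dict[int, dict[int, float]],
        leaf_names: dict[int, str],
        supports: dict[Bipartition, float] | None = None,
        root: int | None = None,
    ):
        self.adjacency = adjacency
        self.leaf_names = leaf_names
        self.supports = supports if supports is not None else {}
        self.root = root
        names = list(leaf_names.values())
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        for node, nbrs in adjacency.items():
            for other, length in nbrs.items():
                if length < 0:
                    raise ValueError("negative branch length")
                if adjacency[other].get(node) != length:
                    raise ValueError("adjacency must be symmetric")
        for leaf in leaf_names:
            if len(adjacency[leaf]) != 1:
                raise ValueError("leaves must have degree 1")

    # -- basic structure ----------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def leaves(self) -> list[int]:
        return sorted(self.leaf_names)

    def node_of(self, name: str) -> int:
        for node, label in self.leaf_names.items():
            if label == name:
                return node
        raise KeyError(f"no leaf named {name!r}")

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, length in nbrs.items():
                if u < v:
                    out.append((u, v, length))
        return sorted(out)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            adjacency={u: dict(nbrs) for u, nbrs in self.adjacency.items()},
            leaf_names=dict(self.leaf_names),
            supports=dict(self.supports),
            root=self.root,
        )

    def total_length(self) -> float:
        return sum(length for _, _, length in self.edges())

    # -- bipartitions -------------------------------------------------------

    def _names_below(self, u: int, v: int) -> frozenset[str]:
        """Leaf names on the v-side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        names = []
        while stack:
            node = stack.pop()
            if node in self.leaf_names:
                names.append(self.leaf_names[node])
            for nbr in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(names)

    def bipartition_of_edge(self, u: int, v: int) -> Bipartition:
        side = self._names_below(u, v)
        return frozenset({side, frozenset(self.taxa) - side})

    def bipartitions(self) -> dict[Bipartition, tuple[int, int]]:
        """Nontrivial bipartitions (both sides >= 2 taxa) keyed to their edge."""
        out: dict[Bipartition, tuple[int, int]] = {}
        for u, v, _ in self.edges():
            bip = self.bipartition_of_edge(u, v)
            if min(len(side) for side in bip) >= 2:
                out[bip] = (u, v)
        return out

    # -- serialization ------------------------------------------------------

    def to_newick(self, with_supports: bool = True) -> str:
        if self.root is not None:
            start = self.root
        else:
            internal = [n for n in self.adjacency if n not in self.leaf_names]
            if not internal:  # two-leaf tree
                (a, b, length), = self.edges()
                return f"({self.leaf_names[a]}:{length:g},{self.leaf_names[b]}:{length:g});"
            start = min(internal, key=lambda n: (-self.degree(n), n))
        all_taxa = frozenset(self.taxa)

        def label_for(parent: int, child: int) -> str:
            if child in self.leaf_names or not with_supports:
                return ""
            bip = self.bipartition_of_edge(parent, child)
            if min(len(s) for s in bip) < 2:
                return ""
            sup = self.supports.get(bip)
            return "" if sup is None else str(int(round(sup)))

        def serialize(node: int, parent: int | None) -> str:
            if node in self.leaf_names:
                name = self.leaf_names[node]
                if not name:
                    raise ValueError("cannot serialize an unnamed leaf")
                return name
            children = [n for n in self.adjacency[node] if n != parent]
            parts = sorted(
                (
                    serialize(c, node)
                    + (label_for(node, c) if c not in self.leaf_names else "")
                    + f":{self.adjacency[node][c]:g}"
                    for c in children
                ),
            )
            return "(" + ",".join(parts) + ")"

        return serialize(start, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        adjacency: dict[int, dict[int, float]] = {}
        leaf_names: dict[int, str] = {}
        ids: dict[dendropy.Node, int] = {}
        for i, node in enumerate(tree.preorder_node_iter()):
            ids[node] = i
            adjacency[i] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 0.0
                adjacency[ids[node]][ids[node.parent_node]] = length
                adjacency[ids[node.parent_node]][ids[node]] = length
            if node.is_leaf():
                leaf_names[ids[node]] = node.taxon.label
        seed = ids[tree.seed_node]
        root = seed if len(adjacency[seed]) == 2 else None
        out = cls(adjacency=adjacency, leaf_names=leaf_names, root=root)
        # recover supports from internal-node labels
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            bip = out.bipartition_of_edge(ids[node.parent_node], ids[node])
            out.supports[bip] = float(node.label)
        return out

    # -- rooting ------------------------------------------------------------

    def unroot(self) -> "PhyloTree":
        """Remove a degree-2 root, merging its two incident edges."""
        out = self.copy()
        if out.root is None:
            return out
        r = out.root
        if out.degree(r) == 2 and r not in out.leaf_names:
            (a, la), (b, lb) = out.adjacency[r].items()
            del out.adjacency[r]
            del out.adjacency[a][r]
            del out.adjacency[b][r]
            out.adjacency[a][b] = la + lb
            out.adjacency[b][a] = la + lb
        out.root = None
        return out


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the Q-criterion.

    Ties in Q are broken by the smallest (i, j) index pair in the current
    taxon ordering, negative limb lengths are clamped to zero, and the output
    is unrooted (final trifurcation resolved by the three-point formulas).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.d.astype(float).copy()
    # active[i] = node id represented by matrix row i
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = {i: name for i, name in enumerate(dm.taxa)}
    active = list(range(n))
    next_id = n

    def add_edge(u: int, v: int, length: float) -> None:
        length = max(0.0, float(length))
        adjacency.setdefault(u, {})[v] = length
        adjacency.setdefault(v, {})[u] = length

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) pair
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        new = next_id
        next_id += 1
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        add_edge(active[i], new, li)
        add_edge(active[j], new, lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[:-1, -1] = d_next[-1, :-1] = dnew[keep]
        d = d_next
        active = [active[k] for k in keep] + [new]

    # resolve the final three nodes around a central vertex
    (x, y, z) = active
    center = next_id
    add_edge(x, center, (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0)
    add_edge(y, center, (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0)
    add_edge(z, center, (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0)
    return PhyloTree(adjacency=adjacency, leaf_names=leaf_names)


# ---------------------------------------------------------------------------
# two-state maximum likelihood
# ---------------------------------------------------------------------------


def _transition_probs(t: float) -> tuple[float, float]:
    """CFN transition probabilities (P(same), P(different)) after length t."""
    e = math.exp(-2.0 * t)
    return (1.0 + e) / 2.0, (1.0 - e) / 2.0


def log_likelihood(tree: PhyloTree, c: CharacterMatrix) -> float:
    """Total log-likelihood of the characters on the tree under the symmetric
    two-state model (equal stationary frequencies), by Felsenstein pruning."""
    if c.n_sites == 0:
        raise ValueError("zero sites")
    if sorted(tree.taxa) != sorted(c.taxa):
        raise ValueError("tree leaves and character taxa differ")
    row_of = {name: i for i, name in enumerate(c.taxa)}
    # root the traversal anywhere internal (model is reversible)
    internal = [n for n in tree.adjacency if n not in tree.leaf_names]
    start = tree.root if tree.root is not None else min(internal)

    n_sites = c.n_sites
    def conditional(node: int, parent: int | None) -> np.ndarray:
        """Partial likelihoods, shape (2, n_sites)."""
        if node in tree.leaf_names:
            cl = np.zeros((2, n_sites))
            states = c.data[row_of[tree.leaf_names[node]]].astype(int)
            cl[0, :] = states == 0
            cl[1, :] = states == 1
            return cl
        cl = np.ones((2, n_sites))
        for child in tree.adjacency[node]:
            if child == parent:
                continue
            child_cl = conditional(child, node)
            same, diff = _transition_probs(tree.adjacency[node][child])
            p = np.array([[same, diff], [diff, same]])
            cl *= p @ child_cl
        return cl

    root_cl = conditional(start, None)
    site_lik = 0.5 * root_cl.sum(axis=0)
    if (site_lik <= 0).any():
        return -math.inf
    return float(np.log(site_lik).sum())


def _optimize_lengths(
    tree: PhyloTree,
    c: CharacterMatrix,
    rel_tol: float = 1e-6,
    sweep_tol: float = 1e-8,
    max_len: float = 20.0,
    max_sweeps: int = 50,
) -> float:
    """Coordinate-wise branch-length optimization in place; returns log-L."""
    current = log_likelihood(tree, c)
    for _ in range(max_sweeps):
        for u, v, _length in tree.edges():
            def neg_ll(t: float) -> float:
                tree.adjacency[u][v] = tree.adjacency[v][u] = t
                return -log_likelihood(tree, c)

            res = minimize_scalar(
                neg_ll,
                bounds=(0.0, max_len),
                method="bounded",
                options={"xatol": rel_tol},
            )
            tree.adjacency[u][v] = tree.adjacency[v][u] = float(res.x)
        new = log_likelihood(tree, c)
        if new < current - 1e-9:  # never accept a decrease (ascent property)
            raise AssertionError("branch-length sweep decreased the likelihood")
        if new - current < sweep_tol:
            current = new
            break
        current = new
    return current


def _nni_neighbors(tree: PhyloTree) -> Iterable[PhyloTree]:
    """All trees one nearest-neighbor interchange away (internal edges only)."""
    for u, v, _ in tree.edges():
        if u in tree.leaf_names or v in tree.leaf_names:
            continue
        u_nbrs = [n for n in tree.adjacency[u] if n != v]
        v_nbrs = [n for n in tree.adjacency[v] if n != u]
        if len(u_nbrs) < 2 or len(v_nbrs) < 1:
            continue
        a = u_nbrs[1]  # swap u's second subtree with each v-side subtree
        for b in v_nbrs:
            out = tree.copy()
            la = out.adjacency[u].pop(a)
            del out.adjacency[a][u]
            lb = out.adjacency[v].pop(b)
            del out.adjacency[b][v]
            out.adjacency[v][a] = out.adjacency[a][v] = la
            out.adjacency[u][b] = out.adjacency[b][u] = lb
            out.supports = {}
            yield out


def ml_optimize(
    tree: PhyloTree,
    c: CharacterMatrix,
    search: str = "lengths_only",
) -> tuple[PhyloTree, float]:
    """Maximum-likelihood refinement of a starting tree.

    ``lengths_only`` optimizes branch lengths on the fixed topology;
    ``nni`` additionally accepts nearest-neighbor interchanges while they
    improve the log-likelihood.
    """
    if search not in ("lengths_only", "nni"):
        raise ValueError(f"unknown search {search!r}")
    # optimize on the unrooted tree (the model is reversible, so the root is
    # irrelevant to the likelihood, and NNI is defined on internal edges)
    best = tree.unroot() if tree.root is not None else tree.copy()
    best_ll = _optimize_lengths(best, c)
    if search == "nni":
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(best):
                # fresh-start lengths: a saturated incumbent would otherwise
                # leave the candidate in a flat region of the likelihood
                for u, v, _ in cand.edges():
                    cand.adjacency[u][v] = cand.adjacency[v][u] = 0.5
                ll = _optimize_lengths(cand, c)
                if ll > best_ll + 1e-8:
                    best, best_ll = cand, ll
                    improved = True
                    break
    return best, best_ll


# ---------------------------------------------------------------------------
# bootstrap and rooting
# ---------------------------------------------------------------------------


def bootstrap_support(
    c: CharacterMatrix,
    n: int = 1000,
    seed: int = 0,
    model: str = "cfn",
    search: str | None = None,
) -> PhyloTree:
    """Nonparametric bootstrap over characters.

    Sites are resampled with replacement; each replicate is rebuilt by the
    same distance + NJ (+ optional ML) path as the base tree, and the support
    of each internal edge is the percentage of replicates containing the same
    bipartition. Replicate r draws from an independent substream keyed by
    (seed, r), so results depend only on the seed.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    base = neighbor_joining(pairwise_distance(c, model=model))
    if search is not None:
        base, _ = ml_optimize(base, c, search=search)
    target = base.bipartitions()
    hits = {bip: 0 for bip in target}
    for r in range(n):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, c.n_sites, size=c.n_sites)
        rep = c.resample_sites(idx)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model=model))
        except ValueError:  # degenerate replicate (e.g. all-constant sites)
            continue
        if search is not None:
            rep_tree, _ = ml_optimize(rep_tree, rep, search=search)
        rep_bips = set(rep_tree.bipartitions())
        for bip in hits:
            if bip in rep_bips:
                hits[bip] += 1
    base.supports = {bip: 100.0 * k / n for bip, k in hits.items()}
    return base


def root_at_normal(tree: PhyloTree, normal_name: str) -> PhyloTree:
    """Root the tree on the edge leading to the normal sample (outgroup
    rooting at the germline state); bipartition supports are preserved."""
    out = tree.copy()
    leaf = out.node_of(normal_name)
    (u, length), = out.adjacency[leaf].items()
    root = max(out.adjacency) + 1
    del out.adjacency[leaf][u]
    del out.adjacency[u][leaf]
    out.adjacency[root] = {leaf: length / 2.0, u: length / 2.0}
    out.adjacency[leaf][root] = length / 2.0
    out.adjacency[u][root] = length / 2.0
    out.root = root
    return out


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted Robinson–Foulds distance: size of the symmetric difference of
    the nontrivial bipartition sets. Requires identical taxon sets."""
    if sorted(a.taxa) != sorted(b.taxa):
        raise ValueError("trees must share the same taxa")
    bips_a = set(a.unroot().bipartitions())
    bips_b = set(b.unroot().bipartitions())
    return len(bips_a ^ bips_b)
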