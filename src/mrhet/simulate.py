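"""Clonal-evolution simulator for multi-region tumor sampling.

Generates, from a single seed, a patient-like dataset: a random bifurcating
clone tree; trunk mutations on the root edge (shared by every region),
branch mutations on internal edges and private mutations on leaf edges
(Poisson counts); one sampled region per leaf clone, each observing the
union of mutations on its clone's root path; an optional metastasis clone
attached below a non-root clone; per-region copy-number segments (shared
ones assigned to the root, private ones to leaves); and an all-absent
matched normal. Observation noise (per-entry dropout and false positives)
is applied to the gene-region presence table after the clean assignment.

The full generating truth is returned so recovery of the trunk / branch /
private decomposition, heterogeneity rate and region topology can be scored
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .heterogeneity import (
    GeneRegionMatrix,
    HeterogeneityReport,
    classify_trunk_branch_private,
)
from .io import (
    CNVSegment,
    CNVState,
    RegionLabel,
    VariantCall,
    write_cnv_segments,
    write_region_variants,
)
from .phylogeny import PhyloTree, robinson_foulds

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "RecoveryMetrics",
    "evaluate_recovery",
    "compatible_character_matrix",
]


def compatible_character_matrix(n_per_split: int = 25):
    """Perfectly compatible binary characters over four tumor regions and a
    normal: two cherries (T1,T2) and (T3,T4), n sites per split, n private
    sites per region, and 6n trunk sites shared by every tumor region.

    The trunk-heavy composition keeps all tumor-tumor mismatch fractions
    well inside the CFN-correctable range (p <= 1/3), so distance-based
    reconstruction of the two cherries is unambiguous; only the distances to
    the mutation-free normal saturate, uniformly across regions.
    """
    from .phylogeny import CharacterMatrix

    sites = []
    sites += [[1, 1, 0, 0, 0]] * n_per_split  # T1+T2 cherry
    sites += [[0, 0, 1, 1, 0]] * n_per_split  # T3+T4 cherry
    sites += [[1, 1, 1, 1, 0]] * (6 * n_per_split)  # trunk
    for leaf in range(4):  # private sites keep terminal branches positive
        row = [0] * 5
        row[leaf] = 1
        sites += [row] * n_per_split
    data = np.array(sites, bool).T
    return CharacterMatrix(
        ["T1", "T2", "T3", "T4", "N"],
        data,
        [f"s{i}" for i in range(data.shape[1])],
        normal="N",
    )

# consequence tokens drawn for simulated variants (weights sum to 1); the
# mix leans nonsynonymous, the way exome calls do once silent sites are set
# aside, and exercises every non-silent class downstream.
_CONSEQUENCES = (
    ("nonsynonymous SNV", 0.70),
    ("stopgain", 0.10),
    ("splicing", 0.08),
    ("frameshift insertion", 0.07),
    ("nonframeshift deletion", 0.05),
)

# pyrimidine-reference substitution classes with transition-heavy weights
_SPECTRUM_PAIRS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
_SPECTRUM_WEIGHTS = np.array([0.10, 0.10, 0.40, 0.08, 0.22, 0.10])


@dataclass
class SimConfig:
    """Study-shaped generating conditions.

    Defaults emulate a four-region primary tumor whose mutated-gene counts
    decompose like the exome profiles this package analyzes: ~20 trunk genes
    against ~18 branch genes per internal lineage and ~25 private genes per
    region, giving ~155 mutated genes of which ~13% are trunk and the
    heterogeneity rate is ~0.87. Noise defaults to zero (clean observation);
    dropout/false-positive rates model imperfect variant calling.
    """

    n_regions: int = 4
    has_metastasis: bool = False
    n_trunk: int = 20
    mean_branch: float = 18.0
    mean_private: float = 25.0
    dropout_rate: float = 0.0
    false_positive_rate: float = 0.0
    n_cnv_shared: int = 6
    n_cnv_private: int = 8
    genome_model: tuple[tuple[str, int], ...] = (
        ("chr1", 50_000_000),
        ("chr2", 40_000_000),
        ("chr3", 30_000_000),
    )
    patient_id: str = "Sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need >= 2 tumor regions")
        for p in (self.dropout_rate, self.false_positive_rate):
            if not 0.0 <= p < 1.0:
                raise ValueError("noise probabilities must be in [0, 1)")
        if min(self.n_trunk, self.n_cnv_shared, self.n_cnv_private) < 0:
            raise ValueError("counts must be non-negative")
        if self.mean_branch < 0 or self.mean_private < 0:
            raise ValueError("Poisson means must be non-negative")


@dataclass
class SimTruth:
    """Generating truth: clone tree, mutation placement, expected categories."""

    clone_tree: PhyloTree  # leaves named by region ids, includes normal leaf
    clone_parent: dict[str, str | None]
    mutation_assignment: dict[str, str]  # gene -> clone whose arrival edge holds it
    region_to_clone: dict[str, str]
    expected_presence: GeneRegionMatrix  # noise-free gene x region truth
    expected_category: dict[str, str]  # gene -> trunk | branch | private

    @property
    def expected_heterogeneity_rate(self) -> float:
        total = len(self.expected_category)
        trunk = sum(1 for c in self.expected_category.values() if c == "trunk")
        return (total - trunk) / total if total else 0.0


@dataclass
class SimResult:
    config: SimConfig
    regions: list[RegionLabel]  # tumor regions (+ metastasis), normal last
    normal: RegionLabel
    variants: dict[str, list[VariantCall]]  # region_id -> calls (normal included)
    cnv_segments: list[CNVSegment]
    observed: GeneRegionMatrix  # after noise
    truth: SimTruth


def _grow_clone_tree(n_leaves: int, rng: np.random.Generator) -> dict[str, str | None]:
    """Random recursive bifurcation; returns child -> parent over clone names."""
    parent: dict[str, str | None] = {"C0": None}
    leaves = ["C0"]
    counter = 1
    while len(leaves) < n_leaves:
        split = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            name = f"C{counter}"
            counter += 1
            parent[name] = split
            leaves.append(name)
    return parent


def _root_path(clone: str, parent: dict[str, str | None]) -> list[str]:
    path = []
    node: str | None = clone
    while node is not None:
        path.append(node)
        node = parent[node]
    return path[::-1]


def _clone_tree_as_phylo(
    parent: dict[str, str | None],
    region_of_clone: dict[str, str],
    genes_of_clone: dict[str, list[str]],
    normal_id: str,
) -> PhyloTree:
    """Project the clone tree to a region tree with the normal at the root.

    Branch lengths are the mutation counts acquired on each edge. Clones that
    carry a sampled region but also have children get a zero-length pendant
    leaf, so every region is a leaf taxon.
    """
    adjacency: dict[int, dict[int, float]] = {}
    leaf_names: dict[int, str] = {}
    ids: dict[str, int] = {}

    def nid(key: str) -> int:
        if key not in ids:
            ids[key] = len(ids)
            adjacency[ids[key]] = {}
        return ids[key]

    def add_edge(a: int, b: int, length: float) -> None:
        adjacency[a][b] = length
        adjacency[b][a] = length

    children: dict[str, list[str]] = {}
    for child, par in parent.items():
        if par is not None:
            children.setdefault(par, []).append(child)

    for clone in parent:
        node = nid(clone)
        if clone in region_of_clone:
            if children.get(clone):
                pendant = nid(f"{clone}@leaf")
                add_edge(node, pendant, 0.0)
                leaf_names[pendant] = region_of_clone[clone]
            else:
                leaf_names[node] = region_of_clone[clone]
    for child, par in parent.items():
        if par is not None:
            add_edge(nid(par), nid(child), float(len(genes_of_clone.get(child, []))))
    # normal hangs off the root with the trunk mutations on the root edge
    normal_node = nid("@normal")
    leaf_names[normal_node] = normal_id
    add_edge(nid("C0"), normal_node, float(len(genes_of_clone.get("C0", []))))
    # suppress degree-2 internal nodes (unsampled pass-through clones)
    for node in [n for n in list(adjacency) if n not in leaf_names]:
        if len(adjacency[node]) == 2:
            (a, la), (b, lb) = adjacency[node].items()
            del adjacency[node]
            del adjacency[a][node]
            del adjacency[b][node]
            adjacency[a][b] = la + lb
            adjacency[b][a] = la + lb
    return PhyloTree(adjacency=adjacency, leaf_names=leaf_names)


def _place_segments(
    n: int,
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    taken: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, int, int]]:
    """Place n random non-overlapping segments, respecting already-taken space."""
    out = []
    for _ in range(n):
        for _attempt in range(200):
            chrom, length = genome[int(rng.integers(len(genome)))]
            seg_len = int(rng.integers(200_000, 2_000_000))
            start = int(rng.integers(0, max(1, length - seg_len)))
            end = start + seg_len
            if all(end <= s or start >= e for s, e in taken.get(chrom, [])):
                taken.setdefault(chrom, []).append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise RuntimeError("could not place a non-overlapping CNV segment")
    return out


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate one synthetic patient; optionally write all files to out_dir.

    Fully reproducible from ``config.seed``: the same config yields
    byte-identical output files.
    """
    rng = np.random.default_rng(config.seed)
    parent = _grow_clone_tree(config.n_regions, rng)
    primary_leaves = sorted(
        (c for c in parent if not any(p == c for p in parent.values())),
        key=lambda c: int(c[1:]),
    )

    if config.has_metastasis:
        # the metastasis descends from a non-root primary subclone; its host
        # keeps its own sampled region even if it thereby gains a child
        non_root = sorted(c for c in parent if parent[c] is not None)
        host = non_root[int(rng.integers(len(non_root)))]
        parent["M0"] = host

    all_clones = list(parent)
    is_leaf = {c: not any(p == c for p in parent.values()) for c in all_clones}
    region_of_clone: dict[str, str] = {}
    labels: list[RegionLabel] = []
    for t_index, clone in enumerate(primary_leaves, start=1):
        rid = f"T{t_index}"
        region_of_clone[clone] = rid
        labels.append(RegionLabel(config.patient_id, rid))
    if config.has_metastasis:
        region_of_clone["M0"] = "M"
        labels.append(RegionLabel(config.patient_id, "M", is_metastasis=True))
    normal = RegionLabel(config.patient_id, "N", is_normal=True)

    # mutation placement on edges (keyed by the child clone of each edge)
    genes_of_clone: dict[str, list[str]] = {}
    counter = 0

    def new_genes(k: int) -> list[str]:
        nonlocal counter
        out = [f"G{counter + i:06d}" for i in range(k)]
        counter += k
        return out

    for clone in sorted(all_clones, key=lambda c: (c[0] != "C", int(c[1:]))):
        if parent[clone] is None:
            genes_of_clone[clone] = new_genes(config.n_trunk)
        elif is_leaf[clone]:
            genes_of_clone[clone] = new_genes(int(rng.poisson(config.mean_private)))
        else:
            genes_of_clone[clone] = new_genes(int(rng.poisson(config.mean_branch)))

    mutation_assignment = {
        gene: clone for clone, genes in genes_of_clone.items() for gene in genes
    }
    all_genes = sorted(mutation_assignment)

    # noise-free presence: region sees every mutation on its clone's root path
    tumor_ids = [lab.region_id for lab in labels]
    presence = np.zeros((len(all_genes), len(tumor_ids)), dtype=bool)
    gene_idx = {g: i for i, g in enumerate(all_genes)}
    for clone, rid in region_of_clone.items():
        j = tumor_ids.index(rid)
        for path_clone in _root_path(clone, parent):
            for gene in genes_of_clone[path_clone]:
                presence[gene_idx[gene], j] = True
    clean = GeneRegionMatrix(genes=list(all_genes), regions=list(labels), present=presence)
    clean_report = classify_trunk_branch_private(clean)

    # observation noise on the presence table
    observed = presence.copy()
    if config.dropout_rate > 0:
        observed &= rng.random(observed.shape) >= config.dropout_rate
    if config.false_positive_rate > 0:
        observed |= (~presence) & (rng.random(presence.shape) < config.false_positive_rate)
    keep = observed.any(axis=1)
    observed_matrix = GeneRegionMatrix(
        genes=[g for g, k in zip(all_genes, keep) if k],
        regions=list(labels),
        present=observed[keep],
    )

    # per-gene variant descriptions (one representative variant per gene)
    tokens = [t for t, _ in _CONSEQUENCES]
    weights = np.array([w for _, w in _CONSEQUENCES])
    gene_variant: dict[str, tuple[str, int, str, str, str]] = {}
    bases = "ACGT"
    complement = str.maketrans("ACGT", "TGCA")
    for gene in all_genes:
        chrom, length = config.genome_model[int(rng.integers(len(config.genome_model)))]
        pos = int(rng.integers(1, length))
        token = tokens[int(rng.choice(len(tokens), p=weights))]
        if "insertion" in token:
            ref = bases[int(rng.integers(4))]
            alt = ref + bases[int(rng.integers(4))]
        elif "deletion" in token:
            alt = bases[int(rng.integers(4))]
            ref = alt + bases[int(rng.integers(4))]
        else:
            # transition-heavy substitution spectrum, C>T/G>A predominant,
            # as exome studies of this tumor type report
            ref, alt = _SPECTRUM_PAIRS[
                int(rng.choice(len(_SPECTRUM_PAIRS), p=_SPECTRUM_WEIGHTS))
            ]
            if rng.random() < 0.5:  # either strand representation
                ref, alt = ref.translate(complement), alt.translate(complement)
        gene_variant[gene] = (chrom, pos, ref, alt, token)

    variants: dict[str, list[VariantCall]] = {lab.region_id: [] for lab in labels}
    variants[normal.region_id] = []  # matched normal: no somatic calls
    label_of = {lab.region_id: lab for lab in labels}
    for gi, gene in enumerate(observed_matrix.genes):
        chrom, pos, ref, alt, token = gene_variant[gene]
        for j, rid in enumerate(tumor_ids):
            if observed_matrix.present[gi, j]:
                variants[rid].append(
                    VariantCall(
                        region=label_of[rid],
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        gene=gene,
                        raw_consequence=token,
                    )
                )

    # CNV segments: shared ones on the root (all regions), private per region
    taken_shared: dict[str, list[tuple[int, int]]] = {}
    shared = _place_segments(config.n_cnv_shared, rng, config.genome_model, taken_shared)
    segments: list[CNVSegment] = []
    shared_states = [
        CNVState.AMPLIFICATION if rng.random() < 0.7 else CNVState.DELETION
        for _ in shared
    ]
    for (chrom, start, end), state in zip(shared, shared_states):
        for lab in labels:
            segments.append(CNVSegment(lab, chrom, start, end, state))
    for lab in labels:
        taken = {c: list(v) for c, v in taken_shared.items()}
        private = _place_segments(config.n_cnv_private, rng, config.genome_model, taken)
        for chrom, start, end in private:
            state = CNVState.AMPLIFICATION if rng.random() < 0.5 else CNVState.DELETION
            segments.append(CNVSegment(lab, chrom, start, end, state))

    clone_tree = _clone_tree_as_phylo(
        parent, region_of_clone, genes_of_clone, normal.region_id
    )
    truth = SimTruth(
        clone_tree=clone_tree,
        clone_parent=parent,
        mutation_assignment=mutation_assignment,
        region_to_clone={rid: clone for clone, rid in region_of_clone.items()},
        expected_presence=clean,
        expected_category=dict(clean_report.per_gene_category),
    )
    result = SimResult(
        config=config,
        regions=labels,
        normal=normal,
        variants=variants,
        cnv_segments=segments,
        observed=observed_matrix,
        truth=truth,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"seed={result.config.seed}"]
    for rid, calls in sorted(result.variants.items()):
        write_region_variants(calls, out_dir / f"variants_{rid}.tsv", header_lines=header)
    write_cnv_segments(result.cnv_segments, out_dir / "cnv_segments.bed", header_lines=header)
    truth = result.truth
    payload = {
        "clone_tree_newick": truth.clone_tree.to_newick(with_supports=False),
        "clone_parent": truth.clone_parent,
        "mutation_assignment": truth.mutation_assignment,
        "region_to_clone": truth.region_to_clone,
        "expected_category": truth.expected_category,
        "expected_heterogeneity_rate": truth.expected_heterogeneity_rate,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class RecoveryMetrics:
    category_accuracy: float
    rate_error: float
    rf_distance: int


def evaluate_recovery(
    truth: SimTruth,
    report: HeterogeneityReport,
    tree: PhyloTree | None = None,
) -> RecoveryMetrics:
    """Score a pipeline run against the generating truth.

    ``category_accuracy`` is the fraction of true genes whose inferred
    trunk/branch/private category matches (genes lost to dropout count as
    misses); ``rate_error`` the absolute heterogeneity-rate difference;
    ``rf_distance`` the Robinson–Foulds distance between the inferred region
    tree and the region-projected generating tree (requires ``tree``).
    """
    true_cats = truth.expected_category
    if not set(report.per_gene_category) & set(true_cats):
        raise ValueError("inferred and true gene sets are disjoint")
    hits = sum(
        1
        for gene, cat in true_cats.items()
        if report.per_gene_category.get(gene) == cat
    )
    accuracy = hits / len(true_cats) if true_cats else 1.0
    rate_error = abs(report.heterogeneity_rate - truth.expected_heterogeneity_rate)
    rf = robinson_foulds(tree, truth.clone_tree) if tree is not None else -1
    return RecoveryMetrics(
        category_accuracy=accuracy, rate_error=rate_error, rf_distance=rf
    )
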