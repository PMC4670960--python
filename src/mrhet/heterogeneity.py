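"""Gene-level mutation heterogeneity statistics across tumor regions.

The substrate of every statistic here is the boolean gene-by-region presence
matrix: a gene is "present" in a region when at least one qualifying variant
of that gene was called there. Genes present in every region are *trunk*
(clonal, acquired before the regions diverged), genes present in exactly one
region are *private*, and everything in between is *branch*. The
heterogeneity rate is the fraction of mutated genes not shared by all tumor
regions — the working measure of intratumor heterogeneity. The matched
normal is never part of these statistics; it only roots the phylogeny.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import RegionLabel, VariantCall, VariantKind

logger = logging.getLogger(__name__)

__all__ = [
    "MutationClass",
    "NON_SILENT",
    "SPM_CLASSES",
    "INDEL_CLASSES",
    "classify_consequence",
    "GeneRegionMatrix",
    "build_gene_matrix",
    "HeterogeneityReport",
    "classify_trunk_branch_private",
    "heterogeneity_rate",
    "round_half_away",
    "VennCounts",
    "overlap_counts",
    "SpectrumCounts",
    "SPECTRUM_CLASSES",
    "mutation_spectrum",
    "annotate_gene_sets",
    "matrix_from_category_counts",
]


class MutationClass(str, Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    STOPGAIN = "stopgain"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    UTR5 = "utr5"
    UTR3 = "utr3"
    OTHER = "other"


#: Classes expected to alter protein function.
NON_SILENT = frozenset(
    {
        MutationClass.NONSYNONYMOUS,
        MutationClass.STOPGAIN,
        MutationClass.SPLICE_SITE,
        MutationClass.FRAMESHIFT_INDEL,
        MutationClass.NONFRAMESHIFT_INDEL,
    }
)

SPM_CLASSES = frozenset(
    {
        MutationClass.NONSYNONYMOUS,
        MutationClass.SYNONYMOUS,
        MutationClass.STOPGAIN,
        MutationClass.SPLICE_SITE,
    }
)

INDEL_CLASSES = frozenset(
    {MutationClass.FRAMESHIFT_INDEL, MutationClass.NONFRAMESHIFT_INDEL}
)

# ANNOVAR-style consequence tokens, normalized to lowercase with single spaces.
_CONSEQUENCE_TABLE: dict[str, MutationClass] = {
    "nonsynonymous snv": MutationClass.NONSYNONYMOUS,
    "nonsynonymous": MutationClass.NONSYNONYMOUS,
    "missense": MutationClass.NONSYNONYMOUS,
    "missense snv": MutationClass.NONSYNONYMOUS,
    "synonymous snv": MutationClass.SYNONYMOUS,
    "synonymous": MutationClass.SYNONYMOUS,
    "silent": MutationClass.SYNONYMOUS,
    "stopgain": MutationClass.STOPGAIN,
    "stopgain snv": MutationClass.STOPGAIN,
    "stop gain": MutationClass.STOPGAIN,
    "nonsense": MutationClass.STOPGAIN,
    "splicing": MutationClass.SPLICE_SITE,
    "splice site": MutationClass.SPLICE_SITE,
    "frameshift insertion": MutationClass.FRAMESHIFT_INDEL,
    "frameshift deletion": MutationClass.FRAMESHIFT_INDEL,
    "frameshift substitution": MutationClass.FRAMESHIFT_INDEL,
    "frameshift": MutationClass.FRAMESHIFT_INDEL,
    "nonframeshift insertion": MutationClass.NONFRAMESHIFT_INDEL,
    "nonframeshift deletion": MutationClass.NONFRAMESHIFT_INDEL,
    "nonframeshift substitution": MutationClass.NONFRAMESHIFT_INDEL,
    "nonframeshift": MutationClass.NONFRAMESHIFT_INDEL,
    "utr5": MutationClass.UTR5,
    "5utr": MutationClass.UTR5,
    "utr3": MutationClass.UTR3,
    "3utr": MutationClass.UTR3,
}


def classify_consequence(v: VariantCall) -> MutationClass:
    """Map an annotator consequence token to a :class:`MutationClass`.

    Total function: unknown tokens fall back to ``other`` with a log message
    rather than aborting, since token dialects drift across annotators.
    """
    token = " ".join(v.raw_consequence.strip().lower().replace("_", " ").split())
    cls = _CONSEQUENCE_TABLE.get(token)
    if cls is None:
        logger.info("unknown consequence token %r -> other", v.raw_consequence)
        return MutationClass.OTHER
    return cls


@dataclass
class GeneRegionMatrix:
    """Boolean presence of mutated genes (rows) across tumor regions (columns)."""

    genes: list[str]
    regions: list[RegionLabel]
    present: np.ndarray  # bool, shape (n_genes, n_regions)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.genes), len(self.regions)):
            raise ValueError(
                f"matrix shape {self.present.shape} does not match "
                f"{len(self.genes)} genes x {len(self.regions)} regions"
            )
        if any(r.is_normal for r in self.regions):
            raise ValueError("normal sample must not appear in a GeneRegionMatrix")
        if len(self.genes) and not self.present.any(axis=1).all():
            bad = [g for g, row in zip(self.genes, self.present) if not row.any()]
            raise ValueError(f"gene(s) with no presence in any region: {bad[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def reordered(self, gene_order: Sequence[str]) -> "GeneRegionMatrix":
        idx = [self.genes.index(g) for g in gene_order]
        return GeneRegionMatrix(list(gene_order), list(self.regions), self.present[idx])


def build_gene_matrix(
    variants: Iterable[VariantCall],
    regions: Sequence[RegionLabel],
    classes: frozenset[MutationClass] | set[MutationClass] = NON_SILENT,
) -> GeneRegionMatrix:
    """Collapse variant calls to a gene-by-region presence matrix.

    A gene is present in a region iff at least one of its variants there has a
    consequence class in ``classes`` (gene-level union over variant types).
    Genes with no qualifying variant anywhere are omitted.
    """
    if not regions:
        raise ValueError("need at least one region")
    if not classes:
        raise ValueError("need at least one mutation class")
    tumor_regions = [r for r in regions if not r.is_normal]
    region_index = {r: i for i, r in enumerate(tumor_regions)}
    present: dict[str, np.ndarray] = {}
    for v in variants:
        if v.region.is_normal:
            continue
        if v.region not in region_index:
            raise ValueError(f"variant region {v.region} not in region list")
        if classify_consequence(v) not in classes:
            continue
        row = present.setdefault(v.gene, np.zeros(len(tumor_regions), dtype=bool))
        row[region_index[v.region]] = True
    genes = sorted(present)
    mat = (
        np.array([present[g] for g in genes], dtype=bool)
        if genes
        else np.zeros((0, len(tumor_regions)), dtype=bool)
    )
    return GeneRegionMatrix(genes=genes, regions=list(tumor_regions), present=mat)


@dataclass
class HeterogeneityReport:
    total_genes: int
    trunk: int
    branch: int
    private: int
    heterogeneity_rate: float
    per_gene_category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trunk + self.branch + self.private != self.total_genes:
            raise ValueError("trunk + branch + private must equal total_genes")


def classify_trunk_branch_private(m: GeneRegionMatrix) -> HeterogeneityReport:
    """Classify each mutated gene as trunk / branch / private.

    Trunk: present in all regions. Private: present in exactly one. Branch:
    everything else. With a single region every gene is trivially trunk and
    the rate is 0. An empty matrix yields the degenerate all-zero report.
    """
    if m.n_regions < 1:
        raise ValueError("matrix must have at least one region")
    if m.n_genes == 0:
        logger.info("empty gene matrix: degenerate heterogeneity report")
        return HeterogeneityReport(0, 0, 0, 0, 0.0, {})
    counts = m.present.sum(axis=1)
    trunk_mask = counts == m.n_regions
    private_mask = counts == 1
    if m.n_regions == 1:
        private_mask = np.zeros_like(private_mask)  # single region: all trunk
    branch_mask = ~(trunk_mask | private_mask)
    per_gene = {}
    for gene, is_trunk, is_private in zip(m.genes, trunk_mask, private_mask):
        per_gene[gene] = "trunk" if is_trunk else ("private" if is_private else "branch")
    trunk = int(trunk_mask.sum())
    total = m.n_genes
    return HeterogeneityReport(
        total_genes=total,
        trunk=trunk,
        branch=int(branch_mask.sum()),
        private=int(private_mask.sum()),
        heterogeneity_rate=(total - trunk) / total,
        per_gene_category=per_gene,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (11.5 -> 12, -11.5 -> -12)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def heterogeneity_rate(m: GeneRegionMatrix) -> tuple[float, int]:
    """Return (heterogeneity rate, percent of genes common to all regions).

    Rate = (total - trunk) / total; the complementary shared fraction is
    reported as an integer percent, rounded half away from zero.
    """
    if m.n_genes == 0:
        raise ValueError("heterogeneity rate undefined for an empty matrix")
    report = classify_trunk_branch_private(m)
    percent_common = round_half_away(100.0 * report.trunk / report.total_genes)
    return report.heterogeneity_rate, percent_common


@dataclass
class VennCounts:
    """Exact Venn-cell gene counts over region subsets."""

    cells: dict[frozenset[str], int]  # nonempty region-id subset -> exclusive count
    per_region: dict[str, int]  # genes present in each region (inclusive)
    pairwise: dict[frozenset[str], int]  # |intersection| for each region pair


def overlap_counts(m: GeneRegionMatrix, max_regions: int = 6) -> VennCounts:
    """Tally genes into exact Venn cells by their region-presence pattern."""
    if m.n_regions > max_regions:
        raise ValueError(
            f"{m.n_regions} regions exceed the {max_regions}-set Venn limit; "
            "use pairwise intersections instead"
        )
    ids = m.region_ids()
    cells: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for k in range(1, m.n_regions + 1)
        for sub in itertools.combinations(ids, k)
    }
    for row in m.present:
        subset = frozenset(rid for rid, bit in zip(ids, row) if bit)
        cells[subset] += 1
    per_region = {
        rid: int(m.present[:, j].sum()) for j, rid in enumerate(ids)
    }
    pairwise = {
        frozenset((ids[a], ids[b])): int((m.present[:, a] & m.present[:, b]).sum())
        for a, b in itertools.combinations(range(m.n_regions), 2)
    }
    return VennCounts(cells=cells, per_region=per_region, pairwise=pairwise)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The six strand-collapsed substitution classes, keyed by pyrimidine reference.
SPECTRUM_CLASSES = (
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)

_CLASS_BY_PYRIMIDINE = {label.split("/")[0]: label for label in SPECTRUM_CLASSES}


@dataclass
class SpectrumCounts:
    counts: dict[str, int]
    n_snvs: int
    n_skipped: int  # non-SNV records, not classified


def mutation_spectrum(variants: Iterable[VariantCall]) -> SpectrumCounts:
    """Tally SNVs into the six strand-collapsed substitution classes.

    Purine-reference substitutions are complemented to their pyrimidine
    representation (G>A counts as C>T/G>A), so the spectrum is invariant
    under complementing every input. Indels are skipped and counted.
    """
    counts = {label: 0 for label in SPECTRUM_CLASSES}
    n_snvs = 0
    n_skipped = 0
    for v in variants:
        if v.variant_kind is not VariantKind.SNV:
            n_skipped += 1
            continue
        ref, alt = v.ref.upper(), v.alt.upper()
        if ref not in "ACGT" or alt not in "ACGT":
            raise ValueError(f"invalid nucleotide in SNV {ref}>{alt} at {v.chrom}:{v.pos}")
        if ref in "AG":  # collapse to pyrimidine reference
            ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        counts[_CLASS_BY_PYRIMIDINE[f"{ref}>{alt}"]] += 1
        n_snvs += 1
    return SpectrumCounts(counts=counts, n_snvs=n_snvs, n_skipped=n_skipped)


def annotate_gene_sets(
    genes: Iterable[str],
    reference: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Flag genes by case-insensitive membership in named reference sets
    (cancer-gene catalogs, druggable-gene tables, ...)."""
    lookup: dict[str, set[str]] = {}
    for set_name, members in reference.items():
        members = set(members)
        if not members:
            logger.warning("reference set %r is empty", set_name)
        for g in members:
            lookup.setdefault(g.upper(), set()).add(set_name)
    return {g: set(lookup.get(g.upper(), set())) for g in genes}


def matrix_from_category_counts(
    total: int,
    trunk: int,
    private: int,
    regions: Sequence[RegionLabel],
    gene_prefix: str = "G",
) -> GeneRegionMatrix:
    """Deterministically construct a presence matrix with the given
    trunk / branch / private decomposition.

    Useful for building worked examples from published marginal counts:
    trunk genes get the all-regions pattern, private genes cycle through
    single regions, and branch genes cycle through all remaining
    some-but-not-all patterns. Requires >= 2 regions when branch + private
    genes exist.
    """
    k = len(regions)
    branch = total - trunk - private
    if branch < 0 or trunk < 0 or private < 0:
        raise ValueError("category counts must be non-negative and sum to total")
    if k < 2 and (branch or private):
        raise ValueError("branch/private patterns need >= 2 regions")
    if k < 3 and branch:
        raise ValueError("branch patterns need >= 3 regions")
    patterns: list[np.ndarray] = []
    patterns += [np.ones(k, dtype=bool)] * trunk
    branch_patterns = [
        np.array([i in sub for i in range(k)], dtype=bool)
        for size in range(2, k)
        for sub in itertools.combinations(range(k), size)
    ]
    for i in range(branch):
        patterns.append(branch_patterns[i % len(branch_patterns)])
    for i in range(private):
        row = np.zeros(k, dtype=bool)
        row[i % k] = True
        patterns.append(row)
    genes = [f"{gene_prefix}{i:05d}" for i in range(total)]
    mat = np.array(patterns, dtype=bool) if total else np.zeros((0, k), dtype=bool)
    return GeneRegionMatrix(genes=genes, regions=list(regions), present=mat)
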