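"""Cross-region copy-number commonality via breakpoint-union interval algebra.

Copy-number calls from different regions rarely share exact boundaries, so
"amplified in all regions" is only well-posed on a common coordinate grid.
The grid used here is the set of *atomic loci*: the breakpoints of every
region's segments are unioned per chromosome, and each resulting interval is
a locus within which every region's state (none / amplified / deleted) is
constant. Commonality statistics then count atoms, mirroring how published
analyses count "genomic loci".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .heterogeneity import round_half_away
from .io import CNVSegment, CNVState, RegionLabel


class AtomState(IntEnum):
    NONE = 0
    AMPLIFICATION = 1
    DELETION = 2

__all__ = [
    "AtomState",
    "AtomicLocusMatrix",
    "harmonize_segments",
    "CommonAlterationStats",
    "common_alteration_stats",
    "atoms_from_common_counts",
]


@dataclass
class AtomicLocusMatrix:
    """Disjoint atomic intervals (rows) with one copy-number state per region."""

    atoms: list[tuple[str, int, int]]  # (chrom, start, end), sorted, disjoint
    regions: list[RegionLabel]
    state_by_region: np.ndarray  # AtomState int8, shape (n_atoms, n_regions)

    def __post_init__(self) -> None:
        self.state_by_region = np.asarray(self.state_by_region, dtype=np.int8)
        if self.state_by_region.shape != (len(self.atoms), len(self.regions)):
            raise ValueError("state matrix shape mismatch")
        prev: dict[str, int] = {}
        for chrom, start, end in self.atoms:
            if start >= end:
                raise ValueError(f"empty atom {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise ValueError(f"overlapping/unsorted atoms on {chrom}")
            prev[chrom] = end
        if len(self.atoms) and not (self.state_by_region != AtomState.NONE).any(axis=1).all():
            raise ValueError("every atom must be altered in at least one region")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]


_STATE_CODE = {
    CNVState.AMPLIFICATION: AtomState.AMPLIFICATION,
    CNVState.DELETION: AtomState.DELETION,
}


def harmonize_segments(
    segments: Sequence[CNVSegment],
    regions: Sequence[RegionLabel],
) -> AtomicLocusMatrix:
    """Tile all regions' segments into atomic loci on the breakpoint union.

    Within one region a locus must carry a single state: an amplification
    overlapping a deletion in the same region is a caller inconsistency and
    raises with the offending locus named. Atoms covered by no region are
    dropped (the atoms exactly tile the union of input segments).
    """
    regions = [r for r in regions if not r.is_normal]
    if not regions:
        raise ValueError("need at least one tumor region")
    region_index = {r: j for j, r in enumerate(regions)}
    by_chrom: dict[str, list[CNVSegment]] = {}
    for seg in segments:
        if seg.region not in region_index:
            raise ValueError(f"segment region {seg.region} not in region list")
        by_chrom.setdefault(seg.chrom, []).append(seg)

    atoms: list[tuple[str, int, int]] = []
    rows: list[np.ndarray] = []
    for chrom in sorted(by_chrom):
        segs = by_chrom[chrom]
        breaks = sorted({s.start for s in segs} | {s.end for s in segs})
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            states = np.full(len(regions), AtomState.NONE, dtype=np.int8)
            for s in segs:
                if s.start <= lo and hi <= s.end:
                    j = region_index[s.region]
                    code = _STATE_CODE[s.state]
                    if states[j] != AtomState.NONE and states[j] != code:
                        raise ValueError(
                            f"region {s.region.region_id} has overlapping amplification "
                            f"and deletion at {chrom}:{lo}-{hi}"
                        )
                    states[j] = code
            if (states != AtomState.NONE).any():
                atoms.append((chrom, lo, hi))
                rows.append(states)
    mat = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(regions)), dtype=np.int8)
    )
    return AtomicLocusMatrix(atoms=atoms, regions=list(regions), state_by_region=mat)


@dataclass
class CommonAlterationStats:
    total_altered_loci: int
    common_amp: int
    common_del: int
    percent_common_amp: int
    percent_common_del: int
    heterogeneity_rate: float
    mode: str


def common_alteration_stats(
    m: AtomicLocusMatrix, mode: str = "strict"
) -> CommonAlterationStats:
    """Count atomic loci altered in common across regions.

    ``strict``: an atom is commonly amplified iff amplified in *every*
    region. ``lenient``: iff amplified in every region that has at least one
    amplification anywhere (regions with zero events of that state are not
    allowed to veto). The CNV heterogeneity rate is the fraction of altered
    loci that are not common to all regions in either state.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    if m.n_atoms == 0:
        raise ValueError("no altered loci")
    stats = {}
    for state in (AtomState.AMPLIFICATION, AtomState.DELETION):
        is_state = m.state_by_region == state
        if mode == "strict":
            active = np.ones(len(m.regions), dtype=bool)
        else:
            active = is_state.any(axis=0)
        if active.any():
            common = int(is_state[:, active].all(axis=1).sum())
        else:
            common = 0
        stats[state] = common
    total = m.n_atoms
    common_amp = stats[AtomState.AMPLIFICATION]
    common_del = stats[AtomState.DELETION]
    return CommonAlterationStats(
        total_altered_loci=total,
        common_amp=common_amp,
        common_del=common_del,
        percent_common_amp=round_half_away(100.0 * common_amp / total),
        percent_common_del=round_half_away(100.0 * common_del / total),
        heterogeneity_rate=1.0 - (common_amp + common_del) / total,
        mode=mode,
    )


def atoms_from_common_counts(
    total: int,
    common_amp: int,
    common_del: int,
    regions: Sequence[RegionLabel],
    chrom: str = "chr1",
    atom_length: int = 1000,
) -> AtomicLocusMatrix:
    """Deterministically build an atom matrix with given commonality counts.

    The first ``common_amp`` atoms are amplified everywhere, the next
    ``common_del`` deleted everywhere, and the remaining atoms are altered in
    all-but-one region (cycling the missing region) so they are never common.
    Useful for reconstructing worked examples from published contingency
    counts.
    """
    k = len(regions)
    rest = total - common_amp - common_del
    if rest < 0:
        raise ValueError("common counts exceed total")
    if k < 2 and rest:
        raise ValueError("non-common atoms need >= 2 regions")
    rows = []
    for i in range(total):
        if i < common_amp:
            row = np.full(k, AtomState.AMPLIFICATION, dtype=np.int8)
        elif i < common_amp + common_del:
            row = np.full(k, AtomState.DELETION, dtype=np.int8)
        else:
            state = AtomState.AMPLIFICATION if i % 2 else AtomState.DELETION
            row = np.full(k, state, dtype=np.int8)
            row[i % k] = AtomState.NONE
        rows.append(row)
    atoms = [(chrom, i * atom_length, (i + 1) * atom_length) for i in range(total)]
    mat = np.array(rows, dtype=np.int8) if rows else np.zeros((0, k), dtype=np.int8)
    return AtomicLocusMatrix(atoms=atoms, regions=list(regions), state_by_region=mat)
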