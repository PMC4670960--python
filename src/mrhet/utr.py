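"""miRNA seed-site prediction in UTRs and mutation-impact calls.

Canonical seed matching: a site in a UTR (given as DNA, 5'->3') is an exact
Watson–Crick match to the miRNA seed (positions 2–8 of the mature sequence).
Three site classes are recognized, in decreasing strength:

* ``8mer``     — reverse complement of miRNA nt 2–8, followed by an 'A'
* ``7mer_m8``  — reverse complement of miRNA nt 2–8
* ``7mer_A1``  — reverse complement of miRNA nt 2–7, followed by an 'A'

Each UTR position is reported once at its strongest class: the 7mer patterns
contained inside an 8mer match are the same physical site and are not
re-reported. A mutation's impact is called by rescanning the mutated UTR and
diffing the site lists with indel-aware position anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import RecordError, VariantCall, VariantKind

__all__ = [
    "MiRNA",
    "SeedSite",
    "scan_seed_sites",
    "read_site_list",
    "apply_mutation",
    "MutationImpact",
    "assess_mutation_impact",
]

_RC = str.maketrans("ACGT", "TGCA")
_RNA_ALPHABET = frozenset("ACGU")
_DNA_ALPHABET = frozenset("ACGT")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3' RNA; the seed is positions 2-8 (1-based)."""

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper().replace("T", "U")
        object.__setattr__(self, "mature_seq", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")
        if not set(seq) <= _RNA_ALPHABET:
            raise ValueError(f"{self.name}: invalid nucleotide in {seq}")

    @property
    def seed_2_8(self) -> str:
        """Seed nt 2-8 as DNA."""
        return self.mature_seq[1:8].replace("U", "T")

    @property
    def seed_2_7(self) -> str:
        return self.mature_seq[1:7].replace("U", "T")


@dataclass(frozen=True)
class SeedSite:
    """One predicted binding site on a UTR (0-based start)."""

    utr_id: str
    start: int
    site_type: str  # 8mer | 7mer_m8 | 7mer_A1
    mirna: str

    def __post_init__(self) -> None:
        if self.site_type not in ("8mer", "7mer_m8", "7mer_A1"):
            raise ValueError(f"unknown site type {self.site_type!r}")

    @property
    def length(self) -> int:
        return 8 if self.site_type == "8mer" else 7


def _check_dna(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _DNA_ALPHABET:
        bad = sorted(set(seq) - _DNA_ALPHABET)
        raise ValueError(f"invalid nucleotide(s) {bad} in UTR sequence")
    return seq


def scan_seed_sites(
    utr: str,
    mirnas: Iterable[MiRNA],
    utr_id: str = "utr",
) -> list[SeedSite]:
    """All canonical seed sites for each miRNA, overlapping sites included.

    For one miRNA, a UTR position yields at most one site, classified at its
    strongest type (8mer > 7mer_m8 > 7mer_A1).
    """
    utr = _check_dna(utr)
    sites: list[SeedSite] = []
    for mir in mirnas:
        match7 = _revcomp_dna(mir.seed_2_8)  # 7 nt, pairs miRNA nt 2-8
        match6 = _revcomp_dna(mir.seed_2_7)  # 6 nt, pairs miRNA nt 2-7
        eightmer_starts = set()
        start = utr.find(match7)
        while start != -1:
            if utr[start + 7 : start + 8] == "A":
                sites.append(SeedSite(utr_id, start, "8mer", mir.name))
                eightmer_starts.add(start)
            else:
                sites.append(SeedSite(utr_id, start, "7mer_m8", mir.name))
            start = utr.find(match7, start + 1)
        start = utr.find(match6)
        while start != -1:
            inside_8mer = (start - 1) in eightmer_starts
            is_m8_start = utr[start : start + 7] == match7
            if utr[start + 6 : start + 7] == "A" and not inside_8mer and not is_m8_start:
                sites.append(SeedSite(utr_id, start, "7mer_A1", mir.name))
            start = utr.find(match6, start + 1)
    sites.sort(key=lambda s: (s.start, s.mirna, s.site_type))
    return sites


def read_site_list(path) -> list[SeedSite]:
    """Load a precomputed binding-site table instead of scanning.

    Tab-delimited with header ``utr_id  start  site_type  mirna`` (0-based
    starts), e.g. the output of an external target predictor. Sites are
    validated against the known type vocabulary.
    """
    sites: list[SeedSite] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = {"utr_id", "start", "site_type", "mirna"} - set(header)
                if missing:
                    raise ValueError(f"site list missing column(s) {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                start = int(row["start"])
            except ValueError:
                raise RecordError(f"line {lineno}: unparsable start {row['start']!r}") from None
            sites.append(
                SeedSite(
                    utr_id=row["utr_id"],
                    start=start,
                    site_type=row["site_type"],
                    mirna=row["mirna"],
                )
            )
    return sites


def apply_mutation(utr: str, v: VariantCall) -> str:
    """Apply one UTR-relative variant (1-based ``pos``) to the sequence.

    Alleles follow the anchored-VCF convention: an insertion's alt begins
    with the ref base; a deletion's ref begins with the alt base. The ref
    allele must match the UTR at the stated position.
    """
    utr = _check_dna(utr)
    i = v.pos - 1
    ref = v.ref.upper()
    alt = v.alt.upper()
    if i + len(ref) > len(utr):
        raise RecordError(f"variant at position {v.pos} extends past UTR end")
    if utr[i : i + len(ref)] != ref:
        raise RecordError(
            f"ref allele {ref!r} does not match UTR at position {v.pos} "
            f"(found {utr[i:i + len(ref)]!r})"
        )
    return utr[:i] + alt + utr[i + len(ref) :]


@dataclass
class MutationImpact:
    disrupted: list[SeedSite]
    created: list[SeedSite]

    @property
    def unchanged(self) -> bool:
        return not self.disrupted and not self.created


def assess_mutation_impact(
    utr: str,
    v: VariantCall,
    mirnas: Sequence[MiRNA],
    utr_id: str = "utr",
) -> MutationImpact:
    """Call whether a UTR mutation disrupts or creates miRNA seed sites.

    The UTR is rescanned after applying the mutation; sites are matched
    between the two scans by (miRNA, site type, anchored start), where starts
    downstream of an indel are shifted back by the net length change so an
    unaffected site does not spuriously appear moved.
    """
    utr = _check_dna(utr)
    before = scan_seed_sites(utr, mirnas, utr_id=utr_id)
    mutated = apply_mutation(utr, v)
    after = scan_seed_sites(mutated, mirnas, utr_id=utr_id)
    delta = len(mutated) - len(utr)
    edit_point = v.pos - 1

    def anchor(start: int, shift: int) -> int:
        return start - shift if start > edit_point else start

    before_keys = {(s.mirna, s.site_type, s.start): s for s in before}
    after_keys = {(s.mirna, s.site_type, anchor(s.start, delta)): s for s in after}
    disrupted = [s for k, s in before_keys.items() if k not in after_keys]
    created = [s for k, s in after_keys.items() if k not in before_keys]
    disrupted.sort(key=lambda s: (s.start, s.mirna))
    created.sort(key=lambda s: (s.start, s.mirna))
    return MutationImpact(disrupted=disrupted, created=created)
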