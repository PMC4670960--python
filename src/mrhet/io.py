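"""Readers and writers for the external formats the pipeline touches.

Variants are 1-based (VCF convention); copy-number segments are 0-based
half-open (BED convention). Conversions happen only inside readers, so all
downstream modules see a single coordinate convention per object type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "RegionLabel",
    "VariantKind",
    "VariantCall",
    "CNVState",
    "CNVSegment",
    "FormatError",
    "RecordError",
    "read_region_variants",
    "write_region_variants",
    "read_cnv_segments",
    "write_cnv_segments",
    "read_fasta",
    "FastaRecords",
    "write_newick",
    "read_newick",
]


class FormatError(ValueError):
    """A file-level problem: missing column, unknown token, empty input."""


class RecordError(ValueError):
    """A single-record problem, reported with its line number where known."""


@dataclass(frozen=True, order=True)
class RegionLabel:
    """One sampled region of one patient (tumor region, metastasis or normal)."""

    patient_id: str
    region_id: str
    is_normal: bool = False
    is_metastasis: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.patient_id}:{self.region_id}" if self.patient_id else self.region_id


class VariantKind(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


_NUCS = frozenset("ACGTN-")


def infer_variant_kind(ref: str, alt: str) -> VariantKind:
    """Classify an allele pair by length: equal single bases are SNVs,
    longer alt is an insertion, longer ref a deletion."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SNV
    if len(alt) > len(ref):
        return VariantKind.INSERTION
    return VariantKind.DELETION


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation observed in one region, with gene annotation."""

    region: RegionLabel
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    raw_consequence: str
    variant_kind: VariantKind = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise RecordError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not set(self.ref.upper()) <= _NUCS or not set(self.alt.upper()) <= _NUCS:
            raise RecordError(
                f"non-nucleotide allele {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.variant_kind is None:
            object.__setattr__(self, "variant_kind", infer_variant_kind(self.ref, self.alt))
        elif self.variant_kind is VariantKind.SNV and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise RecordError("SNV requires single-base ref and alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class CNVState(str, Enum):
    AMPLIFICATION = "amplification"
    DELETION = "deletion"


_STATE_TOKENS = {
    "amp": CNVState.AMPLIFICATION,
    "amplification": CNVState.AMPLIFICATION,
    "gain": CNVState.AMPLIFICATION,
    "del": CNVState.DELETION,
    "deletion": CNVState.DELETION,
    "loss": CNVState.DELETION,
}


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number altered interval in one region, 0-based half-open."""

    region: RegionLabel
    chrom: str
    start: int
    end: int
    state: CNVState

    def __post_init__(self) -> None:
        if self.start < 0:
            raise RecordError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise RecordError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


_VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "consequence")


def _parse_pos(token: str, lineno: int) -> int:
    try:
        pos = int(token)
    except ValueError:
        raise RecordError(f"line {lineno}: unparsable position {token!r}") from None
    if pos < 1:
        raise RecordError(f"line {lineno}: position must be >= 1, got {pos}")
    return pos


def _dedup(calls: list[VariantCall]) -> list[VariantCall]:
    seen: set[tuple] = set()
    out: list[VariantCall] = []
    for call in calls:
        if call.key in seen:
            continue
        seen.add(call.key)
        out.append(call)
    dropped = len(calls) - len(out)
    if dropped:
        logger.info("collapsed %d duplicate variant record(s)", dropped)
    return out


def read_region_variants(
    path: str | Path,
    region: RegionLabel,
    dialect: str = "tsv",
) -> list[VariantCall]:
    """Read one region's somatic variant calls.

    ``dialect='tsv'`` expects a tab-delimited file with a header naming at
    least ``chrom pos ref alt gene consequence`` (order free, ``#`` prefix on
    the header tolerated).  ``dialect='vcf_min'`` accepts a minimal VCF whose
    INFO field carries ``GENE=`` and ``CSQ=`` keys; everything else in the
    record is ignored.  Duplicate (chrom, pos, ref, alt) records are collapsed
    and multi-allelic ALT fields are split into one call per allele.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variants_tsv(path, region)
    if dialect == "vcf_min":
        return _read_variants_vcf_min(path, region)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: Path, region: RegionLabel) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                candidate = [f.lstrip("#").strip().lower() for f in fields]
                missing = [c for c in _VARIANT_COLUMNS if c not in candidate]
                if not missing:
                    header = candidate
                    continue
                if line.startswith("#"):  # metadata line before the header
                    continue
                raise FormatError(
                    f"{path}: missing required column(s): {', '.join(missing)}"
                )
            if line.startswith("#"):
                continue
            row = dict(zip(header, fields))
            pos = _parse_pos(row["pos"], lineno)
            for alt in row["alt"].split(","):
                calls.append(
                    VariantCall(
                        region=region,
                        chrom=row["chrom"],
                        pos=pos,
                        ref=row["ref"].upper(),
                        alt=alt.strip().upper(),
                        gene=row["gene"],
                        raw_consequence=row["consequence"],
                    )
                )
    return _dedup(calls)


def _read_variants_vcf_min(path: Path, region: RegionLabel) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise RecordError(f"line {lineno}: expected >= 8 VCF columns")
            chrom, pos_s, _id, ref, alts, _qual, _filt, info = fields[:8]
            pos = _parse_pos(pos_s, lineno)
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            gene = kv.get("GENE")
            csq = kv.get("CSQ")
            if gene is None or csq is None:
                raise FormatError(
                    f"{path} line {lineno}: INFO must carry GENE= and CSQ= keys"
                )
            for alt in alts.split(","):
                calls.append(
                    VariantCall(
                        region=region,
                        chrom=chrom,
                        pos=pos,
                        ref=ref.upper(),
                        alt=alt.upper(),
                        gene=gene,
                        raw_consequence=csq.replace("_", " "),
                    )
                )
    return _dedup(calls)


def write_region_variants(
    calls: Iterable[VariantCall], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write the tab-delimited variant dialect ``read_region_variants`` reads."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in calls:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{v.raw_consequence}\n"
            )


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (touching intervals merge)."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(ivals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def read_cnv_segments(
    path: str | Path,
    region_map: Mapping[str, RegionLabel] | None = None,
) -> list[CNVSegment]:
    """Read BED-like copy-number calls: ``chrom  start  end  state  region``.

    Within one region and state, overlapping or touching intervals are merged
    on load, so downstream interval algebra can assume disjoint same-state
    segments. ``region_map`` attaches full :class:`RegionLabel` metadata; bare
    region ids are wrapped otherwise.
    """
    path = Path(path)
    raw: dict[tuple[RegionLabel, CNVState, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path} line {lineno}: expected 5 columns")
            chrom, start_s, end_s, state_s, region_id = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RecordError(f"line {lineno}: unparsable coordinates") from None
            if start >= end:
                raise RecordError(
                    f"line {lineno}: start >= end ({start} >= {end}) on {chrom}"
                )
            state = _STATE_TOKENS.get(state_s.strip().lower())
            if state is None:
                raise FormatError(f"{path} line {lineno}: unknown state {state_s!r}")
            if region_map is not None:
                if region_id not in region_map:
                    raise FormatError(f"{path} line {lineno}: unknown region {region_id!r}")
                region = region_map[region_id]
            else:
                region = RegionLabel(patient_id="", region_id=region_id)
            raw.setdefault((region, state, chrom), []).append((start, end))

    segments: list[CNVSegment] = []
    for (region, state, chrom), ivals in raw.items():
        for start, end in _merge_intervals(ivals):
            segments.append(
                CNVSegment(region=region, chrom=chrom, start=start, end=end, state=state)
            )
    segments.sort(key=lambda s: (s.region.region_id, s.chrom, s.start, s.state.value))
    return segments


def write_cnv_segments(
    segments: Iterable[CNVSegment], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for s in sorted(segments, key=lambda s: (s.chrom, s.start, s.region.region_id)):
            token = "amp" if s.state is CNVState.AMPLIFICATION else "del"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{token}\t{s.region.region_id}\n")


@dataclass
class FastaRecords:
    """Uppercased sequences keyed by id; ids whose input used RNA letters
    (U) are recorded in ``rna_ids`` after U->T normalization."""

    sequences: dict[str, str]
    rna_ids: set[str]

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta(path: str | Path) -> FastaRecords:
    sequences: dict[str, str] = {}
    rna_ids: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if "U" in seq:
            rna_ids.add(record.id)
            seq = seq.replace("U", "T")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return FastaRecords(sequences=sequences, rna_ids=rna_ids)


def write_newick(tree, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Serialize a tree to Newick with branch lengths; bootstrap supports are
    written as integer internal-node labels. Round-trips through
    :func:`read_newick`."""
    newick = tree.to_newick()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"[{line}]\n")
        fh.write(newick + "\n")


def read_newick(path: str | Path):
    from .phylogeny import PhyloTree

    text = Path(path).read_text()
    return PhyloTree.from_newick(text)
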