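"""Patient-level pipeline orchestration and TSV/summary report writers.

Ties the per-module analyses together behind one config: per-region variant
tables in, heterogeneity + CNV + phylogeny + UTR reports out, each output
file stamped with the tool version, a config hash and the seed so a bundle
is reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cnv import common_alteration_stats, harmonize_segments
from .heterogeneity import (
    INDEL_CLASSES,
    NON_SILENT,
    SPM_CLASSES,
    MutationClass,
    annotate_gene_sets,
    build_gene_matrix,
    classify_trunk_branch_private,
    heterogeneity_rate,
    mutation_spectrum,
    overlap_counts,
)
from .io import (
    FormatError,
    RegionLabel,
    read_cnv_segments,
    read_fasta,
    read_region_variants,
    write_newick,
)
from .phylogeny import (
    bootstrap_support,
    build_character_matrix,
    pairwise_distance,
    root_at_normal,
)
from .utr import MiRNA, assess_mutation_impact

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "InputError", "ComputationError", "run_pipeline", "CLASS_SETS"]

CLASS_SETS: dict[str, frozenset[MutationClass]] = {
    "non_silent": NON_SILENT,
    "spm": SPM_CLASSES,
    "indel": INDEL_CLASSES,
    "all": frozenset(MutationClass),
}


class InputError(Exception):
    """Bad or missing input (CLI exit code 2)."""


class ComputationError(Exception):
    """A pipeline stage failed on valid-looking input (CLI exit code 3)."""


@dataclass
class RunConfig:
    """One patient-level run.

    ``regions`` maps region id -> variant table path; flags mark the normal
    and metastasis regions. Paths are validated up front.
    """

    patient_id: str
    regions: dict[str, str]  # region_id -> variants path
    normal_region: str | None = None
    metastasis_regions: tuple[str, ...] = ()
    cnv_segments: str | None = None
    utrs: str | None = None
    mirnas: str | None = None
    utr_variants: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> path
    classes: str = "non_silent"
    cnv_mode: str = "strict"
    phylo_model: str = "cfn"
    bootstrap_n: int = 1000
    seed: int = 0
    out_dir: str = "mrhet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise InputError(f"bad config {path}: {exc}") from None

    def validate(self) -> None:
        if self.classes not in CLASS_SETS:
            raise InputError(f"unknown class set {self.classes!r}")
        paths = list(self.regions.values()) + [
            p
            for p in (self.cnv_segments, self.utrs, self.mirnas, self.utr_variants)
            if p
        ]
        paths += list(self.gene_sets.values())
        for p in paths:
            if not Path(p).exists():
                raise InputError(f"input file not found: {p}")
        if self.normal_region is not None and self.normal_region not in self.regions:
            raise InputError(f"normal region {self.normal_region!r} has no variant file")

    def labels(self) -> dict[str, RegionLabel]:
        out = {}
        for rid in self.regions:
            out[rid] = RegionLabel(
                patient_id=self.patient_id,
                region_id=rid,
                is_normal=rid == self.normal_region,
                is_metastasis=rid in self.metastasis_regions,
            )
        return out

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (the output directory does
        not change the analysis, so reruns into different directories agree)."""
        payload = {
            k: sorted(v.items()) if isinstance(v, dict) else v
            for k, v in self.__dict__.items()
            if k != "out_dir"
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> list[str]:
    return [
        f"mrhet {__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every configured stage; returns the headline numbers and the paths
    of the written reports. Stage failures raise with the stage named."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    labels = config.labels()
    bundle: dict[str, Any] = {"out_dir": str(out_dir)}

    # --- variants + heterogeneity -----------------------------------------
    stage = "heterogeneity"
    try:
        all_variants = []
        for rid, path in sorted(config.regions.items()):
            all_variants.extend(read_region_variants(path, labels[rid]))
        tumor_labels = [labels[r] for r in sorted(config.regions) if r != config.normal_region]
        matrix = build_gene_matrix(all_variants, tumor_labels, CLASS_SETS[config.classes])
        report = classify_trunk_branch_private(matrix)
        rate, percent_common = (
            heterogeneity_rate(matrix) if matrix.n_genes else (0.0, 0)
        )
        spectrum = mutation_spectrum(
            [v for v in all_variants if not v.region.is_normal]
        )
        flags = (
            annotate_gene_sets(
                matrix.genes,
                {
                    name: _read_gene_set(path)
                    for name, path in config.gene_sets.items()
                },
            )
            if config.gene_sets
            else {g: set() for g in matrix.genes}
        )
        gene_rows = []
        for i, gene in enumerate(matrix.genes):
            row: dict[str, Any] = {"gene": gene}
            for j, lab in enumerate(matrix.regions):
                row[lab.region_id] = int(matrix.present[i, j])
            row["category"] = report.per_gene_category[gene]
            row["flags"] = ",".join(sorted(flags[gene]))
            gene_rows.append(row)
        _write_tsv(pd.DataFrame(gene_rows), out_dir / "gene_report.tsv", header)
        venn = overlap_counts(matrix) if 0 < matrix.n_regions <= 6 else None
        bundle.update(
            total_genes=report.total_genes,
            trunk=report.trunk,
            branch=report.branch,
            private=report.private,
            heterogeneity_rate=rate,
            percent_common=percent_common,
            spectrum=dict(spectrum.counts),
            venn=venn,
        )
    except (OSError, FormatError, ValueError) as exc:
        raise ComputationError(f"stage {stage}: {exc}") from exc

    # --- CNV ---------------------------------------------------------------
    if config.cnv_segments:
        stage = "cnv"
        try:
            segments = read_cnv_segments(config.cnv_segments, region_map=labels)
            atom_matrix = harmonize_segments(segments, tumor_labels)
            cnv_stats = common_alteration_stats(atom_matrix, mode=config.cnv_mode)
            atom_rows = []
            for (chrom, start, end), states in zip(
                atom_matrix.atoms, atom_matrix.state_by_region
            ):
                row = {"chrom": chrom, "start": start, "end": end}
                for lab, state in zip(atom_matrix.regions, states):
                    row[lab.region_id] = ["none", "amp", "del"][state]
                atom_rows.append(row)
            _write_tsv(pd.DataFrame(atom_rows), out_dir / "cnv_atoms.tsv", header)
            bundle.update(
                cnv_total_loci=cnv_stats.total_altered_loci,
                cnv_common_amp=cnv_stats.common_amp,
                cnv_common_del=cnv_stats.common_del,
                cnv_percent_common_amp=cnv_stats.percent_common_amp,
                cnv_percent_common_del=cnv_stats.percent_common_del,
                cnv_heterogeneity_rate=cnv_stats.heterogeneity_rate,
            )
        except (OSError, FormatError, ValueError) as exc:
            raise ComputationError(f"stage {stage}: {exc}") from exc

    # --- phylogeny ---------------------------------------------------------
    if matrix.n_genes and matrix.n_regions >= 2:
        stage = "phylogeny"
        try:
            cm = build_character_matrix(matrix, include_normal=True)
            dm = pairwise_distance(cm, model=config.phylo_model)
            dist_df = pd.DataFrame(dm.d, index=dm.taxa, columns=dm.taxa)
            with open(out_dir / "distances.tsv", "w") as fh:
                for line in header:
                    fh.write(f"#{line}\n")
                dist_df.to_csv(fh, sep="\t")
            tree = bootstrap_support(
                cm, n=config.bootstrap_n, seed=config.seed, model=config.phylo_model
            )
            if cm.normal is not None:
                tree = root_at_normal(tree, cm.normal)
            write_newick(tree, out_dir / "tree.nwk", header_lines=header)
            bundle["tree_newick"] = tree.to_newick()
            bundle["min_support"] = (
                min(tree.supports.values()) if tree.supports else None
            )
        except ValueError as exc:
            raise ComputationError(f"stage {stage}: {exc}") from exc

    # --- UTR sites ---------------------------------------------------------
    if config.utrs and config.mirnas and config.utr_variants:
        stage = "utr"
        try:
            bundle["utr_verdicts"] = _run_utr_stage(config, labels, out_dir, header)
        except (OSError, FormatError, ValueError) as exc:
            raise ComputationError(f"stage {stage}: {exc}") from exc

    _write_summary(bundle, out_dir / "summary.txt", header)
    bundle["summary_path"] = str(out_dir / "summary.txt")
    return bundle


def _read_gene_set(path: str | Path) -> set[str]:
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def _read_mirnas(path: str | Path) -> list[MiRNA]:
    records = read_fasta(path)
    return [MiRNA(name=k, mature_seq=v.replace("T", "U")) for k, v in records.sequences.items()]


def _run_utr_stage(
    config: RunConfig,
    labels: Mapping[str, RegionLabel],
    out_dir: Path,
    header: list[str],
) -> list[dict[str, Any]]:
    utrs = read_fasta(config.utrs)
    mirnas = _read_mirnas(config.mirnas)
    table = pd.read_csv(config.utr_variants, sep="\t", comment="#")
    required = {"utr_id", "region", "pos", "ref", "alt", "gene"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"utr variants: missing column(s) {sorted(missing)}")
    from .io import VariantCall

    rows = []
    for rec in table.itertuples(index=False):
        if rec.utr_id not in utrs.sequences:
            raise InputError(f"UTR id {rec.utr_id!r} not in {config.utrs}")
        region = labels.get(
            str(rec.region), RegionLabel(config.patient_id, str(rec.region))
        )
        call = VariantCall(
            region=region,
            chrom=str(rec.utr_id),
            pos=int(rec.pos),
            ref=str(rec.ref),
            alt=str(rec.alt),
            gene=str(rec.gene),
            raw_consequence="UTR3",
        )
        impact = assess_mutation_impact(
            utrs.sequences[rec.utr_id], call, mirnas, utr_id=str(rec.utr_id)
        )
        verdict = (
            "unchanged"
            if impact.unchanged
            else ("disrupted" if impact.disrupted else "created")
        )
        rows.append(
            {
                "utr_id": rec.utr_id,
                "gene": rec.gene,
                "region": rec.region,
                "pos": rec.pos,
                "verdict": verdict,
                "disrupted": ";".join(
                    f"{s.mirna}:{s.site_type}@{s.start}" for s in impact.disrupted
                ),
                "created": ";".join(
                    f"{s.mirna}:{s.site_type}@{s.start}" for s in impact.created
                ),
            }
        )
    _write_tsv(pd.DataFrame(rows), out_dir / "utr_verdicts.tsv", header)
    return rows


def _write_summary(bundle: Mapping[str, Any], path: Path, header: list[str]) -> None:
    lines = [f"#{line}" for line in header]
    lines.append(f"total_genes\t{bundle.get('total_genes')}")
    lines.append(f"trunk\t{bundle.get('trunk')}")
    lines.append(f"branch\t{bundle.get('branch')}")
    lines.append(f"private\t{bundle.get('private')}")
    rate = bundle.get("heterogeneity_rate")
    lines.append(f"heterogeneity_rate\t{rate:.4f}" if rate is not None else "heterogeneity_rate\tNA")
    lines.append(f"percent_common\t{bundle.get('percent_common')}")
    for key in (
        "cnv_total_loci",
        "cnv_common_amp",
        "cnv_common_del",
        "cnv_percent_common_amp",
        "cnv_percent_common_del",
    ):
        if key in bundle:
            lines.append(f"{key}\t{bundle[key]}")
    if "cnv_heterogeneity_rate" in bundle:
        lines.append(f"cnv_heterogeneity_rate\t{bundle['cnv_heterogeneity_rate']:.4f}")
    if "spectrum" in bundle:
        for cls, count in bundle["spectrum"].items():
            lines.append(f"spectrum[{cls}]\t{count}")
    if "tree_newick" in bundle:
        lines.append(f"tree\t{bundle['tree_newick']}")
    path.write_text("\n".join(lines) + "\n")
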