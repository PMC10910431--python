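"""End-to-end orchestration: QC -> isoform classification -> phasing -> report.

Every number in a :class:`SampleReport` is recomputable from the persisted
per-read calls table, and the config echo is complete enough to reproduce
the run.  Percentages render half-up to one decimal for display; JSON keeps
full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .gene_model import (
    IsoformSpec,
    PhasingSNV,
    TranscriptModel,
    derive_isoform,
    frame_consequence,
    model_from_config,
)
from .synthetic_data import SequencedRead, read_fastq
from .read_qc import QCParams, QCStats, filter_reads
from .classify import (
    ClassifyParams,
    ReadCall,
    classify_reads,
    junction_counts,
    write_calls,
)
from .phasing import (
    AlleleSkipEstimate,
    PhasedCounts,
    allele_balance,
    allele_skip_direct,
    allele_skip_indirect,
    genotype_calls,
    overall_fractions,
)

__all__ = ["SampleReport", "run_pipeline", "render_report", "format_pct"]

logger = logging.getLogger("ampliskip")


def format_pct(fraction: float, decimals: int = 1) -> str:
    """Format a fraction as a percentage, rounding half-up (0.8843 -> '88.4%')."""
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


@dataclass
class SampleReport:
    """Aggregated per-sample results plus the configuration that produced them."""

    sample_id: str
    qc: QCStats
    overall_fractions: dict[str, float]
    overall_fractions_known: dict[str, float]
    phased_counts: PhasedCounts
    allele_balance: Optional[dict[str, float]]
    estimates: list[AlleleSkipEstimate]
    frame_consequences: dict[str, dict]
    config_echo: dict

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "version": __version__,
            "qc": self.qc.to_dict(),
            "overall_fractions": self.overall_fractions,
            "overall_fractions_known_denominator": self.overall_fractions_known,
            "phased_counts": {
                row: dict(cols) for row, cols in self.phased_counts.counts.items()
            },
            "allele_balance": self.allele_balance,
            "allele_estimates": [e.to_dict() for e in self.estimates],
            "frame_consequences": self.frame_consequences,
            "config": self.config_echo,
        }


def _frame_block(model: TranscriptModel, isoforms: Mapping[str, frozenset]) -> dict:
    block = {}
    for label, skipped in isoforms.items():
        if not skipped:
            continue
        fc = frame_consequence(model, skipped)
        block[label] = {
            "deleted_nt": fc.deleted_nt,
            "in_frame": fc.in_frame,
            "frame_offset": fc.frame_offset,
            "deleted_residues": fc.deleted_residues,
        }
    return block


def run_pipeline(
    fastq: str | Path | Sequence[SequencedRead],
    config: str | Path | Mapping,
    fasta: Optional[str | Path] = None,
    qc_params: QCParams = QCParams(),
    classify_params: ClassifyParams = ClassifyParams(),
    denominator: str = "all",
    snv_min_base_quality: Optional[int] = None,
    sample_id: str = "sample",
    out_dir: Optional[str | Path] = None,
) -> SampleReport:
    """Run QC, classification and phasing on one sample and build its report.

    ``fastq`` may be a path or an in-memory read list.  The model config
    (JSON) defines exon lengths, the CDS anchor, isoform definitions and
    phasing SNVs; sequences come from ``fasta`` or, failing that, from a
    ``sequence_seed`` entry in the config (synthetic amplicon).  When
    ``out_dir`` is given, all intermediate tables are persisted there.
    """
    if isinstance(config, Mapping):
        config_dict = dict(config)
    else:
        with open(config) as fh:
            config_dict = json.load(fh)
    model, snvs, isoform_defs = model_from_config(config_dict, fasta=fasta)
    if not model.has_sequences:
        if "sequence_seed" not in config_dict:
            raise ValueError(
                "no sequences: provide a FASTA or a 'sequence_seed' config entry"
            )
        from .synthetic_data import generate_synthetic_gene

        model = generate_synthetic_gene(
            exon_lengths=[e.length for e in model.exons],
            gc_fraction=float(config_dict.get("gc_fraction", 0.5)),
            seed=int(config_dict["sequence_seed"]),
            cds_start_offset=model.cds_start_offset,
            cds_length=sum(e.cds_width for e in model.exons),
            name=model.name,
        )
    isoforms = [
        derive_isoform(model, skipped) for label, skipped in isoform_defs.items()
    ]

    reads = read_fastq(fastq) if isinstance(fastq, (str, Path)) else list(fastq)
    logger.info("%s: %d input reads", sample_id, len(reads))
    kept, qc_stats = filter_reads(reads, qc_params)
    logger.info(
        "%s: QC kept %d (%d length-fail, %d quality-fail)",
        sample_id, qc_stats.n_kept, qc_stats.n_fail_length, qc_stats.n_fail_quality,
    )
    calls = classify_reads(kept, isoforms, classify_params)

    from .phasing import DEFAULT_SNV_MIN_BASE_QUALITY

    if snv_min_base_quality is None:
        snv_min_base_quality = DEFAULT_SNV_MIN_BASE_QUALITY
    snv = snvs[0] if snvs else None
    if snv is not None:
        calls = genotype_calls(
            kept, calls, snv, isoforms, model, min_base_quality=snv_min_base_quality
        )
    counts = PhasedCounts.from_calls(calls)
    logger.info("%s: classified %d reads", sample_id, counts.n_total)

    fractions_all = overall_fractions(counts, "all")
    fractions_known = overall_fractions(counts, "known")

    balance: Optional[dict[str, float]] = None
    estimates: list[AlleleSkipEstimate] = []
    if snv is not None:
        skipping_here = [
            label
            for label, skipped in isoform_defs.items()
            if snv.exon_index in skipped
        ]
        try:
            balance = allele_balance(counts)
        except ValueError:
            balance = None
        if skipping_here:
            # SNV sits inside skipped exon(s): only the indirect estimate applies
            estimates.append(allele_skip_indirect(counts))
        else:
            estimates.append(allele_skip_direct(counts, "splice_allele"))
            estimates.append(allele_skip_direct(counts, "trans_allele"))

    report = SampleReport(
        sample_id=sample_id,
        qc=qc_stats,
        overall_fractions=(
            fractions_all if denominator == "all" else fractions_known
        ),
        overall_fractions_known=fractions_known,
        phased_counts=counts,
        allele_balance=balance,
        estimates=estimates,
        frame_consequences=_frame_block(model, isoform_defs),
        config_echo={
            "model": {
                "name": model.name,
                "exon_lengths": [e.length for e in model.exons],
                "cds_start_offset": model.cds_start_offset,
            },
            "isoforms": {k: sorted(v) for k, v in isoform_defs.items()},
            "snvs": [
                {
                    "cds_position": s.cds_position,
                    "ref": s.ref_base,
                    "alt": s.alt_base,
                    "splice_allele_base": s.splice_allele_base,
                }
                for s in snvs
            ],
            "qc_params": {
                "min_len": qc_params.min_len,
                "max_len": qc_params.max_len,
                "min_mean_q": qc_params.min_mean_q,
            },
            "classify_params": {
                "max_norm_dist": classify_params.max_norm_dist,
                "min_margin": classify_params.min_margin,
            },
            "denominator": denominator,
            "snv_min_base_quality": snv_min_base_quality,
            "sequence_seed": config_dict.get("sequence_seed"),
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_calls(calls, out / f"{sample_id}.calls.tsv")
        counts.write_tsv(out / f"{sample_id}.phased_counts.tsv")
        junctions = junction_counts(calls, model, isoforms)
        junctions.write_tsv(out / f"{sample_id}.junctions.tsv")
        junctions.write_bed12(model, out / f"{sample_id}.junctions.bed")
        (out / f"{sample_id}.qc.json").write_text(
            json.dumps(qc_stats.to_dict(), indent=2)
        )
        (out / f"{sample_id}.report.json").write_text(render_report(report, "json"))
        (out / f"{sample_id}.report.md").write_text(render_report(report, "markdown"))
    return report


def render_report(report: SampleReport, fmt: str = "json") -> str:
    """Render a report as machine JSON or human Markdown."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")

    d = report.to_dict()
    lines = [f"# Sample {report.sample_id}", ""]
    qc = report.qc
    lines += [
        "## Read QC",
        "",
        f"- input reads: {qc.n_input}",
        f"- kept: {qc.n_kept} "
        f"(length failures: {qc.n_fail_length}, quality failures: {qc.n_fail_quality})",
        "",
        "## Isoform fractions",
        "",
    ]
    for col in ("full", "skip56", "skip6", "other"):
        frac = report.overall_fractions[f"fraction_{col}"]
        frac_str = format_pct(frac) if frac == frac else "n/a"  # NaN guard
        lines.append(f"- {col}: {frac_str}")
    lines.append("")
    if report.allele_balance is not None:
        lines += ["## Allele balance (phased reads)", ""]
        for allele, share in report.allele_balance.items():
            lines.append(f"- {allele}: {format_pct(share)}")
        lines.append("")
    if report.estimates:
        lines += ["## Per-allele skipping estimates", ""]
        for est in report.estimates:
            if not est.defined:
                lines.append(
                    f"- {est.allele} ({est.method}): undefined "
                    f"({'; '.join(est.warnings)})"
                )
                continue
            lines.append(
                f"- {est.allele} ({est.method}, n={est.n_support}): "
                f"skip56 {format_pct(est.fraction_skip56)}, "
                f"skip6 {format_pct(est.fraction_skip6)}, "
                f"total skipped {format_pct(est.fraction_skipped)}"
            )
            for a in est.assumptions:
                lines.append(f"  - assumption: {a}")
            for w in est.warnings:
                lines.append(f"  - warning: {w}")
        lines.append("")
    else:
        lines += ["## Per-allele skipping estimates", "", "- no phasing SNV configured", ""]
    lines += ["## Frame consequences", ""]
    for label, fc in report.frame_consequences.items():
        if fc["in_frame"]:
            lines.append(
                f"- {label}: in-frame deletion of {fc['deleted_nt']} nt "
                f"({fc['deleted_residues']} residues)"
            )
        else:
            lines.append(
                f"- {label}: out-of-frame deletion of {fc['deleted_nt']} nt "
                f"(frame offset {fc['frame_offset']})"
            )
    lines.append("")
    return "\n".join(lines)
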