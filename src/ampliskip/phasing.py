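"""SNV-based allele phasing of isoform-called reads.

Each accepted read is genotyped at the phasing SNV by aligning it to its
called isoform and reading the base aligned to the SNV's isoform-relative
offset.  Reads whose called isoform skips the SNV's exon are *unphasable by
structure*; reads showing a gap or a third base at the site are unphased by
noise and excluded from allele-level estimates.

Per-allele skipping fractions come in two flavours:

* **direct** — the SNV sits in an exon retained by every isoform, so every
  read can in principle be phased and the fraction is a simple row ratio.
* **indirect** — the SNV sits inside the skipped exon(s); skipped reads lack
  the site, so the splice-allele skipping fraction is estimated as
  S / (S + I), where S counts skipped reads (all attributed to the splice
  allele) and I counts phased splice-allele full-length reads.  The
  attribution assumption — the trans allele shows no skipping — is recorded
  on the estimate, not silently applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd

from .gene_model import IsoformSpec, PhasingSNV, TranscriptModel, ISOFORM_LABELS
from .classify import ReadCall
from .synthetic_data import SequencedRead

__all__ = [
    "ALLELE_ROWS",
    "PhasedCounts",
    "AlleleSkipEstimate",
    "genotype_read",
    "genotype_calls",
    "quantify",
    "overall_fractions",
    "allele_skip_direct",
    "allele_skip_indirect",
    "allele_balance",
    "write_snv_vcf",
    "mask_structural_phase",
]

ALLELE_ROWS = ("splice_allele", "trans_allele", "unphased")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _read_base_at(
    query: str, target: str, target_pos: int
) -> tuple[Optional[str], Optional[int]]:
    """Base of ``query`` aligned to position ``target_pos`` of ``target``.

    Global edlib alignment; returns (base, query index), or (None, None)
    when a deletion (gap in the read) spans the site.
    """
    result = edlib.align(query, target, mode="NW", task="path")
    qpos = tpos = 0
    for n_str, op in _CIGAR_RE.findall(result["cigar"]):
        n = int(n_str)
        if op in "=XM":
            if tpos <= target_pos < tpos + n:
                i = qpos + (target_pos - tpos)
                return query[i], i
            qpos += n
            tpos += n
        elif op == "I":  # extra read bases, gap in target
            qpos += n
        else:  # 'D': gap in read
            if tpos <= target_pos < tpos + n:
                return None, None
            tpos += n
    raise RuntimeError(f"target position {target_pos} outside alignment")


#: Default minimum Phred quality of the base read at the SNV site.  An
#: erroneous base at the site silently assigns the read to the wrong allele;
#: because miscalled bases carry low quality, gating them out removes the
#: resulting bias in allele-level estimates.  Set to 0 to disable.
DEFAULT_SNV_MIN_BASE_QUALITY = 10


def genotype_read(
    read: SequencedRead,
    call: ReadCall,
    snv: PhasingSNV,
    isoforms: Sequence[IsoformSpec],
    model: TranscriptModel,
    min_base_quality: int = DEFAULT_SNV_MIN_BASE_QUALITY,
) -> ReadCall:
    """Genotype one isoform-called read at the phasing SNV.

    Returns a new call with ``allele`` set to splice_allele / trans_allele /
    unphased and ``phase_reason`` recording why (direct, structural, gap,
    third_base, low_quality, or no_call for ``other`` reads).  Bases below
    ``min_base_quality`` at the site are treated as unphased noise.
    """
    if call.isoform == "other":
        return call.with_allele("unphased", "no_call")
    iso = next((i for i in isoforms if i.label == call.isoform), None)
    if iso is None:
        raise ValueError(f"call references unknown isoform {call.isoform!r}")
    offset = snv.isoform_offset(iso, model)
    if offset is None:
        return call.with_allele("unphased", "structural")
    if iso.sequence is None or not 0 <= offset < len(iso.sequence):
        raise RuntimeError(
            f"SNV offset {offset} inconsistent with isoform {iso.label!r}"
        )
    base, qindex = _read_base_at(read.sequence, iso.sequence, offset)
    if base is None:
        return call.with_allele("unphased", "gap")
    if min_base_quality > 0 and read.qualities[qindex] < min_base_quality:
        return call.with_allele("unphased", "low_quality")
    allele = snv.allele_of(base)
    if allele is None:
        return call.with_allele("unphased", "third_base")
    return call.with_allele(allele, "direct")


def genotype_calls(
    reads: Sequence[SequencedRead],
    calls: Sequence[ReadCall],
    snv: PhasingSNV,
    isoforms: Sequence[IsoformSpec],
    model: TranscriptModel,
    min_base_quality: int = DEFAULT_SNV_MIN_BASE_QUALITY,
) -> list[ReadCall]:
    """Genotype a matched list of reads and calls (paired by position)."""
    if len(reads) != len(calls):
        raise ValueError("reads and calls must pair one-to-one")
    return [
        genotype_read(read, call, snv, isoforms, model, min_base_quality)
        for read, call in zip(reads, calls)
    ]


@dataclass(frozen=True)
class PhasedCounts:
    """(allele x isoform) contingency table all reported fractions derive from."""

    counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        full = {
            row: {col: int(self.counts.get(row, {}).get(col, 0)) for col in ISOFORM_LABELS}
            for row in ALLELE_ROWS
        }
        for row in ALLELE_ROWS:
            for col, v in full[row].items():
                if v < 0:
                    raise ValueError(f"negative count at [{row}][{col}]")
        object.__setattr__(self, "counts", full)

    def __getitem__(self, row: str) -> Mapping[str, int]:
        return self.counts[row]

    @property
    def n_total(self) -> int:
        return sum(sum(r.values()) for r in self.counts.values())

    def row_total(self, row: str) -> int:
        return sum(self.counts[row].values())

    def column_total(self, col: str) -> int:
        return sum(self.counts[row][col] for row in ALLELE_ROWS)

    @classmethod
    def from_calls(cls, calls: Iterable[ReadCall]) -> "PhasedCounts":
        counts: dict[str, dict[str, int]] = {
            row: {col: 0 for col in ISOFORM_LABELS} for row in ALLELE_ROWS
        }
        for call in calls:
            if call.allele not in ALLELE_ROWS:
                raise ValueError(f"unknown allele label {call.allele!r}")
            col = call.isoform if call.isoform in ISOFORM_LABELS else "other"
            counts[call.allele][col] += 1
        return cls(counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.counts[r][c] for c in ISOFORM_LABELS] for r in ALLELE_ROWS],
            index=list(ALLELE_ROWS),
            columns=list(ISOFORM_LABELS),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="allele")


@dataclass(frozen=True)
class AlleleSkipEstimate:
    """Per-allele skipping fractions with provenance.

    ``defined`` is False when no supporting reads exist — an undefined
    estimate is flagged, never reported as zero.
    """

    allele: str
    fraction_skip56: Optional[float]
    fraction_skip6: Optional[float]
    method: str  # 'direct' | 'indirect'
    n_support: int
    defined: bool = True
    assumptions: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def fraction_skipped(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.fraction_skip56 + self.fraction_skip6  # type: ignore[operator]

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "method": self.method,
            "fraction_skip56": self.fraction_skip56,
            "fraction_skip6": self.fraction_skip6,
            "fraction_skipped": self.fraction_skipped,
            "n_support": self.n_support,
            "defined": self.defined,
            "assumptions": list(self.assumptions),
            "warnings": list(self.warnings),
        }


def quantify(
    calls_or_counts: Sequence[ReadCall] | PhasedCounts,
    denominator: str = "all",
) -> tuple[PhasedCounts, dict[str, float]]:
    """Contingency table plus overall isoform fractions.

    ``denominator`` selects the convention for the overall fractions:
    ``all`` (every accepted read, ``other`` included — the default) or
    ``known`` (reads assigned to the three known forms only).
    """
    counts = (
        calls_or_counts
        if isinstance(calls_or_counts, PhasedCounts)
        else PhasedCounts.from_calls(calls_or_counts)
    )
    fractions = overall_fractions(counts, denominator)
    return counts, fractions


def overall_fractions(counts: PhasedCounts, denominator: str = "all") -> dict[str, float]:
    if denominator not in ("all", "known"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    denom = counts.n_total
    if denominator == "known":
        denom -= counts.column_total("other")
    result: dict[str, float] = {}
    for col in ISOFORM_LABELS:
        result[f"fraction_{col}"] = (
            counts.column_total(col) / denom if denom else float("nan")
        )
    result["denominator"] = denom
    return result


def allele_skip_direct(counts: PhasedCounts, allele: str) -> AlleleSkipEstimate:
    """Skipping fraction of one allele from its phased reads alone.

    Valid when the SNV's exon is retained in every candidate isoform, so
    each read is phasable in principle.
    """
    if allele not in ("splice_allele", "trans_allele"):
        raise ValueError(f"unknown allele {allele!r}")
    row = counts[allele]
    total = counts.row_total(allele)
    if total == 0:
        return AlleleSkipEstimate(
            allele, None, None, "direct", 0, defined=False,
            warnings=("no reads phased to this allele; estimate undefined",),
        )
    return AlleleSkipEstimate(
        allele,
        row["skip56"] / total,
        row["skip6"] / total,
        "direct",
        total,
    )


def allele_skip_indirect(
    counts: PhasedCounts,
    skipping_labels: Sequence[str] = ("skip56", "skip6"),
) -> AlleleSkipEstimate:
    """Splice-allele skipping fraction when skipped reads are unphasable.

    Used when the phasing SNV lies inside the skipped exon(s): skipped reads
    lack the site and cannot be phased.  All skipped reads are attributed to
    the splice allele (justified when the trans allele shows no skipping
    wherever direct phasing is possible):

        S = skipped reads (unphased-by-structure + any phased splice-allele)
        I = phased splice-allele full-length reads
        fraction_skipped = S / (S + I)
    """
    s56 = counts["unphased"]["skip56"] + counts["splice_allele"]["skip56"]
    s6 = counts["unphased"]["skip6"] + counts["splice_allele"]["skip6"]
    skipped = {"skip56": s56 if "skip56" in skipping_labels else 0,
               "skip6": s6 if "skip6" in skipping_labels else 0}
    s_total = sum(skipped.values())
    inclusion = counts["splice_allele"]["full"]
    n_support = s_total + inclusion
    assumptions = (
        "all skipped reads attributed to the splice allele "
        "(trans allele assumed to show no skipping)",
    )
    if n_support == 0:
        return AlleleSkipEstimate(
            "splice_allele", None, None, "indirect", 0, defined=False,
            assumptions=assumptions,
            warnings=("no supporting reads; estimate undefined",),
        )
    warnings: tuple[str, ...] = ()
    if inclusion == 0 and s_total > 0:
        warnings = ("splice allele shows no inclusion reads; fraction is 1.0",)
    return AlleleSkipEstimate(
        "splice_allele",
        skipped["skip56"] / n_support,
        skipped["skip6"] / n_support,
        "indirect",
        n_support,
        assumptions=assumptions,
        warnings=warnings,
    )


def allele_balance(counts: PhasedCounts) -> dict[str, float]:
    """Each allele's share among phased reads only; shares sum to 1."""
    totals = {
        allele: counts.row_total(allele)
        for allele in ("splice_allele", "trans_allele")
    }
    n_phased = sum(totals.values())
    if n_phased == 0:
        raise ValueError("no phased reads; allele balance undefined")
    return {allele: n / n_phased for allele, n in totals.items()}


def write_snv_vcf(
    snv: PhasingSNV, model: TranscriptModel, path: str | Path
) -> None:
    """Minimal single-record VCF describing the phasing SNV in amplicon space."""
    pos = snv.amplicon_offset + 1  # VCF is 1-based
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={model.name},length={model.amplicon_length}>\n")
        fh.write(
            '##INFO=<ID=CDS,Number=1,Type=Integer,Description="CDS coordinate">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write(
            f"{model.name}\t{pos}\tc.{snv.cds_position}{snv.ref_base}>{snv.alt_base}"
            f"\t{snv.ref_base}\t{snv.alt_base}\t.\t.\tCDS={snv.cds_position}\n"
        )


def mask_structural_phase(
    counts: PhasedCounts, labels: Sequence[str] = ("skip56", "skip6")
) -> PhasedCounts:
    """Move phased counts of the given isoform columns into the unphased row.

    Emulates an SNV located inside the skipped exon(s): reads of those
    isoforms lose their phase information.  Used to check the indirect
    estimator against the direct one on simulations where both are possible.
    """
    new: dict[str, dict[str, int]] = {
        row: dict(counts[row]) for row in ALLELE_ROWS
    }
    for col in labels:
        moved = new["splice_allele"][col] + new["trans_allele"][col]
        new["splice_allele"][col] = 0
        new["trans_allele"][col] = 0
        new["unphased"][col] += moved
    return PhasedCounts(new)
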