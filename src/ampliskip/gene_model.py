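"""Amplicon/transcript exon model, skipping isoforms and frame arithmetic.

The central object is a :class:`TranscriptModel`: an ordered list of exons
concatenated into a single cDNA amplicon, with a CDS anchor so that HGVS-style
c.-coordinates can be mapped to positions within the amplicon.  From it we
derive exon-skipping isoforms (:func:`derive_isoform`), annotate the reading
frame consequence of a skipping event (:func:`frame_consequence`) and place
phasing SNVs (:func:`locate_snv`).

Coordinate conventions
----------------------
* CDS positions are 1-based inclusive c.-numbering (HGVS-facing).
* Amplicon offsets are 0-based, half-open intervals (slice-friendly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ModelError",
    "Exon",
    "TranscriptModel",
    "IsoformSpec",
    "FrameConsequence",
    "PhasingSNV",
    "build_transcript_model",
    "derive_isoform",
    "frame_consequence",
    "frame_from_deleted_nt",
    "locate_snv",
    "default_exon_lengths",
    "DEFAULT_CDS_START_OFFSET",
    "DEFAULT_CDS_LENGTH",
    "ISOFORM_LABELS",
    "model_to_bed",
    "model_from_config",
    "write_model_fasta",
]

VALID_BASES = frozenset("ACGT")

#: Canonical isoform labels, in reporting order.
ISOFORM_LABELS = ("full", "skip56", "skip6", "other")

# Default PHYH-like amplicon: 9 exons, exon 5 = 82 nt, exon 6 = 182 nt
# (so that skipping both removes 264 nt and skipping exon 6 alone 182 nt).
# Flanking exon sizes are a convention of this package: they put the three
# isoform lengths (1183 / 919 / 1001 nt) inside the 800-1800 nt QC window
# and place c.823 in retained exon 7.
_DEFAULT_EXON_LENGTHS = (150, 110, 104, 110, 82, 182, 160, 120, 165)
DEFAULT_CDS_START_OFFSET = 60  # 5'UTR occupies the first 60 nt of exon 1
DEFAULT_CDS_LENGTH = 1023  # multiple of 3; leaves a 100 nt 3'UTR in exon 9


def default_exon_lengths() -> tuple[int, ...]:
    """Exon lengths of the default PHYH-like amplicon model."""
    return _DEFAULT_EXON_LENGTHS


class ModelError(ValueError):
    """Raised for inconsistent transcript models or invalid coordinates."""


@dataclass(frozen=True)
class Exon:
    """One exon of the amplicon.

    Parameters
    ----------
    index
        1-based ordinal within the transcript.
    length
        Exon length in nucleotides.
    cds_span
        Inclusive (c.start, c.end) pair of the CDS bases this exon carries,
        or ``None`` for a UTR-only exon.
    sequence
        Optional nucleotide sequence; must match ``length`` when given.
    """

    index: int
    length: int
    cds_span: Optional[tuple[int, int]] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ModelError(f"exon {self.index}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ModelError(
                f"exon {self.index}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        if self.cds_span is not None:
            lo, hi = self.cds_span
            if lo < 1 or hi < lo:
                raise ModelError(f"exon {self.index}: invalid cds_span {self.cds_span}")
            if hi - lo + 1 > self.length:
                raise ModelError(
                    f"exon {self.index}: cds_span width {hi - lo + 1} exceeds length {self.length}"
                )

    @property
    def cds_width(self) -> int:
        if self.cds_span is None:
            return 0
        lo, hi = self.cds_span
        return hi - lo + 1

    @property
    def fully_coding(self) -> bool:
        return self.cds_span is not None and self.cds_width == self.length


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons forming one cDNA amplicon with a CDS anchor."""

    name: str
    exons: tuple[Exon, ...]
    cds_start_offset: int

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError("model needs at least one exon")
        for pos, exon in enumerate(self.exons, start=1):
            if exon.index != pos:
                raise ModelError(
                    f"exon indices must be consecutive from 1; found {exon.index} at position {pos}"
                )
        if not (0 <= self.cds_start_offset < self.amplicon_length):
            raise ModelError(
                f"cds_start_offset {self.cds_start_offset} outside amplicon "
                f"of length {self.amplicon_length}"
            )

    @property
    def amplicon_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def has_sequences(self) -> bool:
        return all(e.sequence is not None for e in self.exons)

    @property
    def sequence(self) -> str:
        if not self.has_sequences:
            raise ModelError("model carries no sequences")
        return "".join(e.sequence for e in self.exons)  # type: ignore[misc]

    def exon_start(self, index: int) -> int:
        """0-based amplicon offset of the first base of exon ``index``."""
        exon = self.exon(index)
        return sum(e.length for e in self.exons[: exon.index - 1])

    def exon(self, index: int) -> Exon:
        if not 1 <= index <= len(self.exons):
            raise ModelError(f"no exon with index {index}")
        return self.exons[index - 1]

    def exon_for_cds(self, cds_position: int) -> Exon:
        """Exon whose cds_span contains ``cds_position`` (c.-coordinate)."""
        for exon in self.exons:
            if exon.cds_span is not None:
                lo, hi = exon.cds_span
                if lo <= cds_position <= hi:
                    return exon
        raise ModelError(f"c.{cds_position} lies outside every exon CDS span")

    def cds_to_amplicon(self, cds_position: int) -> int:
        """Map a c.-coordinate to its 0-based offset within the full amplicon."""
        exon = self.exon_for_cds(cds_position)
        start = self.exon_start(exon.index)
        lo, _ = exon.cds_span  # type: ignore[misc]
        # Leading non-CDS bases occur only in the exon holding the CDS start.
        leading_utr = 0
        if self.cds_start_offset >= start and self.cds_start_offset < start + exon.length:
            leading_utr = self.cds_start_offset - start
        return start + leading_utr + (cds_position - lo)

    def amplicon_to_cds(self, offset: int) -> Optional[int]:
        """Inverse of :meth:`cds_to_amplicon`; ``None`` for UTR positions."""
        if not 0 <= offset < self.amplicon_length:
            raise ModelError(f"offset {offset} outside amplicon")
        for exon in self.exons:
            start = self.exon_start(exon.index)
            if start <= offset < start + exon.length and exon.cds_span is not None:
                lo, _ = exon.cds_span
                leading_utr = 0
                if start <= self.cds_start_offset < start + exon.length:
                    leading_utr = self.cds_start_offset - start
                delta = offset - start - leading_utr
                if 0 <= delta < exon.cds_width:
                    return lo + delta
        return None


@dataclass(frozen=True)
class IsoformSpec:
    """A named exon-subset isoform derived from a transcript model."""

    label: str
    skipped_exons: frozenset[int]
    deleted_nt: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.label == "full") != (not self.skipped_exons):
            raise ModelError("label 'full' iff no exon is skipped")

    def skips(self, exon_index: int) -> bool:
        return exon_index in self.skipped_exons


@dataclass(frozen=True)
class FrameConsequence:
    """Reading-frame effect of removing coding bases from a transcript."""

    deleted_nt: int
    frame_offset: int
    in_frame: bool
    deleted_residues: Optional[int]


@dataclass(frozen=True)
class PhasingSNV:
    """A coding SNV used to assign reads to their allele of origin."""

    cds_position: int
    ref_base: str
    alt_base: str
    splice_allele_base: str
    amplicon_offset: int
    exon_index: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ModelError("ref and alt bases must differ")
        for b in (self.ref_base, self.alt_base, self.splice_allele_base):
            if b not in VALID_BASES:
                raise ModelError(f"invalid base {b!r}")
        if self.splice_allele_base not in (self.ref_base, self.alt_base):
            raise ModelError("splice_allele_base must be ref or alt")

    @property
    def trans_allele_base(self) -> str:
        return self.alt_base if self.splice_allele_base == self.ref_base else self.ref_base

    def allele_of(self, base: str) -> Optional[str]:
        """Map an observed base to an allele name, or None for a third base."""
        if base == self.splice_allele_base:
            return "splice_allele"
        if base == self.trans_allele_base:
            return "trans_allele"
        return None

    def isoform_offset(self, isoform: IsoformSpec, model: TranscriptModel) -> Optional[int]:
        """0-based offset of the SNV within the isoform sequence.

        Returns ``None`` when the isoform skips the SNV's exon (the read is
        then unphasable by structure).
        """
        if isoform.skips(self.exon_index):
            return None
        removed_before = sum(
            model.exon(i).length for i in isoform.skipped_exons if i < self.exon_index
        )
        return self.amplicon_offset - removed_before


def build_transcript_model(
    exon_lengths: Sequence[int],
    cds_start_offset: int = 0,
    sequences: Optional[Sequence[str]] = None,
    cds_length: Optional[int] = None,
    name: str = "amplicon",
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel` from exon lengths and a CDS anchor.

    Parameters
    ----------
    exon_lengths
        Ordered exon lengths in nucleotides.
    cds_start_offset
        0-based amplicon position of the first CDS base (everything before
        it is 5'UTR).
    sequences
        Optional per-exon nucleotide sequences, one per exon.
    cds_length
        Number of CDS bases.  Defaults to everything from the CDS start to
        the amplicon end (no 3'UTR).
    """
    if sequences is not None and len(sequences) != len(exon_lengths):
        raise ModelError(
            f"got {len(sequences)} sequences for {len(exon_lengths)} exons"
        )
    total = sum(exon_lengths)
    if cds_length is None:
        cds_length = total - cds_start_offset
    if cds_start_offset + cds_length > total:
        raise ModelError("CDS extends past the amplicon end")
    if cds_length < 1:
        raise ModelError("CDS must contain at least one base")

    cds_lo = cds_start_offset
    cds_hi = cds_start_offset + cds_length  # half-open, amplicon coords
    exons = []
    start = 0
    for idx, length in enumerate(exon_lengths, start=1):
        end = start + length
        overlap_lo = max(start, cds_lo)
        overlap_hi = min(end, cds_hi)
        span = None
        if overlap_lo < overlap_hi:
            span = (overlap_lo - cds_lo + 1, overlap_hi - cds_lo)
        seq = None
        if sequences is not None:
            seq = sequences[idx - 1].upper()
            if len(seq) != length:
                raise ModelError(
                    f"exon {idx}: sequence length {len(seq)} != declared length {length}"
                )
        exons.append(Exon(index=idx, length=length, cds_span=span, sequence=seq))
        start = end
    return TranscriptModel(name=name, exons=tuple(exons), cds_start_offset=cds_start_offset)


def label_for_skipped(skipped: Iterable[int]) -> str:
    s = frozenset(skipped)
    if not s:
        return "full"
    if s == frozenset({5, 6}):
        return "skip56"
    if s == frozenset({6}):
        return "skip6"
    return "other"


def derive_isoform(
    model: TranscriptModel, skipped_exons: Iterable[int]
) -> IsoformSpec:
    """Build the isoform obtained by removing ``skipped_exons`` from the model.

    The label follows the field convention for this amplicon: {} -> full,
    {5,6} -> skip56, {6} -> skip6, anything else -> other.
    """
    skipped = frozenset(skipped_exons)
    for i in skipped:
        model.exon(i)  # raises on unknown index
    deleted = sum(model.exon(i).length for i in skipped)
    sequence = None
    if model.has_sequences:
        sequence = "".join(
            e.sequence for e in model.exons if e.index not in skipped  # type: ignore[misc]
        )
    return IsoformSpec(
        label=label_for_skipped(skipped),
        skipped_exons=skipped,
        deleted_nt=deleted,
        sequence=sequence,
    )


def frame_from_deleted_nt(deleted_nt: int) -> FrameConsequence:
    """Pure modular-arithmetic frame consequence of deleting CDS bases."""
    if deleted_nt < 0:
        raise ModelError("deleted_nt must be nonnegative")
    offset = deleted_nt % 3
    in_frame = offset == 0
    return FrameConsequence(
        deleted_nt=deleted_nt,
        frame_offset=offset,
        in_frame=in_frame,
        deleted_residues=deleted_nt // 3 if in_frame else None,
    )


def frame_consequence(
    model: TranscriptModel, skipped_exons: Iterable[int]
) -> FrameConsequence:
    """Reading-frame consequence of skipping a set of exons.

    Counts only CDS bases.  Skipping an exon without CDS bases (UTR-only)
    is rejected: its frame consequence is undefined.
    """
    skipped = frozenset(skipped_exons)
    deleted = 0
    for i in skipped:
        exon = model.exon(i)
        if exon.cds_span is None:
            raise ModelError(
                f"exon {i} carries no CDS bases; frame consequence undefined"
            )
        deleted += exon.cds_width
    return frame_from_deleted_nt(deleted)


def locate_snv(
    model: TranscriptModel,
    cds_position: int,
    ref_base: str,
    alt_base: str,
    splice_allele_base: str,
) -> PhasingSNV:
    """Place a phasing SNV given in c.-coordinates onto the amplicon."""
    if cds_position < 1:
        raise ModelError(f"invalid CDS position c.{cds_position}")
    exon = model.exon_for_cds(cds_position)
    offset = model.cds_to_amplicon(cds_position)
    return PhasingSNV(
        cds_position=cds_position,
        ref_base=ref_base.upper(),
        alt_base=alt_base.upper(),
        splice_allele_base=splice_allele_base.upper(),
        amplicon_offset=offset,
        exon_index=exon.index,
    )


# ---------------------------------------------------------------------------
# import / export


def model_to_bed(model: TranscriptModel, path: str | Path) -> None:
    """Write the exon structure as BED (0-based half-open, one line per exon)."""
    with open(path, "w") as fh:
        for exon in model.exons:
            start = model.exon_start(exon.index)
            fh.write(f"{model.name}\t{start}\t{start + exon.length}\texon{exon.index}\n")


def write_model_fasta(model: TranscriptModel, path: str | Path) -> None:
    """Write the full amplicon sequence as single-record FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(model.sequence), id=model.name, description="")
    SeqIO.write([record], str(path), "fasta")


def model_from_config(
    config: Mapping | str | Path,
    fasta: Optional[str | Path] = None,
) -> tuple[TranscriptModel, list[PhasingSNV], dict[str, frozenset[int]]]:
    """Load a model, its phasing SNVs and isoform definitions from JSON config.

    The config carries ``exon_lengths``, ``cds_start_offset``, optional
    ``cds_length`` and ``name``, a map ``isoforms`` of label -> skipped exon
    indices, and a list ``snvs`` of {cds_position, ref, alt,
    splice_allele_base}.  Sequences come from ``fasta`` (a single amplicon
    record, split by exon lengths) when provided.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = json.load(fh)
    lengths = list(config["exon_lengths"])
    sequences = None
    if fasta is not None:
        from Bio import SeqIO

        record = next(SeqIO.parse(str(fasta), "fasta"))
        full = str(record.seq).upper()
        if len(full) != sum(lengths):
            raise ModelError(
                f"FASTA length {len(full)} != sum of exon lengths {sum(lengths)}"
            )
        sequences, start = [], 0
        for length in lengths:
            sequences.append(full[start : start + length])
            start += length
    model = build_transcript_model(
        lengths,
        cds_start_offset=int(config.get("cds_start_offset", 0)),
        sequences=sequences,
        cds_length=config.get("cds_length"),
        name=str(config.get("name", "amplicon")),
    )
    snvs = [
        locate_snv(
            model,
            int(entry["cds_position"]),
            entry["ref"],
            entry["alt"],
            entry["splice_allele_base"],
        )
        for entry in config.get("snvs", [])
    ]
    isoforms = {
        str(label): frozenset(int(i) for i in skipped)
        for label, skipped in config.get(
            "isoforms", {"full": [], "skip56": [5, 6], "skip6": [6]}
        ).items()
    }
    if "full" not in isoforms:
        isoforms["full"] = frozenset()
    return model, snvs, isoforms
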