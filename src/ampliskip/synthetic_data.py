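"""Seeded, truth-labeled ONT-like read simulation from biallelic isoform mixtures.

Emulates an RT-PCR amplicon experiment: two alleles (distinguished by one or
more coding SNVs) each emit a configurable mixture of splice isoforms, and
every emitted read is corrupted with independent per-base substitution /
insertion / deletion events carrying two-level Phred qualities.  A truth
table records each read's allele and isoform of origin, so downstream
classification and phasing can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import (
    ModelError,
    IsoformSpec,
    PhasingSNV,
    TranscriptModel,
    build_transcript_model,
    default_exon_lengths,
    derive_isoform,
    DEFAULT_CDS_LENGTH,
    DEFAULT_CDS_START_OFFSET,
)

__all__ = [
    "AlleleSpec",
    "ErrorModel",
    "SequencedRead",
    "simulate_sample",
    "corrupt_sequence",
    "generate_synthetic_gene",
    "write_fastq",
    "read_fastq",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SequencedRead:
    """A read with per-base Phred qualities (Sanger scale)."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base ONT-like error process.

    Defaults (sub/ins/del = 0.03/0.02/0.02, ~7% total error) are chosen so
    that raw simulated reads straddle a Q10 mean-quality filter realistically;
    correct bases get Q14 (4% implied error) and erroneous bases Q7.
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    quality_correct: int = 14
    quality_error: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {rate}")

    @property
    def error_free(self) -> bool:
        return self.sub_rate == self.ins_rate == self.del_rate == 0


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a biallelic sample.

    ``snv_bases`` maps each phasing SNV's c.-position to the base this allele
    carries there; ``isoform_weights`` gives the allele's splice-isoform
    mixture and ``weight`` its share of total reads.
    """

    name: str
    snv_bases: Mapping[int, str]
    isoform_weights: Mapping[str, float]
    weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"allele weight must lie in [0,1], got {self.weight}")
        total = sum(self.isoform_weights.values())
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(
                f"isoform weights of allele {self.name!r} sum to {total}, not 1"
            )


def corrupt_sequence(
    seq: str, error_model: ErrorModel, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply per-base substitution/insertion/deletion noise to one sequence.

    Every template base is independently deleted (``del_rate``) or emitted,
    possibly substituted (``sub_rate``); before each template base and after
    the last one an extra base is inserted with probability ``ins_rate``.
    Substituted and inserted bases carry ``quality_error``; faithful bases
    ``quality_correct``.  Returns the read sequence and its quality array.
    """
    if not seq:
        raise ValueError("cannot corrupt an empty sequence")
    idx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    n = idx.size

    if error_model.error_free:
        quals = np.full(n, error_model.quality_correct, dtype=np.int16)
        return seq, quals

    keep = rng.random(n) >= error_model.del_rate
    sub = keep & (rng.random(n) < error_model.sub_rate)
    # substitution: shift by 1..3 in base space, never the original base
    shift = rng.integers(1, 4, size=n)
    out_idx = (idx + np.where(sub, shift, 0)) % 4
    quals = np.where(
        sub, error_model.quality_error, error_model.quality_correct
    ).astype(np.int16)

    out_idx = out_idx[keep]
    quals = quals[keep]

    ins_slots = np.nonzero(rng.random(n + 1) < error_model.ins_rate)[0]
    if ins_slots.size:
        kept_positions = np.nonzero(keep)[0]
        insert_at = np.searchsorted(kept_positions, ins_slots)
        ins_bases = rng.integers(0, 4, size=ins_slots.size)
        out_idx = np.insert(out_idx, insert_at, ins_bases)
        quals = np.insert(
            quals, insert_at, np.int16(error_model.quality_error)
        )

    read_seq = _BASES[out_idx].tobytes().decode("ascii")
    return read_seq, quals


def _template(
    isoform: IsoformSpec,
    allele: AlleleSpec,
    snvs: Sequence[PhasingSNV],
    model: TranscriptModel,
) -> str:
    """Isoform sequence with the allele's SNV bases planted where retained.

    When an SNV's exon is skipped by the isoform the read simply lacks the
    site: no sentinel base is planted (such reads are unphasable by
    structure, exactly as in the real assay).
    """
    if isoform.sequence is None:
        raise ModelError(f"isoform {isoform.label!r} carries no sequence")
    seq = list(isoform.sequence)
    for snv in snvs:
        offset = snv.isoform_offset(isoform, model)
        if offset is None:
            continue
        base = allele.snv_bases.get(snv.cds_position)
        if base is None:
            raise ValueError(
                f"allele {allele.name!r} defines no base for SNV c.{snv.cds_position}"
            )
        seq[offset] = base.upper()
    return "".join(seq)


def simulate_sample(
    model: TranscriptModel,
    isoforms: Sequence[IsoformSpec],
    alleles: Sequence[AlleleSpec],
    n_reads: int,
    error_model: ErrorModel,
    snvs: Sequence[PhasingSNV] = (),
    seed: Optional[int] = None,
    read_prefix: str = "sim",
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """Simulate one sample: reads plus a one-row-per-read truth table.

    Each read independently samples its allele (by allele weight), then its
    isoform (by that allele's isoform weights), plants the allele's SNV
    bases, and is corrupted through :func:`corrupt_sequence`.  Fully
    reproducible from ``seed`` (falls back to ``error_model.seed``).
    """
    if n_reads < 1:
        raise ValueError(f"n_reads must be >= 1, got {n_reads}")
    if abs(sum(a.weight for a in alleles) - 1.0) > WEIGHT_TOL:
        raise ValueError("allele weights must sum to 1")
    by_label = {iso.label: iso for iso in isoforms}
    rng = np.random.default_rng(error_model.seed if seed is None else seed)

    templates: dict[tuple[str, str], str] = {}
    for allele in alleles:
        for label, w in allele.isoform_weights.items():
            if label not in by_label:
                raise ValueError(f"allele {allele.name!r} references unknown isoform {label!r}")
            if w > 0:
                templates[(allele.name, label)] = _template(
                    by_label[label], allele, snvs, model
                )

    allele_idx = rng.choice(
        len(alleles), size=n_reads, p=[a.weight for a in alleles]
    )
    reads: list[SequencedRead] = []
    truth_rows: list[tuple[str, str, str]] = []
    iso_choices = {
        a.name: (list(a.isoform_weights), list(a.isoform_weights.values()))
        for a in alleles
    }
    for i in range(n_reads):
        allele = alleles[allele_idx[i]]
        labels, weights = iso_choices[allele.name]
        label = labels[rng.choice(len(labels), p=weights)]
        template = templates[(allele.name, label)]
        seq, quals = corrupt_sequence(template, error_model, rng)
        read_id = f"{read_prefix}_{i:06d}"
        reads.append(SequencedRead(read_id, seq, tuple(int(q) for q in quals)))
        truth_rows.append((read_id, label, allele.name))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "true_isoform", "true_allele"]
    )
    return reads, truth


def generate_synthetic_gene(
    exon_lengths: Optional[Sequence[int]] = None,
    gc_fraction: float = 0.5,
    seed: int = 0,
    cds_start_offset: int = DEFAULT_CDS_START_OFFSET,
    cds_length: Optional[int] = DEFAULT_CDS_LENGTH,
    name: str = "synthetic_amplicon",
    min_pairwise_distance: int = 50,
    max_retries: int = 20,
    candidate_skips: Sequence[Sequence[int]] = ((), (5, 6), (6,)),
) -> TranscriptModel:
    """Random exon sequences at a target GC content, deterministic per seed.

    Guarantees the three candidate isoforms (full / skip exons 5+6 / skip
    exon 6) are pairwise distinguishable: minimum pairwise edit distance of
    ``min_pairwise_distance``, redrawn on failure.
    """
    import edlib

    if exon_lengths is None:
        exon_lengths = default_exon_lengths()
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    for _ in range(max_retries):
        sequences = [
            _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")
            for length in exon_lengths
        ]
        model = build_transcript_model(
            exon_lengths,
            cds_start_offset=cds_start_offset,
            sequences=sequences,
            cds_length=cds_length,
            name=name,
        )
        n_exons = len(exon_lengths)
        usable = [s for s in candidate_skips if all(1 <= i <= n_exons for i in s)]
        candidates = [derive_isoform(model, s) for s in usable]
        ok = True
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                d = edlib.align(
                    candidates[i].sequence, candidates[j].sequence, mode="NW"
                )["editDistance"]
                if d < min_pairwise_distance:
                    ok = False
        if ok:
            return model
    raise ModelError(
        f"could not draw pairwise-distinguishable isoforms in {max_retries} tries"
    )


# ---------------------------------------------------------------------------
# FASTQ / truth-table I/O


def write_fastq(reads: Sequence[SequencedRead], path: str | Path) -> None:
    """Write reads as FASTQ with Sanger Phred+33 qualities."""
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[SequencedRead]:
    """Load FASTQ (Sanger Phred+33) into :class:`SequencedRead` records."""
    from Bio import SeqIO

    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SequencedRead(
                record.id,
                str(record.seq).upper(),
                tuple(record.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
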