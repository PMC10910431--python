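"""Isoform classification by error-tolerant alignment against a candidate set.

With a single known amplicon and an enumerable set of splice isoforms, read
classification is a closed problem: each read is globally aligned (unit-cost
Levenshtein) against every candidate isoform sequence and assigned to the
nearest one, subject to an absolute-distance acceptance rule and a
best-vs-second-best margin rule.  Reads failing either rule are called
``other`` — a first-class category, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import edlib
import pandas as pd

from .gene_model import IsoformSpec, TranscriptModel
from .synthetic_data import SequencedRead

__all__ = [
    "ClassifyParams",
    "ReadCall",
    "JunctionTable",
    "align_distance",
    "classify_read",
    "classify_reads",
    "junction_counts",
    "write_sam",
    "plot_junctions",
    "calls_to_dataframe",
    "write_calls",
]


@dataclass(frozen=True)
class ClassifyParams:
    """Acceptance rules for isoform calls.

    max_norm_dist
        Maximum best edit distance divided by the best isoform's length;
        calls above this are too noisy to trust.
    min_margin
        Required gap (nt) between the best and second-best edit distance;
        ties (margin 0) are never broken arbitrarily — the read becomes
        ``other``.
    """

    max_norm_dist: float = 0.20
    min_margin: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.max_norm_dist < 0.5:
            raise ValueError("max_norm_dist must lie in (0, 0.5)")
        if self.min_margin < 1:
            raise ValueError("min_margin must be >= 1")


@dataclass(frozen=True)
class ReadCall:
    """Per-read outcome: isoform label, audit distances, phasing slot."""

    read_id: str
    isoform: str
    distances: dict[str, int]
    margin: Optional[int]
    allele: str = "unphased"
    phase_reason: Optional[str] = None

    def with_allele(self, allele: str, reason: str) -> "ReadCall":
        return replace(self, allele=allele, phase_reason=reason)


def align_distance(seq_a: str, seq_b: str) -> int:
    """Unit-cost global (end-to-end) Levenshtein distance between sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]


def classify_read(
    read: SequencedRead,
    isoforms: Sequence[IsoformSpec],
    params: ClassifyParams = ClassifyParams(),
) -> ReadCall:
    """Assign one read to its nearest candidate isoform, or ``other``.

    Requires at least two candidates with sequences.  The distances to every
    candidate are retained on the call for auditability.
    """
    if len(isoforms) < 2:
        raise ValueError("need at least two candidate isoforms")
    distances: dict[str, int] = {}
    for iso in isoforms:
        if iso.sequence is None:
            raise ValueError(f"isoform {iso.label!r} carries no sequence")
        distances[iso.label] = align_distance(read.sequence, iso.sequence)
    ordered = sorted(distances.items(), key=lambda kv: kv[1])
    (best_label, best_dist), (_, second_dist) = ordered[0], ordered[1]
    margin = second_dist - best_dist
    best_len = next(len(i.sequence) for i in isoforms if i.label == best_label)
    if best_dist <= params.max_norm_dist * best_len and margin >= params.min_margin:
        label = best_label
    else:
        label = "other"
    return ReadCall(read.id, label, distances, margin)


def classify_reads(
    reads: Sequence[SequencedRead],
    isoforms: Sequence[IsoformSpec],
    params: ClassifyParams = ClassifyParams(),
) -> list[ReadCall]:
    return [classify_read(r, isoforms, params) for r in reads]


@dataclass
class JunctionTable:
    """Counts of reads supporting each adjacent retained-exon junction."""

    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"exon_left": left, "exon_right": right, "n_reads": n}
            for (left, right), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["exon_left", "exon_right", "n_reads"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_bed12(self, model: TranscriptModel, path: str | Path) -> None:
        """BED12-style record per junction: two blocks flanking the gap."""
        with open(path, "w") as fh:
            for (left, right), n in sorted(self.counts.items()):
                l_start = model.exon_start(left)
                l_end = l_start + model.exon(left).length
                r_start = model.exon_start(right)
                r_end = r_start + model.exon(right).length
                fh.write(
                    "\t".join(
                        [
                            model.name,
                            str(l_start),
                            str(r_end),
                            f"junction_{left}_{right}",
                            str(n),
                            "+",
                            str(l_start),
                            str(r_end),
                            "0,0,0",
                            "2",
                            f"{l_end - l_start},{r_end - r_start}",
                            f"0,{r_start - l_start}",
                        ]
                    )
                    + "\n"
                )


def junction_counts(
    calls: Sequence[ReadCall],
    model: TranscriptModel,
    isoforms: Sequence[IsoformSpec],
) -> JunctionTable:
    """Tally exon-exon junction support implied by the isoform calls.

    Each non-``other`` read contributes every adjacent retained-exon pair of
    its called isoform exactly once; e.g. a read skipping exons 5 and 6
    supports the exon4-exon7 junction.
    """
    by_label = {iso.label: iso for iso in isoforms}
    table = JunctionTable()
    for call in calls:
        iso = by_label.get(call.isoform)
        if iso is None:  # 'other' or unknown label
            continue
        retained = [e.index for e in model.exons if not iso.skips(e.index)]
        for left, right in zip(retained, retained[1:]):
            key = (left, right)
            table.counts[key] = table.counts.get(key, 0) + 1
    return table


def plot_junctions(
    table: JunctionTable, model: TranscriptModel, path: str | Path
) -> None:
    """Sashimi-like bar chart of junction-spanning read support."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(table.counts.items())
    labels = [f"e{l}-e{r}" for (l, r), _ in items]
    values = [n for _, n in items]
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(items)), 3))
    ax.bar(labels, values, color="#4878a8")
    ax.set_ylabel("supporting reads")
    ax.set_title(f"{model.name}: splice junction support")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_sam(
    reads: Sequence[SequencedRead],
    calls: Sequence[ReadCall],
    isoforms: Sequence[IsoformSpec],
    path: str | Path,
) -> None:
    """Export each read's alignment to its called isoform as SAM.

    Reads called ``other`` are emitted unmapped.  The extended CIGAR
    operators (=/X) produced by the aligner are valid SAM.
    """
    if len(reads) != len(calls):
        raise ValueError("reads and calls must pair one-to-one")
    by_label = {iso.label: iso for iso in isoforms}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for iso in isoforms:
            fh.write(f"@SQ\tSN:{iso.label}\tLN:{len(iso.sequence)}\n")
        for read, call in zip(reads, calls):
            qual = "".join(chr(q + 33) for q in read.qualities)
            iso = by_label.get(call.isoform)
            if iso is None:
                fh.write(
                    f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t{qual}\n"
                )
                continue
            result = edlib.align(read.sequence, iso.sequence, mode="NW", task="path")
            fh.write(
                f"{read.id}\t0\t{iso.label}\t1\t60\t{result['cigar']}\t*\t0\t0\t"
                f"{read.sequence}\t{qual}\tNM:i:{result['editDistance']}\n"
            )


def calls_to_dataframe(calls: Sequence[ReadCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        best = min(c.distances.values()) if c.distances else None
        rows.append(
            {
                "read_id": c.read_id,
                "isoform": c.isoform,
                "best_distance": best,
                "margin": c.margin,
                "allele": c.allele,
                "phase_reason": c.phase_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "isoform", "best_distance", "margin", "allele", "phase_reason"],
    )


def write_calls(calls: Sequence[ReadCall], path: str | Path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)
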