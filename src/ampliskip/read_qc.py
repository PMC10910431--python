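"""Read filtering: length window plus minimum mean quality.

The mean read quality is computed in error-probability space — per-base
Phred scores are converted to error probabilities, averaged, and converted
back — matching the convention of standard long-read filtering tools.  This
differs from (and is never larger than) the arithmetic mean of the Phred
values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic_data import SequencedRead

__all__ = ["QCParams", "QCStats", "mean_read_quality", "filter_reads"]

#: Tolerance on the quality comparison: a read whose every base is exactly at
#: the threshold must pass, but the probability-space round trip
#: (10**(-q/10) and back) loses the last ulp, so compare with a 1e-9 slack.
QUALITY_EPS = 1e-9


@dataclass(frozen=True)
class QCParams:
    """Filtering thresholds: closed length interval, minimum mean Phred Q."""

    min_len: int = 800
    max_len: int = 1800
    min_mean_q: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError(
                f"need 0 < min_len <= max_len, got {self.min_len}..{self.max_len}"
            )
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


@dataclass(frozen=True)
class QCStats:
    """Partition of the input: kept + failed-length + failed-quality.

    A read failing both checks is counted as a length failure (length takes
    precedence), so the three categories always sum to ``n_input``.
    """

    n_input: int
    n_kept: int
    n_fail_length: int
    n_fail_quality: int

    def __post_init__(self) -> None:
        if self.n_kept + self.n_fail_length + self.n_fail_quality != self.n_input:
            raise ValueError("QC counts do not partition the input")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_fail_length": self.n_fail_length,
            "n_fail_quality": self.n_fail_quality,
        }


def mean_read_quality(qualities: Sequence[int]) -> float:
    """Mean Phred quality of a read, averaged in error-probability space.

    Returns -10*log10(mean of 10^(-q/10)).  Raises on an empty read.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("cannot compute mean quality of an empty read")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


def filter_reads(
    reads: Sequence[SequencedRead], params: QCParams = QCParams()
) -> tuple[list[SequencedRead], QCStats]:
    """Keep reads inside the closed length window with mean quality >= cutoff.

    Input order is preserved; empty input yields empty output and zero stats.
    """
    kept: list[SequencedRead] = []
    n_fail_length = 0
    n_fail_quality = 0
    for read in reads:
        if not params.min_len <= len(read) <= params.max_len:
            n_fail_length += 1
        elif mean_read_quality(read.qualities) < params.min_mean_q - QUALITY_EPS:
            n_fail_quality += 1
        else:
            kept.append(read)
    stats = QCStats(
        n_input=len(reads),
        n_kept=len(kept),
        n_fail_length=n_fail_length,
        n_fail_quality=n_fail_quality,
    )
    return kept, stats
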