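"""Error-tolerant adapter trimming, trimming statistics and the CSV report.

The trimmer is mismatch-only (no indels), mirroring the inference stage: a
3' adapter match removes the match and everything after it; a 5' adapter
match removes everything through the adapter's last base.  Partial matches
are honoured at the relevant read end (adapter prefix at the 3' end, adapter
suffix overhanging the 5' end) down to ``min_overlap`` bases.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from .inference import AdapterCall
from .sequence_io import Read

__all__ = [
    "TrimStats",
    "trim_3p",
    "trim_5p",
    "trim_library",
    "adapter_fraction",
    "write_report",
]


@dataclass(frozen=True)
class TrimStats:
    """Per-file trimming statistics; the fraction of reads carrying the 3'
    adapter is the primary indicator of proper trimming."""

    n_reads: int
    n_with_3p: int
    n_with_5p: int
    pct_with_3p: float
    mean_len_before: float
    mean_len_after: float


def _mismatches_within(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def trim_3p(
    read: Read, adapter: str, error_rate: float = 0.1, min_overlap: int = 3
) -> Read:
    """Remove the leftmost 3' adapter occurrence and everything after it.

    A full-adapter match may sit anywhere; at the read end an adapter
    *prefix* of at least ``min_overlap`` bases suffices.  Up to
    floor(error_rate * matched_length) mismatches are tolerated.  Qualities
    stay in register; a read without a match is returned unchanged.
    """
    if len(adapter) < 3:
        raise ValueError("adapter must be at least 3 nt")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    seq = read.seq
    n, alen = len(seq), len(adapter)
    for pos in range(n):
        matched = min(alen, n - pos)
        if matched < alen and matched < min_overlap:
            break
        limit = math.floor(error_rate * matched)
        if _mismatches_within(seq[pos : pos + matched], adapter[:matched], limit):
            if pos == 0:
                # an adapter-only read trims to nothing; keep 1-base stub to
                # satisfy the non-empty read invariant downstream formats need
                return Read(read.id, seq[:1], read.qual[:1] if read.qual else None)
            return Read(
                read.id, seq[:pos], read.qual[:pos] if read.qual else None
            )
    return read


def trim_5p(
    read: Read, adapter: str, error_rate: float = 0.1, min_overlap: int = 3
) -> Read:
    """Remove through the last base of the rightmost 5' adapter occurrence.

    The adapter may overhang the read start (degraded 5' adapters keep only
    their 3'-side suffix), so adapter *suffixes* anchored at the read start
    are accepted down to ``min_overlap`` bases.  When both adapters are
    called, 5' trimming is applied before 3' trimming.
    """
    if len(adapter) < 3:
        raise ValueError("adapter must be at least 3 nt")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    seq = read.seq
    n, alen = len(seq), len(adapter)
    for end in range(n, min_overlap - 1, -1):
        start = end - alen
        matched = end - max(start, 0)
        if matched < min_overlap:
            continue
        limit = math.floor(error_rate * matched)
        if _mismatches_within(
            seq[max(start, 0) : end], adapter[alen - matched :], limit
        ):
            if end == n:
                return Read(read.id, seq[-1:], read.qual[-1:] if read.qual else None)
            return Read(
                read.id, seq[end:], read.qual[end:] if read.qual else None
            )
    return read


def trim_library(
    reads: Iterable[Read],
    call: AdapterCall,
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[list[Read], TrimStats]:
    """Trim every read with the called adapters and collect statistics."""
    trimmed: list[Read] = []
    n = n3 = n5 = 0
    len_before = len_after = 0
    for read in reads:
        n += 1
        len_before += len(read.seq)
        out = read
        if call.five_prime:
            if call.evidence.get("five_prime_anchored"):
                # anchored barcode: an exact prefix, stripped in place
                if out.seq.startswith(call.five_prime):
                    k = len(call.five_prime)
                    cut = Read(
                        out.id, out.seq[k:], out.qual[k:] if out.qual else None
                    )
                else:
                    cut = out
            else:
                cut = trim_5p(out, call.five_prime, error_rate, min_overlap)
            if cut.seq != out.seq:
                n5 += 1
            out = cut
        if call.three_prime:
            cut = trim_3p(out, call.three_prime, error_rate, min_overlap)
            if cut.seq != out.seq:
                n3 += 1
            out = cut
        len_after += len(out.seq)
        trimmed.append(out)
    if n == 0:
        raise ValueError("empty library")
    stats = TrimStats(
        n_reads=n,
        n_with_3p=n3,
        n_with_5p=n5,
        pct_with_3p=round(100.0 * n3 / n, 1),
        mean_len_before=len_before / n,
        mean_len_after=len_after / n,
    )
    return trimmed, stats


def adapter_fraction(
    reads: Iterable[Read],
    adapter: str,
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> float:
    """Percentage of reads changed by 3' trimming, rounded to one decimal."""
    n = hit = 0
    for read in reads:
        n += 1
        if trim_3p(read, adapter, error_rate, min_overlap).seq != read.seq:
            hit += 1
    if n == 0:
        raise ValueError("empty library")
    return round(100.0 * hit / n, 1)


REPORT_COLUMNS = [
    "filename",
    "status",
    "five_prime",
    "three_prime",
    "pct_with_3p",
    "n_reads",
    "n_with_3p",
    "n_with_5p",
    "mean_len_before",
    "mean_len_after",
    "evidence",
]


def write_report(
    entries: Sequence[tuple[str, AdapterCall, TrimStats | None]],
    path: str | Path,
) -> None:
    """Write the consolidated per-file CSV report (RFC-4180 quoting)."""
    if not entries:
        raise ValueError("no entries to report")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(REPORT_COLUMNS)
        for filename, call, stats in entries:
            writer.writerow(
                [
                    filename,
                    call.status,
                    call.five_prime or "",
                    call.three_prime or "",
                    "" if stats is None else stats.pct_with_3p,
                    "" if stats is None else stats.n_reads,
                    "" if stats is None else stats.n_with_3p,
                    "" if stats is None else stats.n_with_5p,
                    "" if stats is None else round(stats.mean_len_before, 2),
                    "" if stats is None else round(stats.mean_len_after, 2),
                    json.dumps(call.evidence, sort_keys=True, default=str),
                ]
            )
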