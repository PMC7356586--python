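"""FASTQ input/output, read collapsing, SOLiD colorspace codec, trim detection.

Reads are plain immutable records; collapsing turns a library into the ranked
list of unique sequences that every downstream inference step consumes.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "CollapsedRead",
    "ColorRead",
    "FastqParseError",
    "EmptyLibraryError",
    "ColorspaceError",
    "read_fastq",
    "write_fastq",
    "collapse_reads",
    "decode_colorspace",
    "encode_colorspace",
    "detect_trimmed",
    "weighted_median_length",
]

DNA_ALPHABET = frozenset("ACGTN")

# 2-bit base codes; a SOLiD color is the XOR of the codes of adjacent bases,
# which reproduces the standard di-base table (0 = identity, 1 = A<->C/G<->T,
# 2 = A<->G/C<->T, 3 = A<->T/C<->G).
_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS2BASE = "ACGT"


class FastqParseError(ValueError):
    """Raised when a FASTQ record is malformed; names the record index."""


class EmptyLibraryError(ValueError):
    """Raised when an operation that needs reads receives none."""


class ColorspaceError(ValueError):
    """Raised on invalid colorspace input (bad color digit, N on encode)."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read.

    ``qual`` is optional and, when present, is carried verbatim and must match
    ``seq`` in length.
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its occurrence count and abundance rank."""

    seq: str
    count: int
    rank: int


@dataclass(frozen=True)
class ColorRead:
    """A SOLiD colorspace read: known primer base followed by color digits."""

    id: str
    primer_base: str
    colors: str

    def __post_init__(self) -> None:
        if self.primer_base not in "ACGT":
            raise ColorspaceError(
                f"read {self.id!r}: invalid primer base {self.primer_base!r}"
            )


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield reads from a 4-line FASTQ file (plain or gzip) in file order.

    Sequences are uppercased and U is mapped to T.  A malformed record raises
    :class:`FastqParseError` naming the 0-based index of the offending record.
    """
    handle = _open_text(path)
    index = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            seq = seq.upper().replace("U", "T")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield Read(id=title.split()[0] if title else f"read{index}",
                       seq=seq, qual=qual)
            index += 1
    finally:
        handle.close()


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as 4-line FASTQ; missing qualities become 'I' runs."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            out.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def collapse_reads(reads: Iterable[Read | str]) -> list[CollapsedRead]:
    """Collapse reads into unique sequences ranked by descending count.

    Ties in count are broken lexicographically by sequence so that the ranking
    is deterministic under any permutation of the input.
    """
    counts: Counter[str] = Counter(
        r.seq if isinstance(r, Read) else r for r in reads
    )
    if not counts:
        raise EmptyLibraryError("empty library")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(seq=seq, count=count, rank=rank)
        for rank, (seq, count) in enumerate(ordered, start=1)
    ]


def decode_colorspace(cread: ColorRead) -> Read:
    """Decode a SOLiD colorspace read into base space.

    Decoding walks left to right from the primer base; the primer base itself
    is not part of the biological sequence and is dropped from the output.  A
    '.' (missing color) decodes to N and, because each color encodes a
    transition, poisons every subsequent base to N as well.
    """
    bases: list[str] = []
    prev = _BASE2BITS[cread.primer_base]
    poisoned = False
    for i, color in enumerate(cread.colors):
        if poisoned:
            bases.append("N")
            continue
        if color == ".":
            bases.append("N")
            poisoned = True
            continue
        if color not in "0123":
            raise ColorspaceError(
                f"read {cread.id!r}: invalid color {color!r} at position {i}"
            )
        prev ^= int(color)
        bases.append(_BITS2BASE[prev])
    return Read(id=cread.id, seq="".join(bases))


def encode_colorspace(read: Read, primer_base: str = "T") -> ColorRead:
    """Encode a base-space read as SOLiD colors; exact inverse of decoding.

    Raises :class:`ColorspaceError` if the read contains N (a transition to an
    ambiguous base has no color).
    """
    if primer_base not in "ACGT":
        raise ColorspaceError(f"invalid primer base {primer_base!r}")
    colors: list[str] = []
    prev = _BASE2BITS[primer_base]
    for i, base in enumerate(read.seq):
        if base not in _BASE2BITS:
            raise ColorspaceError(
                f"read {read.id!r}: cannot encode base {base!r} at position {i}"
            )
        code = _BASE2BITS[base]
        colors.append(str(prev ^ code))
        prev = code
    return ColorRead(id=read.id, primer_base=primer_base, colors="".join(colors))


def detect_trimmed(
    collapsed: Sequence[CollapsedRead],
    total_reads: int | None = None,
    modal_fraction: float = 0.90,
) -> bool:
    """Decide whether a library has already had its adapters trimmed.

    Untrimmed single-read output has a constant machine read length, so the
    modal length accounts for essentially all reads; trimming spreads the
    length distribution over the insert sizes.  Returns True when the modal
    raw read length accounts for less than ``modal_fraction`` of the reads
    (count-weighted).
    """
    if not collapsed:
        raise EmptyLibraryError("empty library")
    if total_reads is None:
        total_reads = sum(c.count for c in collapsed)
    length_counts: Counter[int] = Counter()
    for c in collapsed:
        length_counts[len(c.seq)] += c.count
    modal = max(length_counts.values())
    return modal / total_reads < modal_fraction


def weighted_median_length(collapsed: Sequence[CollapsedRead]) -> float:
    """Count-weighted median of raw read lengths from a collapsed library."""
    if not collapsed:
        raise EmptyLibraryError("empty library")
    pairs = sorted((len(c.seq), c.count) for c in collapsed)
    total = sum(count for _, count in pairs)
    half = total / 2.0
    cum = 0
    for i, (length, count) in enumerate(pairs):
        cum += count
        if cum > half:
            return float(length)
        if cum == half:
            # even split: average this length with the next distinct one
            nxt = pairs[i + 1][0] if i + 1 < len(pairs) else length
            return (length + nxt) / 2.0
    return float(pairs[-1][0])
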