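"""Detection of randomized N bases at read termini.

Randomized-adapter library protocols add 2-4 random nucleotides at the
ligation junctions to reduce ligation bias.  After adapter trimming these
appear as a constant-length margin that cannot align to the reference
genome: if every insert aligns starting at query position 5, there is a
4-mer at the 5' end; the unaligned tail length plays the same role at the
3' end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

from .align import HSP, AlignParams, find_hsps, revcomp
from .inference import FilterThresholds, is_homopolymer, is_low_complexity
from .sequence_io import CollapsedRead

__all__ = [
    "RandomMerCall",
    "select_randommer_queries",
    "detect_random_mers",
    "REFERENCE_ALIGN_PARAMS",
]

#: Reference search uses a longer seed than read-vs-read alignment: inserts
#: are >= ~21 nt of exact genomic sequence, and the longer word keeps chance
#: hits against a 100 kb+ reference negligible.
REFERENCE_ALIGN_PARAMS = AlignParams(word_size=12, min_score=18, xdrop=6)


@dataclass(frozen=True)
class RandomMerCall:
    """Inferred random-mer lengths with their supporting mode fractions."""

    five_prime_n: int
    three_prime_n: int
    five_mode_fraction: float
    three_mode_fraction: float
    n_aligned: int

    def __post_init__(self) -> None:
        if not (0 <= self.five_prime_n <= 8 and 0 <= self.three_prime_n <= 8):
            raise ValueError("random-mer lengths must be within 0..8")


def select_randommer_queries(
    collapsed: Sequence[CollapsedRead],
    n_query: int = 750,
    min_length: int = 29,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[str], list[str]]:
    """Top-ranked sequences of length >= 29 eligible for reference search.

    Same eligibility rules as adapter inference (no N, no homopolymer or
    low-complexity sequence); returns (queries, warnings).
    """
    queries: list[str] = []
    for c in collapsed:
        seq = c.seq
        if len(seq) < min_length or "N" in seq:
            continue
        if is_homopolymer(seq) or is_low_complexity(seq):
            continue
        queries.append(seq)
        if len(queries) >= n_query:
            break
    if not queries:
        raise ValueError("no queries of sufficient length")
    warnings: list[str] = []
    if len(queries) < n_query:
        warnings.append(
            f"only {len(queries)} eligible queries of length >= {min_length}"
        )
    return queries, warnings


def _best_hit_per_query(hsps: Iterable[HSP]) -> dict[int, HSP]:
    """Best reference hit per query: highest score, then smallest subject
    index (plus strand before minus), then smallest reference coordinate."""
    best: dict[int, HSP] = {}
    for h in hsps:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (-h.score, h.subject_id, h.s_start, h.q_start)
        cur_key = (-cur.score, cur.subject_id, cur.s_start, cur.q_start)
        if key < cur_key:
            best[h.query_id] = h
    return best


def detect_random_mers(
    queries: Sequence[str],
    reference: Sequence[str] | str,
    align_params: AlignParams | None = None,
    support_fraction: float = 0.5,
    max_n: int = 8,
    min_aligned: int = 25,
) -> RandomMerCall:
    """Infer random-mer lengths from query alignments against a reference.

    Both strands of every reference sequence are searched (queries stay
    plus-strand).  Per aligned query the start offset (q_start - 1) and the
    unaligned tail (len - q_end) are recorded; a terminal random-mer is
    called when the modal value is in 1..``max_n`` and supported by at least
    ``support_fraction`` of aligned queries, else 0.
    """
    if isinstance(reference, str):
        reference = [reference]
    if not reference:
        raise ValueError("empty reference")
    subjects: list[str] = []
    for seq in reference:
        subjects.append(seq)
        subjects.append(revcomp(seq))
    params = align_params or REFERENCE_ALIGN_PARAMS
    hsps = find_hsps(list(queries), subjects, params)
    best = _best_hit_per_query(hsps)
    if len(best) < min_aligned:
        raise ValueError(
            f"insufficient reference support: {len(best)} aligned queries"
        )
    starts = Counter(h.q_start for h in best.values())
    tails = Counter(
        len(queries[qid]) - h.q_end for qid, h in best.items()
    )
    n_aligned = len(best)

    def _call(counter: Counter[int], offset: int) -> tuple[int, float]:
        top = max(counter.values())
        mode = min(v for v, c in counter.items() if c == top)
        fraction = counter[mode] / n_aligned
        value = mode - offset
        if 1 <= value <= max_n and fraction >= support_fraction:
            return value, fraction
        return 0, fraction

    five_n, five_frac = _call(starts, offset=1)
    three_n, three_frac = _call(tails, offset=0)
    return RandomMerCall(
        five_prime_n=five_n,
        three_prime_n=three_n,
        five_mode_fraction=five_frac,
        three_mode_fraction=three_frac,
        n_aligned=n_aligned,
    )
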