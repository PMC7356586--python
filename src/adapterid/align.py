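"""Ungapped seed-and-extend local alignment with BLAST-style coordinates.

The aligner finds exact ``word_size`` seeds between every query/subject pair,
extends them in both directions without gaps under an X-drop rule, trims each
extension back to its maximum-score extent and reports one HSP per maximal
segment.  Coordinates are 1-based inclusive, matching the conventions the
filter thresholds downstream were written against.  Plus strand only:
adapters appear in a fixed orientation in single-read data.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

__all__ = ["HSP", "AlignParams", "find_hsps", "revcomp"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HSP:
    """One ungapped local alignment between a query and a subject read.

    ``q_start``/``q_end`` and ``s_start``/``s_end`` are 1-based inclusive;
    ``aligned_seq`` is the query substring covered by the alignment.
    """

    query_id: int
    subject_id: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_seq: str
    mismatches: int
    score: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class AlignParams:
    """Aligner parameters.

    Defaults (word 7, match +1, mismatch -2, X-drop 6, min score 7) are
    calibrated so that 7-nt adapters — the shortest in circulation — are
    findable as bare exact seeds; chance alignments this floor admits are
    suppressed downstream by the consensus support guard.  ``xdrop=None``
    disables the drop-off and extends to the best extent over the full
    overlap.  Caps: ``max_hsps_per_pair`` limits HSPs per query-subject pair
    (the "two hits" rule: one slot for the adapter, one for a shared
    biological sequence); the per-query / per-subject caps are global.
    """

    word_size: int = 7
    match: int = 1
    penalty: int = 2
    xdrop: int | None = 6
    min_score: int = 7
    max_hsps_per_pair: int | None = None
    max_hits_per_query: int | None = None
    max_hits_per_subject: int | None = None

    def __post_init__(self) -> None:
        if self.word_size < 3:
            raise ValueError("word_size must be >= 3")
        if self.match <= 0 or self.penalty < 0:
            raise ValueError("match must be positive, penalty non-negative")


def _validate(seqs: Sequence[str], role: str) -> None:
    if not seqs:
        raise ValueError(f"no {role} sequences")
    for i, seq in enumerate(seqs):
        if not seq or set(seq) - set("ACGT"):
            raise ValueError(
                f"{role} sequence {i} contains characters outside ACGT"
            )


def _extend(
    q: str, s: str, i: int, j: int, w: int, match: int, penalty: int,
    xdrop: int | None,
) -> tuple[int, int]:
    """Extend an exact seed q[i:i+w] == s[j:j+w] left and right.

    Returns (left, right): the number of extra positions kept on each side of
    the seed at the maximum-score extent.  Because the score of an ungapped
    segment containing the seed separates into left + seed + right
    contributions, maximizing each side independently is globally optimal;
    strictly-greater updates keep the shortest maximal extent.
    """
    # right
    best_gain = 0
    gain = 0
    right = 0
    x, y = i + w, j + w
    k = 0
    while x + k < len(q) and y + k < len(s):
        gain += match if q[x + k] == s[y + k] else -penalty
        if gain > best_gain:
            best_gain = gain
            right = k + 1
        elif xdrop is not None and gain < best_gain - xdrop:
            break
        k += 1
    # left
    best_gain = 0
    gain = 0
    left = 0
    k = 1
    while i - k >= 0 and j - k >= 0:
        gain += match if q[i - k] == s[j - k] else -penalty
        if gain > best_gain:
            best_gain = gain
            left = k
        elif xdrop is not None and gain < best_gain - xdrop:
            break
        k += 1
    return left, right


def _pair_hsps(
    q: str, s: str, index: dict[str, list[int]], params: AlignParams
) -> list[tuple[int, int, int, int, int]]:
    """All merged HSPs for one query/subject pair.

    Returns tuples (q_start0, q_end0_exclusive, diag, score, mismatches).
    Overlapping extensions on the same diagonal are reduced to maximal-score
    representatives (tie: smaller q_start).
    """
    w = params.word_size
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    candidates: dict[tuple[int, int, int], tuple[int, int]] = {}
    for i in range(len(q) - w + 1):
        positions = index.get(q[i : i + w])
        if not positions:
            continue
        for j in positions:
            diag = j - i
            covered = False
            for a, b in by_diag[diag]:
                if a <= i and i + w <= b:
                    covered = True
                    break
            if covered:
                continue
            left, right = _extend(
                q, s, i, j, w, params.match, params.penalty, params.xdrop
            )
            qs, qe = i - left, i + w + right  # 0-based, end exclusive
            by_diag[diag].append((qs, qe))
            key = (diag, qs, qe)
            if key not in candidates:
                ss = qs + diag
                mism = sum(
                    1 for a, b in zip(q[qs:qe], s[ss : ss + (qe - qs)]) if a != b
                )
                score = params.match * (qe - qs - mism) - params.penalty * mism
                candidates[key] = (score, mism)
    # merge overlapping candidates on each diagonal: keep max score
    grouped: dict[int, list[tuple[int, int, int, int]]] = defaultdict(list)
    for (diag, qs, qe), (score, mism) in candidates.items():
        grouped[diag].append((qs, qe, score, mism))
    merged: list[tuple[int, int, int, int, int]] = []
    for diag, items in grouped.items():
        items.sort(key=lambda t: (-t[2], t[0], t[1]))
        kept: list[tuple[int, int, int, int]] = []
        for qs, qe, score, mism in items:
            if any(qs < k_qe and k_qs < qe for k_qs, k_qe, _, _ in kept):
                continue
            kept.append((qs, qe, score, mism))
        for qs, qe, score, mism in kept:
            merged.append((qs, qe, diag, score, mism))
    # overlap culling across diagonals: an HSP overlapping a higher-scoring
    # HSP on both the query and the subject interval is a shadow of it
    merged.sort(key=lambda t: (-t[3], t[0], t[0] + t[2]))
    result: list[tuple[int, int, int, int, int]] = []
    for qs, qe, diag, score, mism in merged:
        ss, se = qs + diag, qe + diag
        shadowed = any(
            qs < k_qe and k_qs < qe and ss < k_qe + k_d and k_qs + k_d < se
            for k_qs, k_qe, k_d, _, _ in result
        )
        if not shadowed:
            result.append((qs, qe, diag, score, mism))
    return result


def find_hsps(
    queries: Sequence[str], subjects: Sequence[str], params: AlignParams
) -> list[HSP]:
    """All HSPs between every query and subject, filtered and capped.

    Identical query/subject sequence pairs (the same read appearing in both
    sets) are skipped as self-matches.  HSPs below ``min_score`` are dropped;
    caps are then applied with the deterministic tie-break (score descending,
    then smaller start coordinate, then smaller partner index).
    """
    _validate(queries, "query")
    _validate(subjects, "subject")
    w = params.word_size
    indexes: list[dict[str, list[int]]] = []
    for s in subjects:
        idx: dict[str, list[int]] = defaultdict(list)
        for j in range(len(s) - w + 1):
            idx[s[j : j + w]].append(j)
        indexes.append(idx)
    hsps: list[HSP] = []
    for qi, q in enumerate(queries):
        if len(q) < w:
            continue
        for si, s in enumerate(subjects):
            if q == s or len(s) < w:
                continue
            for qs, qe, diag, score, mism in _pair_hsps(q, s, indexes[si], params):
                if score < params.min_score:
                    continue
                ss = qs + diag
                hsps.append(
                    HSP(
                        query_id=qi,
                        subject_id=si,
                        q_start=qs + 1,
                        q_end=qe,
                        s_start=ss + 1,
                        s_end=ss + (qe - qs),
                        aligned_seq=q[qs:qe],
                        mismatches=mism,
                        score=score,
                    )
                )
    if params.max_hsps_per_pair is not None:
        by_pair: dict[tuple[int, int], list[HSP]] = defaultdict(list)
        for h in hsps:
            by_pair[(h.query_id, h.subject_id)].append(h)
        kept: list[HSP] = []
        for pair_hsps in by_pair.values():
            pair_hsps.sort(key=lambda h: (-h.score, h.q_start, h.s_start))
            kept.extend(pair_hsps[: params.max_hsps_per_pair])
        hsps = kept
    if params.max_hits_per_query is not None:
        by_query: dict[int, list[HSP]] = defaultdict(list)
        for h in hsps:
            by_query[h.query_id].append(h)
        kept = []
        for query_hsps in by_query.values():
            query_hsps.sort(key=lambda h: (-h.score, h.q_start, h.subject_id))
            kept.extend(query_hsps[: params.max_hits_per_query])
        hsps = kept
    if params.max_hits_per_subject is not None:
        by_subject: dict[int, list[HSP]] = defaultdict(list)
        for h in hsps:
            by_subject[h.subject_id].append(h)
        kept = []
        for subject_hsps in by_subject.values():
            subject_hsps.sort(key=lambda h: (-h.score, h.s_start, h.query_id))
            kept.extend(subject_hsps[: params.max_hits_per_subject])
        hsps = kept
    hsps.sort(
        key=lambda h: (h.query_id, h.subject_id, -h.score, h.q_start, h.s_start)
    )
    return hsps


def dump_hsps(hsps: Sequence[HSP]) -> str:
    """Debug dump in BLAST outfmt-6-like tab-separated column order."""
    lines = []
    for h in hsps:
        ident = 100.0 * (h.length - h.mismatches) / h.length
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t{ident:.2f}\t{h.length}\t"
            f"{h.mismatches}\t0\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
            f"{h.s_end}\t{h.score}\t{h.aligned_seq}"
        )
    return "\n".join(lines)
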