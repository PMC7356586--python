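"""Brute-force ungapped alignment enumerator used as an independent oracle.

For every query/subject pair and every diagonal it enumerates all segment
extents around each exact word seed, scores them by direct mismatch
counting, and keeps the maximum-score minimal segment per seed; overlapping
segments on a diagonal are reduced to maximal-score representatives and the
same score floor, caps and tie-breaks as the production aligner are applied.
Only valid with ``xdrop=None`` (unbounded extension).
"""

from __future__ import annotations

from collections import defaultdict

from adapterid.align import AlignParams


def _score(q: str, s: str, qs: int, ss: int, length: int, match: int,
           penalty: int) -> tuple[int, int]:
    mism = sum(1 for k in range(length) if q[qs + k] != s[ss + k])
    return match * (length - mism) - penalty * mism, mism


def brute_force_hsps(queries, subjects, params: AlignParams):
    """All (query_id, subject_id, q_start, q_end, s_start, s_end, score)
    tuples, 1-based inclusive, matching find_hsps semantics."""
    assert params.xdrop is None, "oracle requires unbounded extension"
    w = params.word_size
    out = []
    for qi, q in enumerate(queries):
        for si, s in enumerate(subjects):
            if q == s:
                continue
            candidates = {}
            for diag in range(-(len(q) - w), len(s) - w + 1):
                # seed positions on this diagonal
                seeds = [
                    i
                    for i in range(max(0, -diag), min(len(q), len(s) - diag) - w + 1)
                    if q[i : i + w] == s[i + diag : i + diag + w]
                ]
                for i in seeds:
                    best = None
                    lo_min = max(0, -diag)
                    hi_max = min(len(q), len(s) - diag)
                    for qs in range(lo_min, i + 1):
                        for qe in range(i + w, hi_max + 1):
                            score, mism = _score(
                                q, s, qs, qs + diag, qe - qs,
                                params.match, params.penalty,
                            )
                            key = (-score, qe - qs, qs)
                            if best is None or key < best[0]:
                                best = (key, qs, qe, score, mism)
                    _, qs, qe, score, mism = best
                    candidates[(diag, qs, qe)] = (score, mism)
            grouped = defaultdict(list)
            for (diag, qs, qe), (score, mism) in candidates.items():
                grouped[diag].append((qs, qe, score, mism))
            merged = []
            for diag, items in grouped.items():
                items.sort(key=lambda t: (-t[2], t[0], t[1]))
                kept = []
                for qs, qe, score, mism in items:
                    if any(qs < b and a < qe for a, b, _, _ in kept):
                        continue
                    kept.append((qs, qe, score, mism))
                for qs, qe, score, mism in kept:
                    merged.append((qs, qe, diag, score))
            # cross-diagonal overlap culling, as in the implementation
            merged.sort(key=lambda t: (-t[3], t[0], t[0] + t[2]))
            culled = []
            for qs, qe, diag, score in merged:
                ss, se = qs + diag, qe + diag
                if any(
                    qs < b and a < qe and ss < b + d and a + d < se
                    for a, b, d, _ in culled
                ):
                    continue
                culled.append((qs, qe, diag, score))
            for qs, qe, diag, score in culled:
                if score < params.min_score:
                    continue
                out.append(
                    (qi, si, qs + 1, qe, qs + diag + 1, qe + diag, score)
                )
    # caps, mirroring the production tie-breaks
    if params.max_hsps_per_pair is not None:
        by_pair = defaultdict(list)
        for h in out:
            by_pair[(h[0], h[1])].append(h)
        out = []
        for group in by_pair.values():
            group.sort(key=lambda h: (-h[6], h[2], h[4]))
            out.extend(group[: params.max_hsps_per_pair])
    if params.max_hits_per_query is not None:
        by_query = defaultdict(list)
        for h in out:
            by_query[h[0]].append(h)
        out = []
        for group in by_query.values():
            group.sort(key=lambda h: (-h[6], h[2], h[1]))
            out.extend(group[: params.max_hits_per_query])
    out.sort(key=lambda h: (h[0], h[1], -h[6], h[2], h[4]))
    return out
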