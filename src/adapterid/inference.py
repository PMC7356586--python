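"""Adapter inference from collapsed single-read libraries.

The method rests on one observation: in a raw single-read library the 3'
adapter is the only subsequence shared, at a consistent read position, by
otherwise unrelated reads.  Collapsing the library, aligning abundant reads
against each other with an ungapped aligner, filtering the alignments by
start-position and length rules keyed on the median aligned length, and
taking a consensus of the surviving aligned sequences recovers the adapter
head without any prior knowledge of its sequence.

Three platform variants share this machinery: Illumina (3' adapter, optional
anchored 5' barcode found by prefix consensus), 454/Ion Torrent (5' and 3'
adapters assigned by modal query-start position), and SOLiD (colorspace reads
decoded to base space first).
"""

from __future__ import annotations

import hashlib
import math
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

from .align import HSP, AlignParams, find_hsps
from .sequence_io import (
    CollapsedRead,
    ColorRead,
    ColorspaceError,
    Read,
    collapse_reads,
    decode_colorspace,
    detect_trimmed,
    weighted_median_length,
)

__all__ = [
    "AdapterCall",
    "FilterThresholds",
    "NoAdapterEvidence",
    "LowComplexityLibraryError",
    "STATUS_OK",
    "STATUS_ALREADY_TRIMMED",
    "STATUS_NO_ADAPTER",
    "SOLID_STANDARD_ADAPTER",
    "is_homopolymer",
    "is_low_complexity",
    "detect_anchored_5p",
    "select_query_subject",
    "filter_alignments",
    "infer_3p_short",
    "infer_3p_long",
    "infer_illumina",
    "infer_dual",
    "infer_solid",
]

STATUS_OK = "ok"
STATUS_ALREADY_TRIMMED = "already_trimmed"
STATUS_NO_ADAPTER = "no_adapter_found"

#: Standard SOLiD 3' adapter; custom adapters are inferred the same way.
SOLID_STANDARD_ADAPTER = "CGCCTTGGCCGTACAGCAG"


class NoAdapterEvidence(ValueError):
    """No adapter evidence survives filtering or consensus; maps to a
    ``no_adapter_found`` result, never to a crash."""


class LowComplexityLibraryError(ValueError):
    """Every candidate read failed the complexity eligibility rules."""


@dataclass(frozen=True)
class AdapterCall:
    """Result of adapter inference for one library."""

    five_prime: str | None
    three_prime: str | None
    status: str
    evidence: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == STATUS_ALREADY_TRIMMED and (
            self.five_prime or self.three_prime
        ):
            raise ValueError("already_trimmed call cannot carry adapters")
        if self.status == STATUS_OK and not (self.five_prime or self.three_prime):
            raise ValueError("ok call must carry at least one adapter")


@dataclass
class FilterThresholds:
    """Numeric thresholds of the alignment filter cascade and consensus.

    All positions are 1-based BLAST-style coordinates; lengths in nt.
    ``min_frame_support`` is the minimum number of supporting alignment
    records the consensus groups must have before a call is made — it keeps
    sparse chance alignments in adapter-free libraries from being promoted to
    an adapter.
    """

    start_min: int = 5
    both_start_min: int = 15
    len_discard_le: int = 15
    long_read_len: int = 100
    long_median: int = 60
    long_both_start: int = 20
    mid_len_min: int = 10
    short_start_le: int = 15
    short_retain_lt: int = 15
    trunc_len: int = 20
    start_window: int = 3
    min_insert: int = 15
    min_frame_support: int = 5
    # the top frame of the short-adapter consensus must also hold this
    # fraction of all retained records; scattered chance 7-mers never do,
    # a true short adapter holds well over half
    short_support_fraction: float = 0.2
    # Optional guard on |median aligned length - median read length|; the
    # underlying rule is stated qualitatively only, so it is inactive unless
    # a threshold is supplied.  The observed difference is always logged.
    median_diff_max: int | None = None


def is_homopolymer(seq: str, max_fraction: float = 0.8) -> bool:
    """True when one base accounts for >= 80% of positions."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq)
    return max(counts.values()) / len(seq) >= max_fraction


def is_low_complexity(seq: str, min_entropy: float = 1.5) -> bool:
    """True when the Shannon entropy of overlapping dinucleotide
    frequencies falls below ``min_entropy`` bits.

    A dinucleotide repeat such as ACACAC... has two equiprobable
    dinucleotides and hence exactly 1 bit; random sequence approaches 4 bits.
    """
    if len(seq) < 2:
        return True
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    total = sum(counts.values())
    entropy = -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )
    return entropy < min_entropy


def detect_anchored_5p(
    collapsed: Sequence[CollapsedRead],
    top_n: int = 25,
    consensus_fraction: float = 0.6,
    k_max: int = 6,
    k_min: int = 3,
) -> str | None:
    """Detect a constant 5' barcode by k-mer prefix consensus.

    The k-prefix of each of the ``top_n`` most abundant unique reads is
    tallied for k = 6, 5, 4, 3 in order; the first k whose modal prefix
    reaches the consensus fraction wins.  Returns None when no k succeeds.

    Only one representative per distinct ``2*k_max``-nt prefix is taken
    while walking the ranking: a true anchored barcode is a shared prefix
    followed by *diverse* sequence, whereas near-duplicate reads of one
    over-abundant species share their whole prefix and must not cast more
    than one vote.  Count ties are ordered by a content hash rather than
    lexicographically — in a library of all-unique reads an alphabetical
    order would hand the detector 25 reads that share a prefix by
    construction.
    """
    ordered = sorted(
        collapsed,
        key=lambda c: (-c.count, hashlib.sha256(c.seq.encode()).hexdigest()),
    )
    top: list[str] = []
    seen_contexts: set[str] = set()
    for c in ordered:
        context = c.seq[: 2 * k_max]
        if context in seen_contexts:
            continue
        seen_contexts.add(context)
        top.append(c.seq)
        if len(top) >= top_n:
            break
    for k in range(k_max, k_min - 1, -1):
        prefixes = [seq[:k] for seq in top if len(seq) >= k]
        if not prefixes:
            continue
        counts = Counter(prefixes)
        best = min(
            (p for p, c in counts.items() if c == max(counts.values()))
        )
        if counts[best] / len(prefixes) >= consensus_fraction:
            return best
    return None


def select_query_subject(
    collapsed: Sequence[CollapsedRead],
    n_query: int,
    n_subject: int,
    thresholds: FilterThresholds | None = None,
    distinct_prefix: int | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Select query and subject sequences by walking the abundance ranking.

    Sequences containing N, shorter than the minimum insert length, or
    failing the homopolymer / low-complexity filters are skipped.  Queries
    are the first ``n_query`` eligible sequences and subjects the first
    ``n_subject`` (queries are a subset of subjects; identical-sequence
    self-pairs are skipped by the aligner).  Returns (queries, subjects,
    warnings).

    ``distinct_prefix`` (used in Illumina mode) keeps only the first
    sequence per distinct prefix of that length: near-duplicate reads of
    one over-abundant species — identical except for post-adapter content —
    would otherwise fill the selection with copies of the same biology and
    let shared insert sequence outvote the adapter consensus.  It must stay
    off for 454/Ion Torrent reads, which legitimately all share their 5'
    adapter prefix.
    """
    th = thresholds or FilterThresholds()
    eligible: list[str] = []
    seen_prefixes: set[str] = set()
    needed = max(n_query, n_subject)
    for c in collapsed:
        seq = c.seq
        if len(seq) < th.min_insert or "N" in seq:
            continue
        if is_homopolymer(seq) or is_low_complexity(seq):
            continue
        if distinct_prefix is not None:
            prefix = seq[:distinct_prefix]
            if prefix in seen_prefixes:
                continue
            seen_prefixes.add(prefix)
        eligible.append(seq)
        if len(eligible) >= needed:
            break
    if not eligible:
        raise LowComplexityLibraryError("library too low-complexity")
    warnings: list[str] = []
    if len(eligible) < n_query:
        warnings.append(
            f"only {len(eligible)} eligible sequences for {n_query} queries"
        )
    if len(eligible) < n_subject:
        warnings.append(
            f"only {len(eligible)} eligible sequences for {n_subject} subjects"
        )
    return eligible[:n_query], eligible[:n_subject], warnings


def filter_alignments(
    hsps: Sequence[HSP],
    raw_read_median: float,
    thresholds: FilterThresholds | None = None,
) -> list[HSP]:
    """Remove alignments that reflect shared biology rather than adapters.

    The branch is keyed on the median aligned length m, computed once over
    the input HSPs before any removal:

    * m > 20: drop query or subject start < 5 (likely truncated adapters);
      drop both starts < 15 (the minimum small-RNA insert is ~15, so a true
      adapter starts at >= 16 in at least one of the pair); drop aligned
      length <= 15; and for long-read libraries (read median > 100,
      m > 60) additionally drop both starts < 20 with length < 60.
    * 10 <= m <= 20: the two start filters above, plus drop length < 10.
    * m < 10: drop query or subject start <= 15.

    Raises :class:`NoAdapterEvidence` when nothing survives.
    """
    th = thresholds or FilterThresholds()
    if not hsps:
        raise NoAdapterEvidence("no alignments to filter")
    m = statistics.median(h.length for h in hsps)
    survivors: list[HSP] = []
    if m > th.trunc_len:
        for h in hsps:
            if h.q_start < th.start_min or h.s_start < th.start_min:
                continue
            if h.q_start < th.both_start_min and h.s_start < th.both_start_min:
                continue
            if h.length <= th.len_discard_le:
                continue
            if (
                raw_read_median > th.long_read_len
                and m > th.long_median
                and h.q_start < th.long_both_start
                and h.s_start < th.long_both_start
                and h.length < th.long_median
            ):
                continue
            survivors.append(h)
    elif m >= th.mid_len_min:
        for h in hsps:
            if h.q_start < th.start_min or h.s_start < th.start_min:
                continue
            if h.q_start < th.both_start_min and h.s_start < th.both_start_min:
                continue
            if h.length < th.mid_len_min:
                continue
            survivors.append(h)
    else:
        for h in hsps:
            if h.q_start <= th.short_start_le or h.s_start <= th.short_start_le:
                continue
            survivors.append(h)
    if not survivors:
        raise NoAdapterEvidence("no adapter evidence survives filtering")
    return survivors


def _left_extends(a: str, b: str, max_shift: int, min_overlap: int = 7) -> bool:
    """True when ``b`` equals ``a`` with up to ``max_shift`` leading bases
    removed (exact overlap of at least ``min_overlap``)."""
    for j in range(1, max_shift + 1):
        n = min(len(a) - j, len(b))
        if n >= min_overlap and a[j : j + n] == b[:n]:
            return True
    return False


def _is_shifted_copy(a: str, b: str, max_shift: int, min_overlap: int = 7) -> bool:
    """True when one sequence is the other offset by up to ``max_shift``
    bases with an exact overlap of at least ``min_overlap``."""
    return _left_extends(a, b, max_shift, min_overlap) or _left_extends(
        b, a, max_shift, min_overlap
    )


def _longest_common_prefix(a: str, b: str) -> str:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return a[:i]
    return a[:n]


def _build_frames(
    retained: Sequence[str] | Counter,
) -> list[tuple[str, int, list[str]]]:
    """Group alphabetically sorted sequences into length-variant frames.

    A frame is a maximal run of the sorted unique sequences whose first
    (shortest, since a prefix sorts before its extensions) member is a prefix
    of every member.  Returns (head, total record count, members) sorted by
    count descending, ties alphabetical by head.
    """
    counts = retained if isinstance(retained, Counter) else Counter(retained)
    frames: list[tuple[str, int, list[str]]] = []
    head: str | None = None
    members: list[str] = []
    total = 0
    for seq in sorted(counts):
        if head is not None and seq.startswith(head):
            members.append(seq)
            total += counts[seq]
        else:
            if head is not None:
                frames.append((head, total, members))
            head = seq
            members = [seq]
            total = counts[seq]
    if head is not None:
        frames.append((head, total, members))
    frames.sort(key=lambda f: (-f[1], f[0]))
    return frames


def infer_3p_short(
    hsps: Sequence[HSP], thresholds: FilterThresholds | None = None
) -> tuple[str, dict[str, Any]]:
    """Consensus for short adapters (median aligned length <= 10).

    Short adapters read through at varying depths, so the aligned sequences
    are length variants of one another; sorting them alphabetically groups
    the variants into frames.  With a single frame the most common sequence
    wins; with several, the longest common prefix of the shortest members of
    the two best-supported frames is the adapter head.
    """
    th = thresholds or FilterThresholds()
    retained = [h.aligned_seq for h in hsps if len(h.aligned_seq) < th.short_retain_lt]
    if not retained:
        raise NoAdapterEvidence("no short aligned sequences retained")
    frames = _build_frames(retained)
    evidence: dict[str, Any] = {
        "n_retained": len(retained),
        "n_frames": len(frames),
        "top_frame_counts": [f[1] for f in frames[:5]],
    }
    if frames[0][1] < max(
        th.min_frame_support, th.short_support_fraction * len(retained)
    ):
        raise NoAdapterEvidence(
            "top frame support below minimum; likely chance alignments"
        )
    # minority frames are chance flank-extension artifacts unless their
    # support is comparable to the dominant frame's
    major = [
        f for f in frames
        if f[1] >= max(th.min_frame_support, 0.25 * frames[0][1])
    ]
    evidence["n_major_frames"] = len(major)
    if len(major) == 1:
        members = set(major[0][2])
        counts = Counter(s for s in retained if s in members)
        best = min(
            (s for s, c in counts.items() if c == max(counts.values())),
            key=lambda s: (len(s), s),
        )
        return best, evidence
    a = min(major[0][2], key=lambda s: (len(s), s))
    b = min(major[1][2], key=lambda s: (len(s), s))
    motif = _longest_common_prefix(a, b)
    evidence["frame_heads"] = [a, b]
    if len(motif) < 3:
        raise NoAdapterEvidence("inconsistent short-adapter evidence")
    return motif, evidence


def infer_3p_long(
    hsps: Sequence[HSP], thresholds: FilterThresholds | None = None
) -> tuple[str, dict[str, Any]]:
    """Consensus for ordinary adapters (median aligned length > 10).

    Within a query, true adapter alignments share the query start position
    (the adapter sits right after that query's insert); alignments are kept
    only within a small window after the modal start, which also absorbs
    randomized-junction N-mers.  Aligned sequences are truncated to 20 nt —
    only the adapter head matters for trimming — pooled and counted.
    """
    th = thresholds or FilterThresholds()
    by_query: dict[int, list[HSP]] = defaultdict(list)
    for h in hsps:
        by_query[h.query_id].append(h)
    pooled: Counter[str] = Counter()
    modal_starts: dict[int, int] = {}
    for qid, group in by_query.items():
        starts = Counter(h.q_start for h in group)
        top = max(starts.values())
        mode = min(s for s, c in starts.items() if c == top)
        modal_starts[qid] = mode
        for h in group:
            if mode <= h.q_start <= mode + th.start_window:
                pooled[h.aligned_seq[: th.trunc_len]] += 1
    if not pooled:
        raise NoAdapterEvidence("no alignments at consistent query starts")
    # length variants of one adapter head (differing read-through depth or
    # flank luck) are prefixes of each other: frame-group them so that the
    # dominance comparison is between distinct heads, not between variants
    frames = _build_frames(pooled)
    # Consolidate shifted copies: a frame whose head is the dominant head
    # offset by a few bases is evidence for the same adapter, not a rival —
    # alignments that started inside the adapter (head-damaged partners)
    # produce a systematic left-truncated copy, chance flank extensions a
    # left-extended one.  The merged group is represented by the frame that
    # extends furthest left among those with at least half the group's
    # maximum support: systematic truncated copies can rival the true head
    # in count, whereas chance left-extensions (split across four possible
    # flank bases) never reach parity.
    top_head = min(frames[0][2], key=lambda s: (len(s), s))
    group: list[tuple[str, int, list[str]]] = [frames[0]]
    rest: list[tuple[str, int, list[str]]] = []
    for frame in frames[1:]:
        head = min(frame[2], key=lambda s: (len(s), s))
        if _is_shifted_copy(top_head, head, th.start_window):
            group.append(frame)
        else:
            rest.append(frame)
    if len(group) > 1:
        max_count = max(f[1] for f in group)
        candidates = [f for f in group if f[1] >= 0.5 * max_count]

        def _left_rank(frame: tuple[str, int, list[str]]) -> int:
            head = min(frame[2], key=lambda s: (len(s), s))
            return sum(
                1
                for other in candidates
                if other is not frame
                and _left_extends(
                    head, min(other[2], key=lambda s: (len(s), s)),
                    th.start_window,
                )
            )

        representative = max(candidates, key=lambda f: (_left_rank(f), f[1]))
    else:
        representative = group[0]
    merged = (representative[0], sum(f[1] for f in group), representative[2])
    frames = sorted([merged] + rest, key=lambda f: (-f[1], f[0]))
    evidence: dict[str, Any] = {
        "modal_query_starts": dict(sorted(modal_starts.items())),
        "top_counts": [f[1] for f in frames[:5]],
        "n_pooled": sum(pooled.values()),
    }
    if frames[0][1] < th.min_frame_support:
        raise NoAdapterEvidence(
            "top consensus support below minimum; likely chance alignments"
        )
    if len(frames) == 1 or frames[0][1] >= 2 * frames[1][1]:
        members = frames[0][2]
        best = min(
            (m for m in members if pooled[m] == max(pooled[m2] for m2 in members)),
            key=lambda s: (len(s), s),
        )
        return best, evidence
    a = min(frames[0][2], key=lambda s: (len(s), s))
    b = min(frames[1][2], key=lambda s: (len(s), s))
    motif = _longest_common_prefix(a, b)
    evidence["top_sequences"] = [a, b]
    if len(motif) < 3:
        raise NoAdapterEvidence("inconsistent long-adapter evidence")
    return motif, evidence


def _default_align_params(params: AlignParams | None) -> AlignParams:
    if params is None:
        return AlignParams(max_hsps_per_pair=2)
    return params


def infer_illumina(
    reads: Iterable[Read | str],
    n_query: int = 50,
    n_subject: int = 200,
    thresholds: FilterThresholds | None = None,
    align_params: AlignParams | None = None,
    top_n_anchored: int = 25,
    consensus_fraction: float = 0.6,
    modal_length_fraction: float = 0.90,
) -> AdapterCall:
    """Full inference pipeline for Illumina-style libraries.

    Steps: collapse; already-trimmed check on the read-length distribution;
    anchored 5' barcode by prefix consensus; query/subject selection; ungapped
    all-vs-all alignment (two hits per pair); the median-keyed filter cascade;
    and the short- or long-adapter consensus, dispatched on the median length
    of the filtered alignments.
    """
    th = thresholds or FilterThresholds()
    collapsed = reads if isinstance(reads, list) and reads and isinstance(
        reads[0], CollapsedRead
    ) else collapse_reads(reads)
    total = sum(c.count for c in collapsed)
    evidence: dict[str, Any] = {"n_reads": total, "n_unique": len(collapsed)}
    if detect_trimmed(collapsed, total, modal_length_fraction):
        evidence["reason"] = "variable read-length distribution"
        return AdapterCall(None, None, STATUS_ALREADY_TRIMMED, evidence)
    five = detect_anchored_5p(
        collapsed, top_n=top_n_anchored, consensus_fraction=consensus_fraction
    )
    if five is not None:
        # a prefix-consensus barcode sits at a fixed read position, unlike a
        # dual-platform 5' adapter; the trimmer strips it as a prefix
        evidence["five_prime_anchored"] = True
    queries, subjects, warnings = select_query_subject(
        collapsed, n_query, n_subject, th, distinct_prefix=th.trunc_len
    )
    if warnings:
        evidence["warnings"] = warnings
    params = _default_align_params(align_params)
    hsps = find_hsps(queries, subjects, params)
    evidence["n_hsps"] = len(hsps)
    three: str | None = None
    if hsps:
        raw_median = weighted_median_length(collapsed)
        evidence["median_hsp_length"] = float(
            statistics.median(h.length for h in hsps)
        )
        evidence["median_read_length"] = raw_median
        evidence["median_length_difference"] = abs(
            evidence["median_hsp_length"] - raw_median
        )
        try:
            survivors = filter_alignments(hsps, raw_median, th)
            evidence["n_hsps_filtered"] = len(survivors)
            m = statistics.median(h.length for h in survivors)
            evidence["median_filtered_length"] = float(m)
            if (
                th.median_diff_max is not None
                and evidence["median_length_difference"] > th.median_diff_max
            ):
                raise NoAdapterEvidence(
                    "aligned/read median length difference out of range"
                )
            if m <= 10:
                three, cons_ev = infer_3p_short(survivors, th)
            else:
                three, cons_ev = infer_3p_long(survivors, th)
            evidence.update(cons_ev)
        except NoAdapterEvidence as exc:
            evidence["no_adapter_reason"] = str(exc)
    status = STATUS_OK if (five or three) else STATUS_NO_ADAPTER
    return AdapterCall(five, three, status, evidence)


def infer_dual(
    reads: Iterable[Read | str],
    n_query: int = 15,
    n_subject: int = 100,
    thresholds: FilterThresholds | None = None,
    align_params: AlignParams | None = None,
    five_prime_start_max: int = 6,
) -> AdapterCall:
    """Inference for 454 / Ion Torrent libraries carrying both adapters.

    Aligned sequences (truncated to 20 nt) are pooled; the two most frequent
    are the adapter candidates, and the one whose supporting alignments have
    a modal query start within 1-6 is the 5' adapter (it sits at the read
    start, give or take 5'-end degradation); the other is the 3' adapter.
    """
    th = thresholds or FilterThresholds()
    collapsed = collapse_reads(reads)
    evidence: dict[str, Any] = {
        "n_reads": sum(c.count for c in collapsed),
        "n_unique": len(collapsed),
    }
    queries, subjects, warnings = select_query_subject(
        collapsed, n_query, n_subject, th
    )
    if warnings:
        evidence["warnings"] = warnings
    params = _default_align_params(align_params)
    hsps = find_hsps(queries, subjects, params)
    evidence["n_hsps"] = len(hsps)
    pooled: dict[str, list[HSP]] = defaultdict(list)
    for h in hsps:
        pooled[h.aligned_seq[: th.trunc_len]].append(h)
    ranked = sorted(pooled.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    evidence["top_counts"] = [len(v) for _, v in ranked[:5]]
    if len(ranked) < 2 or len(ranked[1][1]) < th.min_frame_support:
        evidence["no_adapter_reason"] = "fewer than two supported candidates"
        return AdapterCall(None, None, STATUS_NO_ADAPTER, evidence)
    candidates = ranked[:2]
    modal_starts: list[int] = []
    for seq, support in candidates:
        starts = Counter(h.q_start for h in support)
        top = max(starts.values())
        modal_starts.append(min(s for s, c in starts.items() if c == top))
    evidence["candidate_modal_starts"] = {
        seq: start for (seq, _), start in zip(candidates, modal_starts)
    }
    in_window = [1 <= s <= five_prime_start_max for s in modal_starts]
    if sum(in_window) != 1:
        evidence["no_adapter_reason"] = (
            "query-start rule did not separate a 5' from a 3' candidate"
        )
        return AdapterCall(None, None, STATUS_NO_ADAPTER, evidence)
    if in_window[0]:
        five, three = candidates[0][0], candidates[1][0]
    else:
        five, three = candidates[1][0], candidates[0][0]
    return AdapterCall(five, three, STATUS_OK, evidence)


def infer_solid(
    color_reads: Iterable[ColorRead],
    max_decode_failures: float = 0.10,
    **kwargs: Any,
) -> AdapterCall:
    """Inference for SOLiD colorspace libraries.

    Reads are decoded to base space and the Illumina pipeline is applied to
    the decoded library; the evidence records whether the call matches the
    standard SOLiD adapter.  Trimming is then performed in color space by
    encoding the called adapter.
    """
    decoded: list[Read] = []
    failures = 0
    total = 0
    for cread in color_reads:
        total += 1
        try:
            decoded.append(decode_colorspace(cread))
        except ColorspaceError:
            failures += 1
    if total == 0:
        raise ValueError("empty library")
    if failures / total > max_decode_failures:
        raise ColorspaceError("corrupt colorspace input")
    call = infer_illumina(decoded, **kwargs)
    evidence = dict(call.evidence)
    evidence["decode_failures"] = failures
    evidence["standard_solid_adapter"] = SOLID_STANDARD_ADAPTER
    evidence["matches_standard_adapter"] = bool(
        call.three_prime
        and (
            SOLID_STANDARD_ADAPTER.startswith(call.three_prime)
            or call.three_prime.startswith(SOLID_STANDARD_ADAPTER)
        )
    )
    return replace(call, evidence=evidence)
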