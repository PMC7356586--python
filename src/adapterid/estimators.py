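"""Scikit-learn style estimators wrapping the inference pipelines.

``AdapterFinder`` is a transformer: ``fit`` learns the adapter call from a
library and ``transform`` trims reads with the learned adapters, so it
composes with sklearn pipelines and model selection.  ``RandomMerDetector``
does the same for terminal random N-mers.  The module-level ``infer_*``
functions in :mod:`adapterid.inference` remain the functional interface.
"""

from __future__ import annotations

from typing import Any, Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .align import AlignParams
from .inference import (
    AdapterCall,
    FilterThresholds,
    infer_dual,
    infer_illumina,
    infer_solid,
)
from .randmer import RandomMerCall, detect_random_mers, select_randommer_queries
from .sequence_io import ColorRead, Read, collapse_reads, decode_colorspace
from .trim import TrimStats, trim_library

__all__ = ["AdapterFinder", "RandomMerDetector"]


def _as_reads(X: Iterable[Any]) -> list[Read]:
    reads: list[Read] = []
    for i, item in enumerate(X):
        if isinstance(item, Read):
            reads.append(item)
        elif isinstance(item, ColorRead):
            reads.append(decode_colorspace(item))
        elif isinstance(item, str):
            reads.append(Read(id=f"r{i}", seq=item.upper().replace("U", "T")))
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as a read")
    if not reads:
        raise ValueError("empty library")
    return reads


class AdapterFinder(BaseEstimator, TransformerMixin):
    """Learn the adapter content of a single-read library and trim it.

    Parameters
    ----------
    platform : one of "ILLUMINA", "ION_TORRENT", "454", "SOLID"
        Selects the inference variant: 3'-adapter (+ anchored barcode)
        consensus for Illumina/SOLiD, dual 5'/3' assignment for the others.
    n_query, n_subject : int or None
        Number of collapsed reads aligned as queries/subjects; defaults are
        50/200 (Illumina/SOLiD) and 15/100 (454/Ion Torrent).
    thresholds : FilterThresholds or None
        Filter-cascade and consensus thresholds.
    align_params : AlignParams or None
        Aligner settings; default word 7, two HSPs per query-subject pair.
    error_rate, min_overlap
        Trimming tolerance used by :meth:`transform`.

    Attributes
    ----------
    call_ : AdapterCall
    five_prime_, three_prime_ : str or None
    status_ : str
    evidence_ : dict
    """

    def __init__(
        self,
        platform: str = "ILLUMINA",
        n_query: int | None = None,
        n_subject: int | None = None,
        thresholds: FilterThresholds | None = None,
        align_params: AlignParams | None = None,
        error_rate: float = 0.1,
        min_overlap: int = 3,
    ) -> None:
        self.platform = platform
        self.n_query = n_query
        self.n_subject = n_subject
        self.thresholds = thresholds
        self.align_params = align_params
        self.error_rate = error_rate
        self.min_overlap = min_overlap

    def fit(self, X: Iterable[Any], y: Any = None) -> "AdapterFinder":
        platform = self.platform.upper()
        X = list(X)
        if platform in ("ILLUMINA", "SOLID"):
            if platform == "SOLID" and any(isinstance(x, ColorRead) for x in X):
                call = infer_solid(
                    X,
                    n_query=self.n_query or 50,
                    n_subject=self.n_subject or 200,
                    thresholds=self.thresholds,
                    align_params=self.align_params,
                )
            else:
                call = infer_illumina(
                    _as_reads(X),
                    n_query=self.n_query or 50,
                    n_subject=self.n_subject or 200,
                    thresholds=self.thresholds,
                    align_params=self.align_params,
                )
        elif platform in ("ION_TORRENT", "454"):
            call = infer_dual(
                _as_reads(X),
                n_query=self.n_query or 15,
                n_subject=self.n_subject or 100,
                thresholds=self.thresholds,
                align_params=self.align_params,
            )
        else:
            raise ValueError(f"unknown platform {self.platform!r}")
        self.call_ = call
        self.five_prime_ = call.five_prime
        self.three_prime_ = call.three_prime
        self.status_ = call.status
        self.evidence_ = call.evidence
        return self

    def transform(self, X: Iterable[Any]) -> list[Read]:
        """Trim the learned adapters off every read."""
        if not hasattr(self, "call_"):
            raise ValueError("AdapterFinder is not fitted yet")
        reads = _as_reads(X)
        trimmed, self.trim_stats_ = trim_library(
            reads, self.call_, self.error_rate, self.min_overlap
        )
        return trimmed


class RandomMerDetector(BaseEstimator, TransformerMixin):
    """Detect terminal random N-mers of adapter-trimmed reads.

    Requires a reference sequence; abundant reads of length >= 29 are
    aligned against both reference strands, and the modal alignment start
    offset / unaligned tail length give the 5' and 3' N-mer lengths.

    Attributes
    ----------
    call_ : RandomMerCall
    five_prime_n_, three_prime_n_ : int
    """

    def __init__(
        self,
        reference: str | Sequence[str] | None = None,
        n_query: int = 750,
        min_query_length: int = 29,
        support_fraction: float = 0.5,
        max_n: int = 8,
        min_aligned: int = 25,
        align_params: AlignParams | None = None,
    ) -> None:
        self.reference = reference
        self.n_query = n_query
        self.min_query_length = min_query_length
        self.support_fraction = support_fraction
        self.max_n = max_n
        self.min_aligned = min_aligned
        self.align_params = align_params

    def fit(self, X: Iterable[Any], y: Any = None) -> "RandomMerDetector":
        if self.reference is None:
            raise ValueError("RandomMerDetector requires a reference")
        collapsed = collapse_reads(_as_reads(X))
        queries, self.warnings_ = select_randommer_queries(
            collapsed, n_query=self.n_query, min_length=self.min_query_length
        )
        self.call_ = detect_random_mers(
            queries,
            self.reference,
            align_params=self.align_params,
            support_fraction=self.support_fraction,
            max_n=self.max_n,
            min_aligned=self.min_aligned,
        )
        self.five_prime_n_ = self.call_.five_prime_n
        self.three_prime_n_ = self.call_.three_prime_n
        return self

    def transform(self, X: Iterable[Any]) -> list[Read]:
        """Strip the detected N-mers off both read termini."""
        if not hasattr(self, "call_"):
            raise ValueError("RandomMerDetector is not fitted yet")
        n5, n3 = self.five_prime_n_, self.three_prime_n_
        out: list[Read] = []
        for read in _as_reads(X):
            end = len(read.seq) - n3
            if end - n5 < 1:
                out.append(read)
                continue
            out.append(
                Read(
                    read.id,
                    read.seq[n5:end],
                    read.qual[n5:end] if read.qual else None,
                )
            )
        return out
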