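"""Synthetic single-read library simulator with exhaustive ground truth.

Every platform read layout is generated from explicit parts —

    [5' adapter (454/Ion Torrent)] [barcode] [5' N-mer] insert [3' N-mer]
    [3' adapter] [filler]

— truncated to the fixed machine read length for Illumina/SOLiD or emitted
at natural length for 454/Ion Torrent.  Insert abundances follow a Zipf law
over a finite species pool, mimicking the skewed abundance spectrum of small
RNA libraries that makes read collapsing informative.  The ground truth
records every part of every read, so each read can be reconstructed
byte-exactly from its truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

from .sequence_io import ColorRead, Read, encode_colorspace

__all__ = [
    "SimConfig",
    "ReadTruth",
    "LibraryTruth",
    "simulate_reference",
    "simulate_library",
    "encode_colorspace",
]

_BASES = np.array(list("ACGT"))

PLATFORMS = ("ILLUMINA", "ION_TORRENT", "454", "SOLID")
DEGRADATION_MODELS = ("none", "low", "homogeneous", "heterogeneous")

#: Platforms whose output is a fixed machine read length (pad/truncate).
_FIXED_LENGTH = {"ILLUMINA", "SOLID"}


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    ``intact_fraction`` is the share of reads whose 3' adapter is planted
    unmodified; the remainder is modified according to
    ``degradation_model``:

    * ``none`` — nothing is modified (intact_fraction must be 1).
    * ``low`` — like heterogeneous but restricted to a small minority
      (intact_fraction must be >= 0.95).
    * ``homogeneous`` — one fixed substitution, drawn once per library,
      applied to every modified copy.
    * ``heterogeneous`` — per-read modifications diverse in size and type:
      60% tail truncation to a uniform shorter length, 25% one or two
      random substitutions, 15% both.  Truncation dominates because the
      main real-world cause of non-intact 3' adapters is the read running
      out before the adapter ends; substitution multiplicity is kept at
      realistic sequencing-error levels.
    """

    platform: str = "ILLUMINA"
    n_reads: int = 10_000
    read_length: int = 50
    adapter_3p: str | None = "TGGAATTCTCGGGTGCCAAGG"
    adapter_5p: str | None = None
    barcode: str | None = None
    random_mer_5p: int = 0
    random_mer_3p: int = 0
    insert_len: tuple[int, int] = (18, 26)
    intact_fraction: float = 1.0
    degradation_model: str = "none"
    overrepresented_insert: tuple[str, float] | None = None
    seed: int = 0
    # abundance model (small-RNA-like skew) and 5'-adapter degradation
    n_species: int = 2000
    zipf_exponent: float = 1.1
    five_prime_degraded_fraction: float = 0.0
    five_prime_min_suffix: int = 12
    primer_base: str = "T"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.degradation_model not in DEGRADATION_MODELS:
            raise ValueError(
                f"unknown degradation model {self.degradation_model!r}"
            )
        if not 0.0 <= self.intact_fraction <= 1.0:
            raise ValueError("intact_fraction must be in [0, 1]")
        if self.degradation_model == "none" and self.intact_fraction < 1.0:
            raise ValueError(
                "degradation_model 'none' requires intact_fraction == 1"
            )
        if self.degradation_model == "low" and self.intact_fraction < 0.95:
            raise ValueError(
                "degradation_model 'low' requires intact_fraction >= 0.95"
            )
        lo, hi = self.insert_len
        if lo < 1 or hi < lo:
            raise ValueError("invalid insert length range")
        fixed_overhead = (
            len(self.barcode or "") + self.random_mer_5p + self.random_mer_3p
        )
        if self.platform in _FIXED_LENGTH and lo + fixed_overhead > self.read_length:
            raise ValueError(
                "insert range incompatible with read_length: minimum insert "
                "plus barcode and random-mers exceeds the machine read length"
            )


@dataclass(frozen=True)
class ReadTruth:
    """Per-read ground truth; concatenating the parts (then truncating to
    the machine read length on fixed-length platforms) reproduces the read."""

    read_id: str
    five_prime_part: str
    barcode_part: str
    nmer5_part: str
    insert: str
    nmer3_part: str
    adapter_3p_part: str
    filler_part: str
    intact: bool
    insert_start: int  # 1-based position of the insert in the emitted read
    insert_end: int  # 1-based inclusive; 0/-1 pair when fully truncated away

    def assembled(self) -> str:
        return (
            self.five_prime_part
            + self.barcode_part
            + self.nmer5_part
            + self.insert
            + self.nmer3_part
            + self.adapter_3p_part
            + self.filler_part
        )


@dataclass
class LibraryTruth:
    """Ground truth for a simulated library."""

    config: SimConfig
    reads: list[ReadTruth]
    n_intact: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": asdict(self.config),
            "n_intact": self.n_intact,
            "reads": [asdict(r) for r in self.reads],
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(length: int, seed: int) -> str:
    """An i.i.d. uniform random reference sequence; deterministic per seed."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    return _random_seq(rng, length)


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    choices = [b for b in "ACGT" if b != old]
    new = choices[int(rng.integers(0, 3))]
    return seq[:pos] + new + seq[pos + 1 :]


def _degrade_3p(
    adapter: str, model: str, rng: np.random.Generator,
    homogeneous_sub: tuple[int, str] | None,
) -> str:
    """A modified 3'-adapter copy guaranteed to differ from the original."""
    if model == "homogeneous":
        pos, base = homogeneous_sub  # type: ignore[misc]
        return adapter[:pos] + base + adapter[pos + 1 :]
    # heterogeneous (also used by "low" for its small modified minority)
    u = rng.random()
    copy = adapter
    if u < 0.60:
        copy = copy[: int(rng.integers(0, len(adapter)))]
    elif u < 0.85:
        for _ in range(int(rng.integers(1, 3))):
            if copy:
                copy = _substitute(copy, int(rng.integers(0, len(copy))), rng)
    else:
        copy = copy[: int(rng.integers(0, len(adapter)))]
        if copy:
            copy = _substitute(copy, int(rng.integers(0, len(copy))), rng)
    if copy == adapter:  # safety net: guarantee a modification
        copy = adapter[:-1]
    return copy


def _species_pool(
    cfg: SimConfig, rng: np.random.Generator, reference: str | None
) -> tuple[list[str], np.ndarray]:
    """Insert species and their Zipf-skewed sampling probabilities."""
    lo, hi = cfg.insert_len
    lengths = rng.integers(lo, hi + 1, size=cfg.n_species)
    species: list[str] = []
    if reference is not None:
        ref_fwd = reference
        from .align import revcomp

        ref_rev = revcomp(reference)
        for length in lengths:
            strand = ref_fwd if rng.random() < 0.5 else ref_rev
            start = int(rng.integers(0, len(strand) - int(length) + 1))
            species.append(strand[start : start + int(length)])
    else:
        for length in lengths:
            species.append(_random_seq(rng, int(length)))
    weights = np.arange(1, cfg.n_species + 1, dtype=float) ** (
        -cfg.zipf_exponent
    )
    weights /= weights.sum()
    return species, weights


def simulate_library(
    cfg: SimConfig, reference: str | Sequence[str] | None = None
) -> tuple[list[Read] | list[ColorRead], LibraryTruth]:
    """Simulate a library under ``cfg``; deterministic per seed.

    Returns the reads (colorspace-encoded for SOLID) and the ground truth.
    """
    if isinstance(reference, (list, tuple)):
        reference = "".join(reference)
    rng = np.random.default_rng(cfg.seed)
    species, weights = _species_pool(cfg, rng, reference)

    n = cfg.n_reads
    species_idx = rng.choice(len(species), size=n, p=weights)
    n_intact = int(round(cfg.intact_fraction * n))
    modified = np.zeros(n, dtype=bool)
    if cfg.degradation_model != "none" and n_intact < n:
        modified_idx = rng.choice(n, size=n - n_intact, replace=False)
        modified[modified_idx] = True
    homogeneous_sub: tuple[int, str] | None = None
    if cfg.degradation_model == "homogeneous" and cfg.adapter_3p:
        pos = int(rng.integers(0, len(cfg.adapter_3p)))
        old = cfg.adapter_3p[pos]
        base = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
        homogeneous_sub = (pos, base)

    overrep_seq: str | None = None
    overrep_mask = np.zeros(n, dtype=bool)
    if cfg.overrepresented_insert is not None:
        overrep_seq, frac = cfg.overrepresented_insert
        overrep_mask[: int(round(frac * n))] = True
        # assignment order is independent of everything else drawn per-read

    dual = cfg.platform in ("ION_TORRENT", "454")
    reads: list[Read] = []
    truths: list[ReadTruth] = []
    for i in range(n):
        insert = overrep_seq if overrep_mask[i] else species[int(species_idx[i])]
        five_part = ""
        if dual and cfg.adapter_5p:
            five_part = cfg.adapter_5p
            if (
                cfg.five_prime_degraded_fraction > 0
                and rng.random() < cfg.five_prime_degraded_fraction
            ):
                keep = int(
                    rng.integers(cfg.five_prime_min_suffix, len(cfg.adapter_5p))
                )
                five_part = cfg.adapter_5p[len(cfg.adapter_5p) - keep :]
        barcode_part = cfg.barcode or ""
        nmer5 = _random_seq(rng, cfg.random_mer_5p)
        nmer3 = _random_seq(rng, cfg.random_mer_3p)
        adapter_part = cfg.adapter_3p or ""
        if adapter_part and modified[i]:
            adapter_part = _degrade_3p(
                cfg.adapter_3p, cfg.degradation_model, rng, homogeneous_sub
            )
        prefix_len = len(five_part) + len(barcode_part) + len(nmer5)
        if cfg.platform in _FIXED_LENGTH:
            body = (
                five_part + barcode_part + nmer5 + insert + nmer3 + adapter_part
            )
            filler_len = max(0, cfg.read_length - len(body))
            filler = _random_seq(rng, filler_len)
            if modified[i] and cfg.adapter_3p:
                # a truncated adapter copy must stay non-intact: resample the
                # filler if it chance-completes the full adapter
                while cfg.adapter_3p in body + filler:
                    filler = _random_seq(rng, filler_len)
            full = (body + filler)[: cfg.read_length]
            # parts as emitted (truncation may cut into any part)
            emitted = _truncate_parts(
                [five_part, barcode_part, nmer5, insert, nmer3, adapter_part, filler],
                cfg.read_length,
            )
        else:
            filler = ""
            emitted = [
                five_part, barcode_part, nmer5, insert, nmer3, adapter_part, filler,
            ]
            full = "".join(emitted)
        insert_emitted = emitted[3]
        if insert_emitted:
            insert_start = prefix_len + 1
            insert_end = prefix_len + len(insert_emitted)
        else:
            insert_start, insert_end = 0, -1
        read_id = f"sim{i}"
        reads.append(Read(id=read_id, seq=full, qual="I" * len(full)))
        truths.append(
            ReadTruth(
                read_id=read_id,
                five_prime_part=emitted[0],
                barcode_part=emitted[1],
                nmer5_part=emitted[2],
                insert=insert_emitted,
                nmer3_part=emitted[4],
                adapter_3p_part=emitted[5],
                filler_part=emitted[6],
                intact=bool(adapter_part == (cfg.adapter_3p or ""))
                and bool(cfg.adapter_3p)
                and emitted[5] == cfg.adapter_3p,
                insert_start=insert_start,
                insert_end=insert_end,
            )
        )
    truth = LibraryTruth(config=cfg, reads=truths, n_intact=n_intact)
    if cfg.platform == "SOLID":
        color_reads = [
            encode_colorspace(r, primer_base=cfg.primer_base) for r in reads
        ]
        return color_reads, truth
    return reads, truth


def _truncate_parts(parts: list[str], limit: int) -> list[str]:
    """Truncate a list of concatenated parts to a total length limit."""
    out: list[str] = []
    remaining = limit
    for part in parts:
        take = min(len(part), max(0, remaining))
        out.append(part[:take])
        remaining -= take
    return out


def write_fasta(sequences: dict[str, str] | str, path: str) -> None:
    """Write reference sequence(s) as FASTA."""
    if isinstance(sequences, str):
        sequences = {"reference": sequences}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
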