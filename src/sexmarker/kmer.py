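"""Comparative k-mer sieve.

Selects transcripts carrying k-mers present in every male sample and
absent from every female sample — the presence/absence signature that
flags putatively Y-chromosomal transcripts without a Y assembly.
Profiles are exact in-memory sets: the all-males/no-females predicate
needs exactness, and candidate transcriptomes are desk-scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import SeqRecord, Sex, revcomp

_ACGT = frozenset("ACGT")


@dataclass
class SampleKmerProfile:
    """Set of fixed-length k-mers observed in one sample, with its sex."""

    sample_id: str
    sex: Sex
    k: int
    kmers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {m for m in self.kmers if len(m) != self.k or set(m) - _ACGT}
        if bad:
            raise ValueError(
                f"{self.sample_id}: k-mers with wrong length or non-ACGT "
                f"characters, e.g. {sorted(bad)[:3]}"
            )


def kmers_of(seq: str, k: int, canonical: bool = False) -> set[str]:
    """Every length-k window of seq (plus its reverse complement when
    canonical); windows containing anything outside A/C/G/T are dropped."""
    seq = seq.upper()
    out: set[str] = set()
    for s in ([seq, revcomp(seq)] if canonical else [seq]):
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if not set(w) - _ACGT:
                out.add(w)
    return out


def build_profile(records: Sequence[SeqRecord], k: int, sex: Sex,
                  sample_id: str = "", canonical: bool = False) -> SampleKmerProfile:
    """k-mer profile over all records of one sample.

    ``canonical`` folds in reverse-complement k-mers; default off because
    transcripts are stranded (turn on for unstranded raw-read input).
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if not records:
        raise ValueError("no records given")
    kmers: set[str] = set()
    for rec in records:
        kmers |= kmers_of(rec.ungapped, k, canonical)
    if not kmers:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'}: every record shorter than "
            f"k={k}; profile is empty", stacklevel=2,
        )
    return SampleKmerProfile(sample_id=sample_id, sex=sex, k=k, kmers=kmers)


def male_specific_kmers(profiles: Iterable[SampleKmerProfile]) -> set[str]:
    """k-mers present in every male profile and absent from every female
    profile: intersection over males minus union over females."""
    profiles = list(profiles)
    males = [p for p in profiles if p.sex == Sex.male]
    females = [p for p in profiles if p.sex == Sex.female]
    if not males or not females:
        raise ValueError("need at least one male and one female profile")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"mixed k across profiles: {sorted(ks)}")
    specific = set.intersection(*(p.kmers for p in males))
    for p in females:
        specific -= p.kmers
    return specific


@dataclass(frozen=True)
class SieveHit:
    transcript_id: str
    n_specific_kmers: int


def sieve_transcripts(transcripts: Sequence[SeqRecord], specific_set: set[str],
                      k: int, canonical: bool = False) -> list[SieveHit]:
    """Retain transcripts containing at least one male-specific k-mer.

    Input order is preserved; each hit carries the count of matching
    k-mer windows (distinct k-mers counted once).
    """
    if any(len(m) != k for m in specific_set):
        raise ValueError("specific_set contains k-mers of the wrong length")
    hits = []
    for rec in transcripts:
        n = len(kmers_of(rec.ungapped, k, canonical) & specific_set)
        if n > 0:
            hits.append(SieveHit(rec.id, n))
    return hits
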