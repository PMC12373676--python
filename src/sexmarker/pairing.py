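"""X/Y gametolog pairing and divergence ranking.

Each candidate Y transcript is searched against a provided set of
X-chromosome loci by local alignment. The best hit is accepted only when
it is near-full-length, high-identity and unambiguous (no runner-up of
comparable score); a perfect full-length hit is rejected instead, since a
sequence identical to the female genome cannot be Y-diverged. Accepted
pairs are globally aligned and ranked by X/Y divergence — the most
diverged pairs are the best marker substrates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio import Align

from .core import GAP, GametologAlignment


@dataclass(frozen=True)
class PairingPolicy:
    """Hit-acceptance thresholds. ``close to 100%`` identity/coverage is
    quantified here as defaults 0.90/0.90 — explicit artifact choices,
    configurable. The identity floor deliberately sits below the ~0.95
    identity of a 5%-diverged gametolog pair so that true X/Y pairs are
    not rejected for the very divergence that makes them good markers.
    A secondary hit scoring above ``max_secondary_ratio`` times the best
    score marks the candidate ambiguous."""

    min_identity: float = 0.90
    min_coverage: float = 0.90
    max_secondary_ratio: float = 0.9

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "max_secondary_ratio"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring. A gap of length L costs
    gap_open + (L - 1) * gap_extend (the first gapped base pays the open
    penalty)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


class PairStatus(str, enum.Enum):
    accepted = "accepted"
    ambiguous_multi_hit = "ambiguous_multi_hit"
    rejected_female_identical = "rejected_female_identical"
    no_hit = "no_hit"


@dataclass
class GametologPair:
    y_id: str
    x_id: str | None
    alignment: GametologAlignment | None
    divergence: float | None
    status: PairStatus


def _aligner(scoring: AlignScoring, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def _rows_of(alignment: Align.Alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def align_pair(x_seq: str, y_seq: str,
               scoring: AlignScoring | None = None) -> GametologAlignment:
    """Global affine-gap alignment of the X and Y copies.

    Deterministic: among co-optimal alignments the first in the aligner's
    canonical enumeration order is taken.
    """
    scoring = scoring or AlignScoring()
    x_seq, y_seq = x_seq.upper(), y_seq.upper()
    aln = _aligner(scoring, "global").align(x_seq, y_seq)[0]
    x_row, y_row = _rows_of(aln)
    return GametologAlignment(x_row=x_row, y_row=y_row)


def align_score(a: str, b: str, scoring: AlignScoring | None = None,
                mode: str = "global") -> float:
    """Optimal alignment score only (used for hit screening and testing)."""
    scoring = scoring or AlignScoring()
    return float(_aligner(scoring, mode).score(a.upper(), b.upper()))


def _local_hit_stats(y_seq: str, candidate: str,
                     scoring: AlignScoring) -> tuple[float, float, float]:
    """(score, identity, coverage) of the best local hit of y_seq in
    candidate. Identity = identical columns / aligned columns; coverage =
    aligned y span / len(y_seq)."""
    aligner = _aligner(scoring, "local")
    alns = aligner.align(candidate, y_seq)
    if len(alns) == 0:
        return 0.0, 0.0, 0.0
    aln = alns[0]
    c_row, y_row = _rows_of(aln)
    ncols = len(c_row)
    ident = sum(1 for a, b in zip(c_row, y_row) if a == b and a != GAP)
    y_start, y_end = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    coverage = (y_end - y_start) / len(y_seq)
    identity = ident / ncols if ncols else 0.0
    return float(aln.score), identity, coverage


def find_counterpart(y_id: str, y_seq: str, x_candidates: dict[str, str],
                     policy: PairingPolicy | None = None,
                     scoring: AlignScoring | None = None) -> GametologPair:
    """Locate the X counterpart of a Y candidate among provided X loci.

    Statuses:
      * ``no_hit`` — best hit below identity/coverage thresholds;
      * ``ambiguous_multi_hit`` — a secondary locus scores within
        max_secondary_ratio of the best (paralog/autosome risk);
      * ``rejected_female_identical`` — perfect full-length identity, i.e.
        the sequence also exists unchanged in the female genome;
      * ``accepted`` — otherwise, with the global X/Y alignment attached.
    """
    policy = policy or PairingPolicy()
    scoring = scoring or AlignScoring()
    if not y_seq:
        raise ValueError("empty query sequence")
    if not x_candidates:
        raise ValueError("no X candidates supplied")

    stats = {
        cid: _local_hit_stats(y_seq, cseq, scoring)
        for cid, cseq in x_candidates.items()
    }
    best_id = max(stats, key=lambda c: (stats[c][0], c))
    best_score, best_ident, best_cov = stats[best_id]

    if best_score <= 0 or best_ident < policy.min_identity or best_cov < policy.min_coverage:
        return GametologPair(y_id, None, None, None, PairStatus.no_hit)
    secondary = [s for cid, (s, _, _) in stats.items() if cid != best_id]
    if secondary and max(secondary) >= policy.max_secondary_ratio * best_score:
        return GametologPair(y_id, None, None, None, PairStatus.ambiguous_multi_hit)
    if best_ident == 1.0 and best_cov >= 1.0:
        return GametologPair(y_id, best_id, None, None,
                             PairStatus.rejected_female_identical)

    aln = align_pair(x_candidates[best_id], y_seq, scoring)
    return GametologPair(y_id, best_id, aln, aln.divergence(), PairStatus.accepted)


def divergence_rank(pairs: list[GametologPair]) -> list[GametologPair]:
    """Accepted pairs in descending divergence order; ties broken by y_id."""
    if any(p.status != PairStatus.accepted for p in pairs):
        raise ValueError("divergence_rank expects accepted pairs only")
    return sorted(pairs, key=lambda p: (-p.divergence, p.y_id))
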