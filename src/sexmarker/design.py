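"""CAPS marker design on a gametolog alignment.

Given an X/Y (optionally multi-cultivar) alignment and a restriction
enzyme table, this module finds allele-differential recognition sites,
locates conserved windows flanking each site, designs a common degenerate
primer pair over those windows, designs allele-specific probes across the
diagnostic polymorphism, predicts the per-genotype band patterns and
ranks candidates by gel resolvability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .assay import digest, insilico_pcr, pattern_positions, predict_genotype_bands
from .core import (
    GAP,
    IUPAC_SETS,
    BandPattern,
    ColumnClass,
    GametologAlignment,
    Genotype,
    RestrictionEnzyme,
    degeneracy,
    iupac_code_for,
    revcomp,
)


class DesignFailure(RuntimeError):
    """No primer/probe satisfying the constraints exists; carries the reason."""


@dataclass(frozen=True)
class DifferentialSite:
    """A restriction site present in exactly one allele of the alignment."""

    enzyme: RestrictionEnzyme
    allele_with_site: str          # "X" or "Y"
    site_start: int                # ungapped position in the carrying allele
    alignment_column: int          # column of the first recognition base
    strand: str = "+"

    @property
    def span(self) -> int:
        return len(self.enzyme.recognition)


@dataclass(frozen=True)
class DegeneratePrimer:
    """A primer whose polymorphic positions carry minimal IUPAC codes so
    one oligo matches every row of the alignment."""

    seq: str
    strand: str                    # "+" forward, "-" reverse
    columns: tuple[int, int]       # half-open alignment-column window
    degeneracy: int
    tm_estimate: float

    def __post_init__(self) -> None:
        if len(IUPAC_SETS[self.seq[-1]]) != 1:
            raise ValueError("3'-terminal base must be non-degenerate")


@dataclass(frozen=True)
class AlleleProbes:
    """Allele-discrimination oligos for TaqMan-style genotyping: the
    cut-allele (Y/FAM) probe spans the restriction site, the uncut-allele
    (X/VIC) probe spans the homologous columns."""

    probe_for_cut_allele: str
    probe_for_uncut_allele: str
    columns: tuple[int, int]


@dataclass
class CapsCandidate:
    site: DifferentialSite
    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    amplicon_len_x: int
    amplicon_len_y: int
    predicted_bands: dict[Genotype, BandPattern]
    probes: AlleleProbes | None = None
    score: float = 0.0

    @property
    def diagnostic(self) -> bool:
        return (self.predicted_bands[Genotype.XX].bands
                != self.predicted_bands[Genotype.XY].bands)


@dataclass(frozen=True)
class FlankConfig:
    """Constraints on primer windows flanking a differential site.

    Windows must sit within ``max_distance`` alignment columns of the
    site (keeps amplicons gel-friendly), contain no indel column, and at
    most ``max_poly`` substitution columns (each becomes a degenerate
    base). Degeneracy of an emitted primer may not exceed the cap.
    """

    primer_len_min: int = 18
    primer_len_max: int = 25
    max_poly: int = 3
    max_distance: int = 400
    degeneracy_cap: int = 16
    tm_min: float = 48.0
    tm_max: float = 72.0


@dataclass(frozen=True)
class ProbeConfig:
    min_len: int = 15
    max_len: int = 25


# ---------------------------------------------------------------------------
# Differential-site scan


def _sites_with_strand(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    hits = [(p, "+") for p in pattern_positions(enzyme.recognition, seq)]
    if not enzyme.is_palindromic:
        hits += [(p, "-") for p in pattern_positions(revcomp(enzyme.recognition), seq)]
    return sorted(hits)


def _pos_to_col(row: str) -> list[int]:
    return [i for i, c in enumerate(row) if c != GAP]


def scan_differential_sites(alignment: GametologAlignment,
                            enzymes: Sequence[RestrictionEnzyme]) -> list[DifferentialSite]:
    """All recognition sites present in exactly one allele.

    The absence test is homology-aware: the other allele's ungapped
    sequence spanning the site's alignment columns, extended by
    |recognition| - 1 on each side, must contain no match on either
    strand — a site merely shifted by an indel does not count as absent.
    """
    rows = {"X": alignment.x_row, "Y": alignment.y_row}
    seqs = {a: r.replace(GAP, "") for a, r in rows.items()}
    maps = {a: _pos_to_col(r) for a, r in rows.items()}
    col_maps = {a: alignment.col_to_pos(r) for a, r in rows.items()}

    out: list[DifferentialSite] = []
    for enzyme in enzymes:
        span = len(enzyme.recognition)
        for allele in ("X", "Y"):
            other = "Y" if allele == "X" else "X"
            for start, strand in _sites_with_strand(seqs[allele], enzyme):
                c1 = maps[allele][start]
                c2 = maps[allele][start + span - 1]
                # homologous window in the other allele, +/- (span - 1)
                other_pos = [col_maps[other][c] for c in range(c1, c2 + 1)
                             if col_maps[other][c] is not None]
                if other_pos:
                    lo, hi = min(other_pos), max(other_pos) + 1
                else:  # site falls entirely in a gap of the other allele
                    after = next((col_maps[other][c] for c in range(c2 + 1, len(alignment))
                                  if col_maps[other][c] is not None), len(seqs[other]))
                    lo = hi = after
                lo = max(0, lo - (span - 1))
                hi = min(len(seqs[other]), hi + (span - 1))
                if _sites_with_strand(seqs[other][lo:hi], enzyme):
                    continue
                out.append(DifferentialSite(enzyme, allele, start, c1, strand))
    return out


# ---------------------------------------------------------------------------
# Conserved flanks and degenerate primers


def find_conserved_flanks(alignment: GametologAlignment, column: int,
                          cfg: FlankConfig | None = None,
                          site_span: int = 1) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Nearest windows flanking [column, column + site_span) that can host
    a common primer: length primer_len_min, zero indel columns, at most
    max_poly substitution columns, within max_distance columns of the
    site. Conservation is judged across every row (all cultivars).
    Returns (left_window, right_window) as half-open column ranges, or
    None if either side has no admissible window.
    """
    cfg = cfg or FlankConfig()
    if not 0 <= column < len(alignment):
        raise ValueError("column outside alignment")
    classes = alignment.conservation_classes()
    w = cfg.primer_len_min

    def ok(s: int) -> bool:
        win = classes[s:s + w]
        return (len(win) == w
                and not any(c == ColumnClass.indel for c in win)
                and sum(c == ColumnClass.substitution for c in win) <= cfg.max_poly)

    left = None
    for s in range(column - w, max(-1, column - cfg.max_distance - 1), -1):
        if s >= 0 and ok(s):
            left = (s, s + w)
            break
    right = None
    site_end = column + site_span
    for s in range(site_end, min(len(classes) - w, site_end + cfg.max_distance) + 1):
        if ok(s):
            right = (s, s + w)
            break
    if left is None or right is None:
        return None
    return left, right


def _consensus(alignment: GametologAlignment, window: tuple[int, int]) -> str:
    rows = list(alignment.all_rows().values())
    out = []
    for c in range(*window):
        col = {r[c] for r in rows}
        if GAP in col:
            raise DesignFailure(f"indel column {c} inside primer window")
        out.append(iupac_code_for(col))
    return "".join(out)


def wallace_tm(seq: str) -> float:
    """Wallace-rule Tm (2*(A+T) + 4*(G+C)) averaged over the degenerate
    expansions of each base. Approximate; used for ranking only."""
    tm = 0.0
    for c in seq.upper():
        bases = IUPAC_SETS[c]
        tm += sum(2.0 if b in "AT" else 4.0 for b in bases) / len(bases)
    return tm


def _shift_for_concrete_3prime(alignment: GametologAlignment,
                               window: tuple[int, int], direction: int,
                               three_prime_col: str) -> tuple[int, int]:
    """Slide a window until its 3'-terminal column is invariant."""
    s, e = window
    classes = alignment.conservation_classes()
    for _ in range(len(alignment)):
        col = e - 1 if three_prime_col == "right" else s
        if classes[col] == ColumnClass.identical:
            return s, e
        s += direction
        e += direction
        if s < 0 or e > len(alignment):
            break
    raise DesignFailure("no window with a non-degenerate 3' terminus")


def design_degenerate_primers(alignment: GametologAlignment,
                              windows: tuple[tuple[int, int], tuple[int, int]],
                              cfg: FlankConfig | None = None
                              ) -> tuple[DegeneratePrimer, DegeneratePrimer]:
    """Common primer pair over conserved flank windows.

    Each primer is the column-wise consensus over all rows, polymorphic
    columns encoded as the minimal covering IUPAC code; the reverse
    primer is reverse-complemented. Windows are shifted away from the
    site if needed so the 3'-terminal base is non-degenerate, and
    extended up to primer_len_max (when adjacent columns are clean) to
    reach the Tm floor.
    """
    cfg = cfg or FlankConfig()
    left, right = windows
    left = _shift_for_concrete_3prime(alignment, left, -1, "right")
    right = _shift_for_concrete_3prime(alignment, right, +1, "left")
    classes = alignment.conservation_classes()

    def extend(win: tuple[int, int], grow_left: bool) -> tuple[int, int]:
        s, e = win
        while e - s < cfg.primer_len_max:
            nxt = s - 1 if grow_left else e
            if nxt < 0 or nxt >= len(alignment) or classes[nxt] != ColumnClass.identical:
                break
            if wallace_tm(_consensus(alignment, (s, e))) >= cfg.tm_min:
                break
            if grow_left:
                s -= 1
            else:
                e += 1
        return s, e

    left = extend(left, grow_left=True)    # fwd 3' end stays put
    right = extend(right, grow_left=False)  # rev 3' end (left edge) stays put

    fwd_seq = _consensus(alignment, left)
    rev_seq = revcomp(_consensus(alignment, right))
    for name, seq in (("forward", fwd_seq), ("reverse", rev_seq)):
        d = degeneracy(seq)
        if d > cfg.degeneracy_cap:
            raise DesignFailure(f"{name} primer degeneracy {d} exceeds cap "
                                f"{cfg.degeneracy_cap}")
        if wallace_tm(seq) > cfg.tm_max:
            raise DesignFailure(f"{name} primer Tm above {cfg.tm_max}")
    fwd = DegeneratePrimer(fwd_seq, "+", left, degeneracy(fwd_seq), wallace_tm(fwd_seq))
    rev = DegeneratePrimer(rev_seq, "-", right, degeneracy(rev_seq), wallace_tm(rev_seq))
    return fwd, rev


# ---------------------------------------------------------------------------
# Allele-specific probes


def design_allele_probes(alignment: GametologAlignment, site: DifferentialSite,
                         cfg: ProbeConfig | None = None) -> AlleleProbes:
    """Short oligos centered on the diagnostic polymorphism: each matches
    its own allele exactly and mismatches the other at >= 1 diagnostic
    column of the restriction site."""
    cfg = cfg or ProbeConfig()
    classes = alignment.column_classes
    c1, c2 = site.alignment_column, site.alignment_column + site.span
    diag = [c for c in range(c1, c2) if classes[c] != ColumnClass.identical]
    if not diag:
        raise DesignFailure("site columns are not polymorphic between alleles")

    center = (diag[0] + diag[-1] + 1) // 2
    carrier_row = alignment.y_row if site.allele_with_site == "Y" else alignment.x_row
    other_row = alignment.x_row if site.allele_with_site == "Y" else alignment.y_row

    target = min(cfg.max_len, max(cfg.min_len, site.span + 2 * 8))
    for length in range(target, cfg.max_len + 1):
        s = max(0, center - length // 2)
        e = min(len(alignment), s + length)
        s = max(0, e - length)
        if not (s <= diag[0] and diag[-1] < e):
            continue
        cut_probe = carrier_row[s:e].replace(GAP, "")
        uncut_probe = other_row[s:e].replace(GAP, "")
        if len(cut_probe) < cfg.min_len or len(uncut_probe) < cfg.min_len:
            continue
        # each probe must mismatch the other allele at a diagnostic column
        if any(carrier_row[c] != other_row[c] for c in diag):
            return AlleleProbes(cut_probe, uncut_probe, (s, e))
    raise DesignFailure("alleles identical over all feasible probe windows")


# ---------------------------------------------------------------------------
# Candidate assembly and ranking


def build_candidate(alignment: GametologAlignment, site: DifferentialSite,
                    flank_cfg: FlankConfig | None = None,
                    probe_cfg: ProbeConfig | None = None,
                    max_amplicon: int = 2000) -> CapsCandidate:
    """Full CAPS candidate for one differential site: flanks, primers,
    in-silico amplicons from both alleles, predicted band patterns and
    allele probes."""
    flank_cfg = flank_cfg or FlankConfig()
    windows = find_conserved_flanks(alignment, site.alignment_column,
                                    flank_cfg, site_span=site.span)
    if windows is None:
        raise DesignFailure("no conserved flank windows within reach of the site")
    fwd, rev = design_degenerate_primers(alignment, windows, flank_cfg)

    x_seq, y_seq = alignment.x_seq, alignment.y_seq
    x_amps = insilico_pcr(x_seq, fwd, rev, max_amplicon)
    y_amps = insilico_pcr(y_seq, fwd, rev, max_amplicon)
    if len(x_amps) != 1 or len(y_amps) != 1:
        raise DesignFailure(
            f"primers must amplify exactly one product per allele "
            f"(got {len(x_amps)} on X, {len(y_amps)} on Y)")
    bands = predict_genotype_bands(x_amps[0], y_amps[0], site.enzyme)
    try:
        probes = design_allele_probes(alignment, site, probe_cfg)
    except DesignFailure:
        probes = None
    return CapsCandidate(
        site=site, fwd=fwd, rev=rev,
        amplicon_len_x=len(x_amps[0]), amplicon_len_y=len(y_amps[0]),
        predicted_bands=bands, probes=probes,
    )


def min_band_gap(candidate: CapsCandidate) -> int:
    """Smallest pairwise distance between distinct predicted XY bands —
    the hardest band separation a gel must resolve."""
    bands = sorted(set(candidate.predicted_bands[Genotype.XY].bands))
    if len(bands) < 2:
        return 0
    return min(b - a for a, b in zip(bands, bands[1:]))


def rank_candidates(candidates: Sequence[CapsCandidate],
                    weights: tuple[float, float, float] = (1.0, 1.0, 0.01)
                    ) -> list[CapsCandidate]:
    """Deterministic ranking: larger minimum band gap (gel resolvability)
    first, then lower total primer degeneracy, then shorter amplicon.
    Ties broken by enzyme name and site column."""
    w_gap, w_deg, w_len = weights
    ranked = []
    for c in candidates:
        c.score = (w_gap * min_band_gap(c)
                   - w_deg * (c.fwd.degeneracy + c.rev.degeneracy)
                   - w_len * max(c.amplicon_len_x, c.amplicon_len_y))
        ranked.append(c)
    return sorted(ranked, key=lambda c: (-c.score, c.site.enzyme.name,
                                         c.site.alignment_column))
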