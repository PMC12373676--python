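"""In-silico CAPS assay: PCR, restriction digestion, band prediction,
genotype calling, and TaqMan-style allele-signal simulation.

The CAPS read-out this simulates: a common primer pair amplifies both the
X and the Y copy of a gametolog; a restriction site present in only one
allele splits that allele's amplicon, so XX samples show the intact band
while XY samples add the digestion fragments. Digestion is treated as
complete, and heteroduplexes are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    IUPAC_SETS,
    BandPattern,
    Genotype,
    RestrictionEnzyme,
    revcomp,
)

_CONCRETE = frozenset("ACGT")


def _pattern_matches_at(pattern: str, template: str, pos: int) -> bool:
    """IUPAC pattern vs concrete template. Template N (or any ambiguity)
    never satisfies a match — conservative, avoids phantom sites."""
    if pos < 0 or pos + len(pattern) > len(template):
        return False
    for pc, tc in zip(pattern, template[pos:pos + len(pattern)]):
        if tc not in _CONCRETE or tc not in IUPAC_SETS[pc]:
            return False
    return True


def pattern_positions(pattern: str, template: str) -> list[int]:
    """All start positions where the IUPAC pattern matches the template."""
    pattern, template = pattern.upper(), template.upper()
    return [i for i in range(len(template) - len(pattern) + 1)
            if _pattern_matches_at(pattern, template, i)]


# ---------------------------------------------------------------------------
# PCR


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, 5'->3' on the template plus strand,
    primer footprints included."""

    seq: str
    start: int  # template coordinate of the forward primer 5' end
    end: int    # template coordinate one past the reverse primer footprint

    def __len__(self) -> int:
        return len(self.seq)


def _primer_seq(primer) -> str:
    return getattr(primer, "seq", primer).upper()


def insilico_pcr(template: str, fwd, rev, max_amplicon: int = 5000) -> list[Amplicon]:
    """Every product where fwd binds the plus strand and rev binds the
    minus strand downstream, both with zero mismatches under IUPAC
    expansion. Primers may be plain strings or DegeneratePrimer objects.
    """
    template = template.upper()
    fwd_seq = _primer_seq(fwd)
    rev_fp = revcomp(_primer_seq(rev))  # plus-strand footprint of rev primer
    fwd_hits = pattern_positions(fwd_seq, template)
    rev_hits = pattern_positions(rev_fp, template)
    out = []
    for i in fwd_hits:
        for j in rev_hits:
            if j < i + len(fwd_seq):
                continue  # footprints must not overlap
            end = j + len(rev_fp)
            if end - i > max_amplicon:
                continue
            out.append(Amplicon(template[i:end], i, end))
    return sorted(out, key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# Digestion


def cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Distinct top-strand cut coordinates of the enzyme on seq.

    Both strands are scanned; palindromic recognition sequences only once.
    A minus-strand site cuts the top strand at site_start +
    (|recognition| - cut_offset).
    """
    seq = seq.upper()
    rec = enzyme.recognition
    cuts = {s + enzyme.cut_offset for s in pattern_positions(rec, seq)}
    if not enzyme.is_palindromic:
        rc = revcomp(rec)
        cuts |= {s + (len(rec) - enzyme.cut_offset)
                 for s in pattern_positions(rc, seq)}
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(amplicon, enzyme: RestrictionEnzyme) -> BandPattern:
    """Fragment lengths after complete digestion; an uncut amplicon gives
    a single full-length band."""
    seq = getattr(amplicon, "seq", amplicon).upper()
    if not seq:
        raise ValueError("empty amplicon")
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    return BandPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def predict_genotype_bands(x_amplicon, y_amplicon,
                           enzyme: RestrictionEnzyme) -> dict[Genotype, BandPattern]:
    """Expected band patterns per genotype.

    XX = digest of the X amplicon alone; XY = multiset union of the X and
    Y digests (both alleles amplify in an XY individual). Monoecious
    individuals carry two X chromosomes and read as XX.
    """
    if x_amplicon is None:
        raise ValueError("no X amplicon: the common-primer contract is broken")
    xx = digest(x_amplicon, enzyme)
    if y_amplicon is None:
        xy = xx
    else:
        xy = BandPattern(tuple(list(xx.bands) + list(digest(y_amplicon, enzyme).bands)))
    return {Genotype.XX: xx, Genotype.XY: xy}


def _multiset_match(observed: Sequence[int], expected: Sequence[int],
                    tol: int) -> bool:
    """Equal-size multisets whose sorted elements pair within +/- tol."""
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tol
               for o, e in zip(sorted(observed), sorted(expected)))


def call_genotype(observed_bands: Iterable[int],
                  patterns: Mapping[Genotype, BandPattern],
                  tolerance_bp: int = 10) -> Genotype:
    """Read a band pattern against the predicted XX/XY patterns.

    The default 10 bp tolerance mimics agarose resolution. Patterns that
    do not discriminate XX from XY always yield ``ambiguous``.
    """
    observed = sorted(observed_bands)
    if not observed:
        raise ValueError("no observed bands")
    xx, xy = patterns[Genotype.XX], patterns[Genotype.XY]
    if xx.bands == xy.bands:
        return Genotype.ambiguous
    if _multiset_match(observed, xy.bands, tolerance_bp):
        return Genotype.XY
    if _multiset_match(observed, xx.bands, tolerance_bp):
        return Genotype.XX
    return Genotype.ambiguous


# ---------------------------------------------------------------------------
# TaqMan allelic discrimination

VIC = "VIC"  # reporter dye on the probe for the uncut (X) allele
FAM = "FAM"  # reporter dye on the probe for the cut (Y) allele


def _probe_binds(probe: str, allele: str) -> bool:
    probe, allele = probe.upper(), allele.upper()
    return probe in allele or revcomp(probe) in allele


def simulate_taqman(genotype: Genotype | None, probe_for_cut_allele: str,
                    probe_for_uncut_allele: str, x_allele: str,
                    y_allele: str | None) -> set[str]:
    """Endpoint allelic-discrimination signals for a genotype.

    A dye fires iff its probe matches an allele present in the genotype
    with zero mismatches. Expected: XX -> {VIC}; XY -> {VIC, FAM};
    no-template control (genotype None) -> {}.
    """
    if y_allele is not None:
        if not (_probe_binds(probe_for_cut_allele, y_allele)
                or _probe_binds(probe_for_cut_allele, x_allele)):
            raise ValueError("cut-allele probe matches neither allele")
    if not (_probe_binds(probe_for_uncut_allele, x_allele)
            or (y_allele is not None and _probe_binds(probe_for_uncut_allele, y_allele))):
        raise ValueError("uncut-allele probe matches neither allele")

    if genotype is None:
        return set()
    alleles = [x_allele, x_allele] if genotype == Genotype.XX else [x_allele, y_allele]
    signals = set()
    for allele in alleles:
        if allele is None:
            continue
        if _probe_binds(probe_for_uncut_allele, allele):
            signals.add(VIC)
        if _probe_binds(probe_for_cut_allele, allele):
            signals.add(FAM)
    return signals
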