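"""Regenerate the packaged synthetic fixtures.

Builds the synthetic CsPDS5-style X/Y loci (random backbones carrying
the published primer/probe footprints and the allele-differential EcoRI
site, arranged so the assay arithmetic reproduces the published marker:
419 bp amplicons, Y digest 157 + 262 bp, X uncut), the matching gapped
alignment with one extra cultivar row, and the synthetic stand-ins for
the candidate supplementary sets (25 transcripts; 6 gene alignments).

Run from the repository root:  python scripts/make_synthetic_fixtures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sexmarker.assay import digest, insilico_pcr, pattern_positions
from sexmarker.core import GametologAlignment, SeqRecord, revcomp, write_fasta
from sexmarker.design import design_degenerate_primers, scan_differential_sites
from sexmarker.fixtures import (
    CSPDS5_FWD_PRIMER,
    CSPDS5_REV_PRIMER,
    FEM_PROBE,
    MALE_PROBE,
    TAQMAN_FWD_PRIMER,
    TAQMAN_REV_PRIMER,
)
from sexmarker.synth import ECO_RI, _random_seq, generate_gametolog_pair

DATA = Path(__file__).resolve().parents[1] / "src" / "sexmarker" / "data"

# concrete realisations of the degenerate oligos (one allowed base per code)
FWD_REAL = "GGATTATCATCCAGAGAATG"      # Y->T, M->A
REV_REAL = "TACCATATTCTCATCAGAAGC"     # R->A
TAQF_REAL = "TATTTCAATGGAGCTTCTCACC"   # Y->T, W->A
TAQR_REAL = "AACCTTAGGAGCACATGTTTC"    # M->A, K->G, K->T, R->G

FLANK = 150
SITE_AMP = 156          # EcoRI site start within the Y amplicon
PROBE_AT = 144          # probe-region start within the amplicon
X_DEL_AT = 40           # base deleted from filler D in the X allele


def _assert_realisation(real: str, pattern: str) -> None:
    assert len(real) == len(pattern)
    assert all(pattern_positions(pattern, real) == [0] for _ in [0]), (real, pattern)


def build_locus(seed: int):
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, 40)     # 20..60
    b = _random_seq(rng, 62)     # 82..144
    c = _random_seq(rng, 73)     # 166..239 (Y coords)
    d = _random_seq(rng, 138)    # 260..398 (Y coords)
    flank5 = _random_seq(rng, FLANK)
    flank3 = _random_seq(rng, FLANK)

    y_amp = (FWD_REAL + a + TAQF_REAL + b + MALE_PROBE + c
             + revcomp(TAQR_REAL) + d + revcomp(REV_REAL))
    x_amp = (FWD_REAL + a + TAQF_REAL + b + FEM_PROBE + c
             + revcomp(TAQR_REAL) + d[:X_DEL_AT] + d[X_DEL_AT + 1:]
             + revcomp(REV_REAL))
    assert len(y_amp) == len(x_amp) == 419
    y_g = flank5 + y_amp + flank3
    x_g = flank5 + x_amp + flank3

    # --- constraint checks; any failure rejects this seed ---
    for g, site_pos in ((y_g, [FLANK + SITE_AMP]), (x_g, [])):
        if pattern_positions("GAATTC", g) != site_pos:
            return None
        if pattern_positions(CSPDS5_FWD_PRIMER, g) != [FLANK]:
            return None
        if pattern_positions(revcomp(CSPDS5_REV_PRIMER), g) != [FLANK + 398]:
            return None
        if (pattern_positions(revcomp(CSPDS5_FWD_PRIMER), g)
                or pattern_positions(CSPDS5_REV_PRIMER, g)):
            return None
        if pattern_positions(TAQMAN_FWD_PRIMER, g) != [FLANK + 60]:
            return None
        if (pattern_positions(revcomp(TAQMAN_FWD_PRIMER), g)
                or pattern_positions(TAQMAN_REV_PRIMER, g)):
            return None
    if pattern_positions(revcomp(TAQMAN_REV_PRIMER), y_g) != [FLANK + 239]:
        return None
    if pattern_positions(revcomp(TAQMAN_REV_PRIMER), x_g) != [FLANK + 240]:
        return None
    for probe, host, other in ((MALE_PROBE, y_g, x_g), (FEM_PROBE, x_g, y_g)):
        if pattern_positions(probe, host) != [FLANK + PROBE_AT]:
            return None
        if pattern_positions(probe, other) or pattern_positions(revcomp(probe), other):
            return None

    # --- gapped alignment rows ---
    pre = flank5 + y_amp[:PROBE_AT]                      # identical X/Y
    mid = c + revcomp(TAQR_REAL) + d[:X_DEL_AT]          # identical X/Y
    post = d[X_DEL_AT + 1:] + revcomp(REV_REAL) + flank3
    y_row = pre + MALE_PROBE + "-" + mid + d[X_DEL_AT] + post
    x_row = pre + FEM_PROBE + mid + "-" + post
    assert len(y_row) == len(x_row) == len(y_g) + 1
    assert y_row.replace("-", "") == y_g and x_row.replace("-", "") == x_g

    # extra cultivar row: X-like with SNPs at the degenerate primer bases
    aln = GametologAlignment(x_row=x_row, y_row=y_row)
    col_of_x = {p: i for i, p in enumerate(aln.col_to_x) if p is not None}
    cb = list(x_row)
    cb[col_of_x[FLANK + 3]] = "C"        # fwd primer Y position (T/C)
    cb[col_of_x[FLANK + 17]] = "C"       # fwd primer M position (A/C)
    cb[col_of_x[FLANK + 398 + 2]] = "C"  # rev primer R position (T/C on + strand)
    cultivar_row = "".join(cb)
    aln = GametologAlignment(x_row=x_row, y_row=y_row,
                             extra_rows={"cspds5_cultivarB_chrX": cultivar_row})

    # the consensus over the published footprints must reproduce the
    # published degenerate primers exactly
    fwd_win = (col_of_x[FLANK], col_of_x[FLANK + 19] + 1)
    rev_win = (col_of_x[FLANK + 398], col_of_x[FLANK + 418] + 1)
    fwd, rev = design_degenerate_primers(aln, (fwd_win, rev_win))
    assert fwd.seq == CSPDS5_FWD_PRIMER, fwd.seq
    assert rev.seq == CSPDS5_REV_PRIMER, rev.seq

    # package-level verification of the assay arithmetic
    for g in (x_g, y_g):
        amps = insilico_pcr(g, CSPDS5_FWD_PRIMER, CSPDS5_REV_PRIMER)
        assert len(amps) == 1 and len(amps[0]) == 419
    assert digest(insilico_pcr(y_g, CSPDS5_FWD_PRIMER, CSPDS5_REV_PRIMER)[0],
                  ECO_RI).bands == (157, 262)
    assert digest(insilico_pcr(x_g, CSPDS5_FWD_PRIMER, CSPDS5_REV_PRIMER)[0],
                  ECO_RI).bands == (419,)
    taq_y = insilico_pcr(y_g, TAQMAN_FWD_PRIMER, TAQMAN_REV_PRIMER)
    taq_x = insilico_pcr(x_g, TAQMAN_FWD_PRIMER, TAQMAN_REV_PRIMER)
    assert len(taq_y) == 1 and len(taq_y[0]) == 200
    assert len(taq_x) == 1 and len(taq_x[0]) == 201
    eco_sites = [s for s in scan_differential_sites(aln, [ECO_RI])]
    assert len(eco_sites) == 1 and eco_sites[0].allele_with_site == "Y"
    assert eco_sites[0].site_start == FLANK + SITE_AMP
    return x_g, y_g, aln


def main() -> None:
    for pat, real in ((CSPDS5_FWD_PRIMER, FWD_REAL), (CSPDS5_REV_PRIMER, REV_REAL),
                      (TAQMAN_FWD_PRIMER, TAQF_REAL), (TAQMAN_REV_PRIMER, TAQR_REAL)):
        _assert_realisation(real, pat)

    locus = None
    for seed in range(1000, 1200):
        locus = build_locus(seed)
        if locus is not None:
            print(f"locus built with seed {seed}")
            break
    assert locus is not None, "no seed satisfied the fixture constraints"
    x_g, y_g, aln = locus

    (DATA / "synthetic_s2").mkdir(parents=True, exist_ok=True)
    write_fasta([SeqRecord("cspds5_chrX", x_g), SeqRecord("cspds5_chrY", y_g)],
                DATA / "synthetic_cspds5_genomic.fasta")
    rows = [SeqRecord("cspds5_chrX", aln.x_row), SeqRecord("cspds5_chrY", aln.y_row)]
    rows += [SeqRecord(k, v) for k, v in aln.extra_rows.items()]
    write_fasta(rows, DATA / "synthetic_cspds5_alignment.fasta")
    write_fasta(rows, DATA / "synthetic_s2" / "candY.t9.aln.fasta")

    # 25-record transcript stand-in; candY.t9 carries the worked-example Y locus
    rng = np.random.default_rng(7)
    s1 = []
    for i in range(1, 26):
        seq = y_g if i == 9 else _random_seq(rng, int(rng.integers(300, 800)))
        s1.append(SeqRecord(f"candY.t{i}", seq))
    write_fasta(s1, DATA / "synthetic_s1_transcripts.fasta")

    # five further candidate-gene alignments at varied divergence
    for gene, div, seed in (("candY.t5", 0.02, 11), ("candY.t12", 0.05, 12),
                            ("candY.t18", 0.08, 13), ("candY.t22", 0.10, 14),
                            ("candY.t25", 0.12, 15)):
        x, y, truth = generate_gametolog_pair(length=500, divergence=div,
                                              seed=seed, flank_gap=40)
        write_fasta([SeqRecord(f"{gene}_chrX", truth.alignment.x_row),
                     SeqRecord(f"{gene}_chrY", truth.alignment.y_row)],
                    DATA / "synthetic_s2" / f"{gene}.aln.fasta")
    print("fixtures written to", DATA)


if __name__ == "__main__":
    main()
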