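"""In-silico PCR, digestion, band prediction, genotype calls, TaqMan."""

import pytest
from conftest import random_dna
from hypothesis import given
from hypothesis import strategies as st
from oracles import naive_cut_positions

from sexmarker import (
    BandPattern,
    Genotype,
    RestrictionEnzyme,
    call_genotype,
    cut_positions,
    digest,
    insilico_pcr,
    predict_genotype_bands,
    revcomp,
    simulate_taqman,
)
from sexmarker.assay import FAM, VIC
from sexmarker.fixtures import (
    CSPDS5_FWD_PRIMER,
    CSPDS5_REV_PRIMER,
    FEM_PROBE,
    MALE_PROBE,
    TAQMAN_FWD_PRIMER,
    TAQMAN_REV_PRIMER,
)
from sexmarker.synth import ECO_RI

dna = st.text(alphabet="ACGT", min_size=30, max_size=400)


class TestPcr:
    def test_worked_example_single_419bp_amplicon_each_allele(self, cspds5_genomic):
        for allele in ("X", "Y"):
            amps = insilico_pcr(cspds5_genomic[allele].seq,
                                CSPDS5_FWD_PRIMER, CSPDS5_REV_PRIMER)
            assert len(amps) == 1
            assert len(amps[0]) == 419

    def test_taqman_primers_give_inner_amplicon_with_site(self, cspds5_genomic):
        y = insilico_pcr(cspds5_genomic["Y"].seq, TAQMAN_FWD_PRIMER,
                         TAQMAN_REV_PRIMER)
        x = insilico_pcr(cspds5_genomic["X"].seq, TAQMAN_FWD_PRIMER,
                         TAQMAN_REV_PRIMER)
        assert len(y) == 1 and len(x) == 1
        assert abs(len(y[0]) - 200) <= 5 and abs(len(x[0]) - 200) <= 5
        assert "GAATTC" in y[0].seq and "GAATTC" not in x[0].seq

    def test_no_forward_match_gives_empty(self, rng):
        template = random_dna(rng, 200)
        assert insilico_pcr(template, "GGGGGGGGGGGGCCCCCCCC", "AAAA") == []

    def test_planted_offsets_give_exact_length(self, rng):
        fwd, rev = "GATTACAGATTACAGATT", "CCGGTTAACCGGTTAACC"
        filler = random_dna(rng, 150)
        template = random_dna(rng, 37) + fwd + filler + revcomp(rev) + random_dna(rng, 21)
        amps = [a for a in insilico_pcr(template, fwd, rev)
                if a.start == 37]
        assert amps and len(amps[0]) == len(fwd) + 150 + len(rev)

    def test_degenerate_primer_binds_all_expansions(self):
        template = "TTTT" + "GGACTATC" + "A" * 30 + revcomp("CCTTGG") + "TTTT"
        amps = insilico_pcr(template, "GGAYTATC", "CCTTGG")
        assert len(amps) == 1


class TestDigest:
    def test_worked_example_bands(self, cspds5_genomic):
        y_amp = insilico_pcr(cspds5_genomic["Y"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        x_amp = insilico_pcr(cspds5_genomic["X"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        assert digest(y_amp, ECO_RI).bands == (157, 262)
        assert digest(x_amp, ECO_RI).bands == (419,)

    def test_uncut_gives_full_length(self, rng):
        seq = random_dna(rng, 100).replace("GAATTC", "GAATTG")
        assert digest(seq, ECO_RI).bands == (len(seq),)

    @given(dna)
    def test_fragments_sum_to_amplicon_length(self, seq):
        assert digest(seq, ECO_RI).total() == len(seq)

    @given(dna)
    def test_cut_positions_match_bruteforce_oracle(self, seq):
        assert cut_positions(seq, ECO_RI) == naive_cut_positions(seq, "GAATTC", 1)

    def test_nonpalindromic_both_strands(self, rng):
        enzyme = RestrictionEnzyme("SapI-like", "GCTCTTC", 1)
        seq = ("T" * 50 + "GCTCTTC" + "T" * 50 + revcomp("GCTCTTC") + "T" * 50)
        assert cut_positions(seq, enzyme) == \
            naive_cut_positions(seq, "GCTCTTC", 1)
        assert len(cut_positions(seq, enzyme)) == 2

    def test_revcomp_invariance_for_palindromes(self, rng):
        # exact for a blunt (centre-cutting) palindrome; a sticky-end
        # cutter shifts top-strand fragment bounds by the overhang length
        ecorv = RestrictionEnzyme("EcoRV", "GATATC", 3)
        overhang = len(ECO_RI.recognition) - 2 * ECO_RI.cut_offset
        for _ in range(20):
            seq = random_dna(rng, 300)
            assert digest(seq, ecorv).bands == digest(revcomp(seq), ecorv).bands
            fwd = digest(seq, ECO_RI).bands
            rev = digest(revcomp(seq), ECO_RI).bands
            assert len(fwd) == len(rev)
            assert all(abs(a - b) <= overhang for a, b in zip(fwd, rev))

    def test_n_never_matches_recognition(self):
        seq = "T" * 20 + "GAANTC" + "T" * 20
        assert digest(seq, ECO_RI).bands == (len(seq),)


class TestGenotypeBands:
    def test_worked_example_patterns(self, cspds5_genomic):
        x_amp = insilico_pcr(cspds5_genomic["X"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        y_amp = insilico_pcr(cspds5_genomic["Y"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        patterns = predict_genotype_bands(x_amp, y_amp, ECO_RI)
        assert patterns[Genotype.XX].bands == (419,)
        assert patterns[Genotype.XY].bands == (157, 262, 419)

    def test_xx_is_submultiset_of_xy(self, rng):
        x_amp, y_amp = random_dna(rng, 350), random_dna(rng, 340)
        patterns = predict_genotype_bands(x_amp, y_amp, ECO_RI)
        xy = list(patterns[Genotype.XY].bands)
        for b in patterns[Genotype.XX].bands:
            xy.remove(b)  # raises if not contained

    def test_cutting_neither_allele_is_non_diagnostic(self, rng):
        seq = random_dna(rng, 200).replace("GAATTC", "GAATTG")
        patterns = predict_genotype_bands(seq, seq, ECO_RI)
        assert patterns[Genotype.XX].bands != patterns[Genotype.XY].bands or \
            call_genotype([len(seq)], patterns) == Genotype.ambiguous

    def test_missing_x_amplicon_invalid(self):
        with pytest.raises(ValueError):
            predict_genotype_bands(None, "ACGT" * 30, ECO_RI)


class TestCallGenotype:
    PATTERNS = {Genotype.XX: BandPattern((419,)),
                Genotype.XY: BandPattern((157, 262, 419))}

    @pytest.mark.parametrize("observed,expected", [
        ([419], Genotype.XX),
        ([160, 258, 422], Genotype.XY),
        ([300], Genotype.ambiguous),
        ([157, 262], Genotype.ambiguous),      # full-length band missing
    ])
    def test_gel_reading_rules(self, observed, expected):
        assert call_genotype(observed, self.PATTERNS, 10) == expected

    def test_roundtrip_at_zero_tolerance(self, cspds5_genomic):
        x_amp = insilico_pcr(cspds5_genomic["X"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        y_amp = insilico_pcr(cspds5_genomic["Y"].seq, CSPDS5_FWD_PRIMER,
                             CSPDS5_REV_PRIMER)[0]
        patterns = predict_genotype_bands(x_amp, y_amp, ECO_RI)
        for g in (Genotype.XX, Genotype.XY):
            assert call_genotype(patterns[g].bands, patterns, 0) == g


class TestTaqman:
    def _alleles(self, cspds5_genomic):
        return cspds5_genomic["X"].seq, cspds5_genomic["Y"].seq

    def test_xx_fires_vic_only(self, cspds5_genomic):
        x, y = self._alleles(cspds5_genomic)
        assert simulate_taqman(Genotype.XX, MALE_PROBE, FEM_PROBE, x, y) == {VIC}

    def test_xy_fires_both_dyes(self, cspds5_genomic):
        x, y = self._alleles(cspds5_genomic)
        assert simulate_taqman(Genotype.XY, MALE_PROBE, FEM_PROBE, x, y) == {VIC, FAM}

    def test_no_template_control_is_dark(self, cspds5_genomic):
        x, y = self._alleles(cspds5_genomic)
        assert simulate_taqman(None, MALE_PROBE, FEM_PROBE, x, y) == set()

    def test_probe_matching_neither_allele_rejected(self, cspds5_genomic):
        x, y = self._alleles(cspds5_genomic)
        with pytest.raises(ValueError):
            simulate_taqman(Genotype.XX, "TTTTTTTTTTTTTTTAAAAAGGG", FEM_PROBE, x, y)
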