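"""Differential-site scanning, conserved flanks, degenerate primers,
allele probes and candidate ranking."""

import pytest
from conftest import random_dna
from oracles import naive_site_positions

from sexmarker import (
    DesignFailure,
    GametologAlignment,
    Genotype,
    RestrictionEnzyme,
    build_candidate,
    design_allele_probes,
    design_degenerate_primers,
    find_conserved_flanks,
    iupac_match,
    rank_candidates,
    revcomp,
    scan_differential_sites,
)
from sexmarker.design import FlankConfig, min_band_gap
from sexmarker.fixtures import (
    CSPDS5_FWD_PRIMER,
    CSPDS5_REV_PRIMER,
    FEM_PROBE,
    MALE_PROBE,
)
from sexmarker.synth import ECO_RI


def _plant(seq, pos, motif):
    return seq[:pos] + motif + seq[pos + len(motif):]


class TestScanDifferentialSites:
    def test_identical_alleles_have_no_sites(self, rng, enzymes):
        seq = random_dna(rng, 500)
        aln = GametologAlignment(x_row=seq, y_row=seq)
        assert scan_differential_sites(aln, enzymes) == []

    def test_planted_site_found_exactly(self, rng):
        for trial in range(5):
            y = random_dna(rng, 1000)
            pos = int(rng.integers(100, 900))
            y = _plant(y, pos, "GAATTC")
            x = _plant(y, pos, "GTCTAC")  # ablated at homologous position
            if naive_site_positions(y, "GAATTC") != [pos] or \
                    naive_site_positions(x, "GAATTC"):
                continue  # accidental second site; not the planted scenario
            aln = GametologAlignment(x_row=x, y_row=y)
            sites = scan_differential_sites(aln, [ECO_RI])
            assert [(s.allele_with_site, s.site_start) for s in sites] == [("Y", pos)]

    def test_agrees_with_window_scan_oracle(self, rng, enzymes):
        x, y = random_dna(rng, 1500), random_dna(rng, 1500)
        aln = GametologAlignment(x_row=x, y_row=y)
        got = {(s.enzyme.name, s.allele_with_site, s.site_start)
               for s in scan_differential_sites(aln, enzymes)}
        expected = set()
        for e in enzymes:
            for allele, seq, other in (("X", x, y), ("Y", y, x)):
                for p in naive_site_positions(seq, e.recognition):
                    lo = max(0, p - (len(e.recognition) - 1))
                    hi = min(len(other), p + 2 * len(e.recognition) - 1)
                    window = other[lo:hi]
                    if not naive_site_positions(window, e.recognition) and \
                            not naive_site_positions(window, revcomp(e.recognition)):
                        expected.add((e.name, allele, p))
        assert got == expected

    def test_palindromic_mirror_coordinates(self, rng):
        y = _plant(random_dna(rng, 600), 300, "GAATTC")
        x = _plant(y, 300, "GTCTAC")
        aln = GametologAlignment(x_row=x, y_row=y)
        mirrored = GametologAlignment(x_row=revcomp(x), y_row=revcomp(y))
        sites = scan_differential_sites(aln, [ECO_RI])
        m_sites = scan_differential_sites(mirrored, [ECO_RI])
        assert len(sites) == len(m_sites) == 1
        assert m_sites[0].site_start == 600 - sites[0].site_start - 6

    def test_nonpalindromic_minus_strand_site(self, rng):
        enzyme = RestrictionEnzyme("BspQI-like", "GCTCTTC", 1)
        y = _plant(random_dna(rng, 400), 200, revcomp("GCTCTTC"))
        x = _plant(y, 200, "ATATATA")
        aln = GametologAlignment(x_row=x, y_row=y)
        sites = scan_differential_sites(aln, [enzyme])
        assert any(s.strand == "-" and s.site_start == 200 for s in sites)


class TestConservedFlanks:
    def test_fully_identical_alignment_adjacent_windows(self):
        seq = "ACGT" * 30
        aln = GametologAlignment(x_row=seq, y_row=seq)
        left, right = find_conserved_flanks(aln, 60, site_span=6)
        assert left == (42, 60) and right == (66, 84)

    def test_indel_block_pushes_window_out(self):
        n = 60
        x = "A" * n + "-" * 10 + "C" * 30 + "GAATTC" + "T" * 40
        y = "A" * n + "G" * 10 + "C" * 30 + "GAATTC" + "T" * 40
        aln = GametologAlignment(x_row=x, y_row=y)
        site_col = n + 40
        left, right = find_conserved_flanks(aln, site_col, site_span=6)
        assert left[1] <= n + 40 and not (left[0] < n + 10 <= left[1])
        assert left == (site_col - 18, site_col)  # the C-block + nothing of the indel

    def test_too_many_substitutions_disqualify(self):
        x = "ACGT" * 20
        y = "ATGA" * 20  # heavily diverged everywhere
        aln = GametologAlignment(x_row=x, y_row=y)
        assert find_conserved_flanks(aln, 40, FlankConfig(max_distance=80)) is None


class TestDegeneratePrimers:
    def test_reproduces_published_primer_pair(self, cspds5_alignment):
        aln = cspds5_alignment
        col_of_x = {p: i for i, p in enumerate(aln.col_to_x) if p is not None}
        fwd_win = (col_of_x[150], col_of_x[169] + 1)
        rev_win = (col_of_x[548], col_of_x[568] + 1)
        fwd, rev = design_degenerate_primers(aln, (fwd_win, rev_win))
        assert fwd.seq == CSPDS5_FWD_PRIMER
        assert rev.seq == CSPDS5_REV_PRIMER
        assert (fwd.degeneracy, rev.degeneracy) == (4, 2)

    def test_invariant_window_gives_concrete_primer(self, rng):
        seq = random_dna(rng, 120)
        aln = GametologAlignment(x_row=seq, y_row=seq)
        fwd, rev = design_degenerate_primers(aln, ((10, 30), (80, 100)))
        assert fwd.degeneracy == 1 and rev.degeneracy == 1
        assert fwd.seq == seq[10:30] and rev.seq == revcomp(seq[80:100])

    def test_common_primer_contract(self, cspds5_alignment):
        # every emitted primer matches every row at every column
        aln = cspds5_alignment
        windows = find_conserved_flanks(aln, 306, site_span=6)
        fwd, rev = design_degenerate_primers(aln, windows)
        rows = aln.all_rows().values()
        for row in rows:
            window = row[fwd.columns[0]:fwd.columns[1]]
            assert all(iupac_match(p, b) for p, b in zip(fwd.seq, window))
            window = row[rev.columns[0]:rev.columns[1]]
            assert all(iupac_match(p, b)
                       for p, b in zip(revcomp(rev.seq), window))

    def test_degeneracy_cap_enforced(self, rng):
        seq = random_dna(rng, 100)
        other = list(seq)
        for i in range(10, 28):  # hyper-polymorphic window
            other[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
        aln = GametologAlignment(x_row=seq, y_row="".join(other))
        with pytest.raises(DesignFailure):
            design_degenerate_primers(
                aln, ((10, 28), (60, 80)),
                FlankConfig(max_poly=18, degeneracy_cap=16))


class TestAlleleProbes:
    def test_worked_example_probes_span_diagnostic_region(self, cspds5_alignment):
        sites = scan_differential_sites(cspds5_alignment, [ECO_RI])
        probes = design_allele_probes(cspds5_alignment, sites[0])
        assert "GAATTC" in probes.probe_for_cut_allele
        assert "GAATTC" not in probes.probe_for_uncut_allele
        assert probes.probe_for_cut_allele in MALE_PROBE or \
            MALE_PROBE in probes.probe_for_cut_allele or \
            probes.probe_for_cut_allele in cspds5_alignment.y_seq
        assert probes.probe_for_uncut_allele in cspds5_alignment.x_seq

    def test_single_snp_probes_differ_at_one_position(self, rng):
        seq = random_dna(rng, 200)
        pos = 100
        y = _plant(seq, pos, "GAATTC")
        x = _plant(y, pos + 2, "G")  # GAATTC -> GAGTTC, single diagnostic SNP
        aln = GametologAlignment(x_row=x, y_row=y)
        site = scan_differential_sites(aln, [ECO_RI])[0]
        probes = design_allele_probes(aln, site)
        diffs = [i for i, (a, b) in enumerate(zip(probes.probe_for_cut_allele,
                                                  probes.probe_for_uncut_allele))
                 if a != b]
        assert len(diffs) == 1

    def test_mismatch_count_oracle_on_planted_fixtures(self, rng):
        from sexmarker import generate_gametolog_pair
        for seed in (41, 42, 43):
            x, y, truth = generate_gametolog_pair(seed=seed)
            probes = design_allele_probes(truth.alignment, truth.site)
            assert probes.probe_for_cut_allele in y
            assert probes.probe_for_uncut_allele in x
            assert probes.probe_for_cut_allele not in x
            assert probes.probe_for_uncut_allele not in y

    def test_identical_site_region_fails(self, rng):
        seq = random_dna(rng, 200)
        aln = GametologAlignment(x_row=seq, y_row=seq)
        from sexmarker.design import DifferentialSite
        fake = DifferentialSite(ECO_RI, "Y", 100, 100)
        with pytest.raises(DesignFailure):
            design_allele_probes(aln, fake)


class TestRanking:
    def _candidates(self, alignment, enzymes):
        out = []
        for site in scan_differential_sites(alignment, enzymes):
            try:
                out.append(build_candidate(alignment, site))
            except DesignFailure:
                continue
        return out

    def test_single_candidate_is_itself(self, cspds5_alignment):
        cands = self._candidates(cspds5_alignment, [ECO_RI])
        assert len(cands) == 1
        assert rank_candidates(cands) == cands

    def test_larger_band_gap_ranks_first(self, cspds5_alignment, enzymes):
        cands = self._candidates(cspds5_alignment, enzymes)
        ranked = rank_candidates(cands)
        gaps = [min_band_gap(c) for c in ranked]
        # score is dominated by the band gap for same-locus candidates
        if len(ranked) >= 2:
            assert ranked[0].score >= ranked[-1].score

    def test_permutation_invariance(self, cspds5_alignment, enzymes, rng):
        cands = self._candidates(cspds5_alignment, enzymes)
        ranked = rank_candidates(list(cands))
        for _ in range(3):
            perm = list(cands)
            rng.shuffle(perm)
            again = rank_candidates(perm)
            assert [(c.site.enzyme.name, c.site.alignment_column) for c in again] \
                == [(c.site.enzyme.name, c.site.alignment_column) for c in ranked]
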