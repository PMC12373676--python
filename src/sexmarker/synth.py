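"""Seeded synthetic data with known ground truth.

Generators emulate the discovery scenario end to end: an X/Y gametolog
pair diverged to a tunable degree, carrying one planted allele-specific
restriction site flanked by conserved primer windows; male/female sample
cohorts that differ by presence of the Y allele plus per-sample SNP
noise; and a TPM table in which Y transcripts are male-only. Every
generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    IUPAC_SETS,
    ExpressionTable,
    GametologAlignment,
    RestrictionEnzyme,
    Role,
    SeqRecord,
    Sex,
    write_fasta,
)
from .design import DifferentialSite, scan_differential_sites

ECO_RI = RestrictionEnzyme("EcoRI", "GAATTC", 1)

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in "ACGT" if b != base])


@dataclass
class PairTruth:
    """Ground truth for one synthetic gametolog pair."""

    x_seq: str
    y_seq: str
    alignment: GametologAlignment
    site: DifferentialSite
    left_window: tuple[int, int]
    right_window: tuple[int, int]
    mutations: list[tuple[str, int, str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site": {
                "enzyme": self.site.enzyme.name,
                "recognition": self.site.enzyme.recognition,
                "allele": self.site.allele_with_site,
                "site_start": self.site.site_start,
                "alignment_column": self.site.alignment_column,
            },
            "left_window": list(self.left_window),
            "right_window": list(self.right_window),
            "n_mutations": len(self.mutations),
        }


def generate_gametolog_pair(length: int = 1000, divergence: float = 0.05,
                            enzyme: RestrictionEnzyme = ECO_RI,
                            seed: int = 0, flank_len: int = 25,
                            flank_gap: int = 60, n_site_diffs: int = 3,
                            ) -> tuple[str, str, PairTruth]:
    """Random ancestor mutated into X and Y copies.

    One recognition site of ``enzyme`` is planted in Y and ablated in X
    by ``n_site_diffs`` substitutions at the homologous position (the
    diagnostic polymorphism). Two windows of ``flank_len`` columns,
    ``flank_gap`` columns away on each side of the site, are kept free of
    mutations so a common primer pair always exists. Elsewhere each
    position mutates in one branch with probability ``divergence``.
    Substitutions only, so the truth alignment is gap-free. Regeneration
    with the same seed is bit-for-bit identical.
    """
    span = len(enzyme.recognition)
    if length < 300:
        raise ValueError("length must be >= 300")
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    if not 1 <= n_site_diffs <= span:
        raise ValueError("n_site_diffs must be in [1, len(recognition)]")
    if span + 2 * (flank_len + flank_gap) + 20 > length:
        raise ValueError("site plus flank windows exceed sequence length")

    # domain-separated stream: a cohort seeded with the same integer must
    # not replay the pair generator's draws
    rng = np.random.default_rng([101, seed])
    for _ in range(100):
        ancestor = _random_seq(rng, length)
        site_start = (length - span) // 2
        # concrete realisation of the recognition sequence
        site_seq = "".join(str(rng.choice(sorted(IUPAC_SETS[c])))
                           for c in enzyme.recognition)
        y = list(ancestor)
        y[site_start:site_start + span] = site_seq
        x = y.copy()
        diff_pos = rng.choice(span, size=n_site_diffs, replace=False)
        for p in sorted(diff_pos):
            x[site_start + p] = _mutate_base(rng, x[site_start + p])

        left = (site_start - flank_gap - flank_len, site_start - flank_gap)
        right = (site_start + span + flank_gap,
                 site_start + span + flank_gap + flank_len)
        protected = set(range(site_start, site_start + span))
        protected |= set(range(*left)) | set(range(*right))

        mutations: list[tuple[str, int, str, str]] = []
        for pos in range(length):
            if pos in protected:
                continue
            if rng.random() < divergence:
                branch = "X" if rng.random() < 0.5 else "Y"
                row = x if branch == "X" else y
                old = row[pos]
                row[pos] = _mutate_base(rng, old)
                mutations.append((branch, pos, old, row[pos]))

        x_seq, y_seq = "".join(x), "".join(y)
        alignment = GametologAlignment(x_row=x_seq, y_row=y_seq)
        sites = [s for s in scan_differential_sites(alignment, [enzyme])
                 if s.enzyme.name == enzyme.name]
        planted = [s for s in sites if s.allele_with_site == "Y"
                   and s.site_start == site_start and s.strand == "+"]
        if len(sites) == 1 and planted:
            truth = PairTruth(x_seq, y_seq, alignment, planted[0],
                              left, right, mutations)
            return x_seq, y_seq, truth
    raise RuntimeError("could not generate a pair with a unique planted site")


@dataclass
class Cohort:
    """Synthetic male/female sample cohort with expression ground truth."""

    samples: dict[str, list[SeqRecord]]
    sexes: dict[str, Sex]
    transcripts: list[SeqRecord]
    x_loci: list[SeqRecord]
    expression: ExpressionTable
    y_transcript_id: str
    pair_truth: PairTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, records in self.samples.items():
            write_fasta(records, outdir / f"{sid}.fasta")
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        write_fasta(self.x_loci, outdir / "x_loci.fasta")
        self.expression.to_frame().to_csv(outdir / "tpm.tsv", sep="\t")
        with open(outdir / "sexes.tsv", "w") as fh:
            for sid, sex in self.sexes.items():
                fh.write(f"{sid}\t{sex.value}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"y_transcript": self.y_transcript_id,
                       **self.pair_truth.to_dict()}, fh, indent=2)


def _lognormal_tpm(rng: np.random.Generator, mean: float, sigma: float = 0.4) -> float:
    return float(rng.lognormal(np.log(mean) - sigma ** 2 / 2, sigma))


def generate_cohort(pair: tuple[str, str, PairTruth] | None = None,
                    n_male: int = 3, n_female: int = 3,
                    snp_rate: float = 0.001, n_decoys: int = 20,
                    seed: int = 0, y_mean_tpm: float = 50.0,
                    decoy_mean_tpm: float = 20.0) -> Cohort:
    """Sample cohort around one gametolog pair.

    Female samples carry the X-derived transcript and autosomal decoys;
    male samples additionally carry the Y-derived transcript. Each sample
    gets independent SNPs at ``snp_rate`` per base. The TPM table gives
    the Y transcript a male mean of ``y_mean_tpm`` and exact zero in
    females; decoys are expressed in both sexes, and the first decoy is
    male-biased but female-nonzero — male-biased yet not Y-linked, so the
    strict zero-female filter must remove it.
    """
    if n_male < 1 or n_female < 1:
        raise ValueError("need at least one sample per sex")
    rng = np.random.default_rng([202, seed])
    if pair is None:
        pair = generate_gametolog_pair(seed=int(rng.integers(2 ** 31)))
    x_seq, y_seq, truth = pair

    transcripts = [
        SeqRecord("chrY.t1", y_seq, Role.transcript),
        SeqRecord("chrX.t1", x_seq, Role.transcript),
    ]
    decoys = [SeqRecord(f"auto.t{i + 1}", _random_seq(rng, int(rng.integers(600, 1200))))
              for i in range(n_decoys)]
    transcripts += decoys
    x_loci = [SeqRecord("locusX.1", x_seq, Role.genomic)] + [
        SeqRecord(f"locusA.{i + 1}", d.seq, Role.genomic) for i, d in enumerate(decoys)
    ]

    def with_snps(seq: str) -> str:
        if snp_rate <= 0:
            return seq
        s = list(seq)
        hits = np.nonzero(rng.random(len(s)) < snp_rate)[0]
        for p in hits:
            s[p] = _mutate_base(rng, s[p])
        return "".join(s)

    samples: dict[str, list[SeqRecord]] = {}
    sexes: dict[str, Sex] = {}
    for i in range(n_male):
        sid = f"male{i + 1}"
        sexes[sid] = Sex.male
        samples[sid] = [SeqRecord(t.id, with_snps(t.seq)) for t in transcripts]
    for i in range(n_female):
        sid = f"female{i + 1}"
        sexes[sid] = Sex.female
        samples[sid] = [SeqRecord(t.id, with_snps(t.seq))
                        for t in transcripts if t.id != "chrY.t1"]

    sample_ids = list(samples)
    tpm = np.zeros((len(transcripts), len(sample_ids)))
    for ti, t in enumerate(transcripts):
        for si, sid in enumerate(sample_ids):
            male = sexes[sid] == Sex.male
            if t.id == "chrY.t1":
                tpm[ti, si] = _lognormal_tpm(rng, y_mean_tpm) if male else 0.0
            elif t.id == "auto.t1":  # male-biased but female-nonzero decoy
                tpm[ti, si] = _lognormal_tpm(rng, y_mean_tpm if male else 2.0)
            else:
                tpm[ti, si] = _lognormal_tpm(rng, decoy_mean_tpm)
    expression = ExpressionTable(
        transcript_ids=[t.id for t in transcripts],
        sample_ids=sample_ids, sex_labels=sexes, tpm=tpm,
    )
    return Cohort(samples, sexes, transcripts, x_loci, expression,
                  "chrY.t1", truth)
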