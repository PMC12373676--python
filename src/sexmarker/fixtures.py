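"""Packaged example data: the CsPDS5-style worked example and synthetic
stand-ins for the candidate-gene supplementary sets.

The oligos below are the published CsPDS5 sex-genotyping reagents for
Cannabis sativa: a common degenerate primer pair amplifying a 419 bp
region of both gametolog copies, TaqMan primers for a ~200 bp inner
fragment, and the two allele-discrimination probes (Y/FAM probe spanning
the EcoRI site, X/VIC probe spanning the homologous X sequence).

The packaged X/Y sequences are SYNTHETIC reconstructions (the real loci
are not redistributed here): random backbones with the published primer
and probe footprints and the allele-differential EcoRI site planted so
that the assay arithmetic matches the published marker — one 419 bp
amplicon per allele, Y digest 157 + 262 bp, X uncut. Likewise the
``synthetic_s1``/``synthetic_s2`` files mimic only the shape of the
candidate sets (25 Y-transcript records; 6 candidate-gene alignments).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import GametologAlignment, SeqRecord, read_fasta

# Published CsPDS5-CAPS genotyping primers (degenerate; common to X and Y)
CSPDS5_FWD_PRIMER = "GGAYTATCATCCAGAGAMTG"
CSPDS5_REV_PRIMER = "TACCATATTCTCATCAGARGC"

# Published TaqMan primers and allele-discrimination probes
TAQMAN_FWD_PRIMER = "TATTYCAWTGGAGCTTCTCACC"
TAQMAN_REV_PRIMER = "AACCTTMGKAGCACAKRTTTC"
MALE_PROBE = "AGTTACAGTTTGGAATTCCTTT"   # Y allele, FAM; spans GAATTC
FEM_PROBE = "TGTCCGAATTACAGATTACATTT"   # X allele, VIC

CSPDS5_AMPLICON_LEN = 419
CSPDS5_Y_BANDS = (157, 262)


def _data(name: str) -> Path:
    return Path(resources.files("sexmarker").joinpath("data", name))


def enzyme_table_path() -> Path:
    return _data("enzymes.tsv")


def cspds5_genomic() -> dict[str, SeqRecord]:
    """Synthetic X and Y genomic loci of the worked example, keyed 'X'/'Y'."""
    records = read_fasta(_data("synthetic_cspds5_genomic.fasta"))
    return {("X" if "chrX" in r.id else "Y"): r for r in records}


def cspds5_alignment() -> GametologAlignment:
    """Synthetic X/Y (+ one extra cultivar row) alignment of the worked
    example locus."""
    return GametologAlignment.from_fasta(
        _data("synthetic_cspds5_alignment.fasta"),
        x_id="cspds5_chrX", y_id="cspds5_chrY")


def s1_transcripts() -> list[SeqRecord]:
    """Synthetic stand-in for the 25-record Y-transcript candidate set."""
    return read_fasta(_data("synthetic_s1_transcripts.fasta"))


def s2_alignment_paths() -> list[Path]:
    """Synthetic stand-ins for the 6 candidate-gene alignment files."""
    d = _data("synthetic_s2")
    return sorted(d.glob("*.fasta"))


def s2_alignments() -> dict[str, GametologAlignment]:
    return {p.stem: GametologAlignment.from_fasta(p)
            for p in s2_alignment_paths()}
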