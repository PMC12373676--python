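"""Domain types, sequence/enzyme/expression I/O and IUPAC algebra.

Coordinates are 0-based, half-open everywhere, including machine-readable
reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"

#: IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC code for each base set (inverse of IUPAC_SETS).
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", GAP: GAP,
}


class AlphabetError(ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


class FastaFormatError(ValueError):
    """A FASTA record violated the format contract."""


class Role(str, enum.Enum):
    transcript = "transcript"
    genomic = "genomic"
    amplicon = "amplicon"
    primer = "primer"
    probe = "probe"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Genotype(str, enum.Enum):
    XX = "XX"
    XY = "XY"
    ambiguous = "ambiguous"


def _check_alphabet(seq: str, allow_gap: bool = False) -> None:
    allowed = set(IUPAC_SETS)
    if allow_gap:
        allowed.add(GAP)
    bad = set(seq.upper()) - allowed
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence with its functional role."""

    id: str
    seq: str
    role: Role = Role.transcript

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        _check_alphabet(self.seq, allow_gap=True)
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


def iupac_match(pattern_char: str, base_char: str) -> bool:
    """True iff the IUPAC base sets of the two characters intersect."""
    try:
        p = IUPAC_SETS[pattern_char.upper()]
        b = IUPAC_SETS[base_char.upper()]
    except KeyError as exc:
        raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from exc
    return bool(p & b)


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (Y<->R, M<->K, W<->W, ...)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from exc


def expand_iupac(seq: str) -> list[str]:
    """All concrete A/C/G/T realisations of a degenerate sequence."""
    outs = [""]
    for c in seq.upper():
        try:
            bases = sorted(IUPAC_SETS[c])
        except KeyError as exc:
            raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from exc
        outs = [o + b for o in outs for b in bases]
    return outs


def degeneracy(seq: str) -> int:
    """Product of per-base IUPAC set sizes (1 for a fully concrete oligo)."""
    d = 1
    for c in seq.upper():
        try:
            d *= len(IUPAC_SETS[c])
        except KeyError as exc:
            raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from exc
    return d


def iupac_code_for(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering the union of the given codes' base sets."""
    union: frozenset[str] = frozenset()
    for b in bases:
        try:
            union |= IUPAC_SETS[b.upper()]
        except KeyError as exc:
            raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from exc
    if not union:
        raise AlphabetError("empty base set")
    return _SET_TO_CODE[union]


# ---------------------------------------------------------------------------
# Restriction enzymes


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC recognition sequence and the
    top-strand cut position measured from the recognition start.

    Band sizes downstream are computed from top-strand cut coordinates;
    sticky-end overhangs are ignored because gel bands are double-stranded
    lengths.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        _check_alphabet(self.recognition)
        object.__setattr__(self, "recognition", self.recognition.upper())
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition shorter than 4 nt")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset out of range")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


def read_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Read a TSV with columns name, recognition, cut_offset."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "recognition", "cut_offset"} - set(df.columns)
    if missing:
        raise ValueError(f"enzyme table missing columns: {sorted(missing)}")
    return [
        RestrictionEnzyme(str(r["name"]), str(r["recognition"]), int(r["cut_offset"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)


def read_fasta(path: str | Path, keep_gaps: bool = False,
               role: Role = Role.transcript) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, in file order.

    Gap characters are retained only when ``keep_gaps`` is set (alignment
    input); otherwise they are stripped.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not keep_gaps:
            seq = seq.replace(GAP, "").replace(".", "")
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, seq, role))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Expression tables


@dataclass
class ExpressionTable:
    """Transcript x sample TPM matrix with per-sample sex labels."""

    transcript_ids: list[str]
    sample_ids: list[str]
    sex_labels: dict[str, Sex]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError("tpm matrix shape does not match id lists")
        if (self.tpm < 0).any():
            raise ValueError("negative TPM entries")
        unlabeled = [s for s in self.sample_ids if s not in self.sex_labels]
        if unlabeled:
            raise ValueError(f"samples without sex label: {unlabeled}")

    def columns_for(self, sex: Sex) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids)
                if self.sex_labels[s] == sex]

    @classmethod
    def from_tsv(cls, expr_path: str | Path, sexes_path: str | Path) -> "ExpressionTable":
        """Load a TPM TSV (first column transcript id, header row sample ids)
        and a two-column sample/sex TSV."""
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        sx = pd.read_csv(sexes_path, sep="\t", header=None,
                         names=["sample", "sex"], comment="#")
        labels = {str(r["sample"]): Sex(str(r["sex"]).lower()) for _, r in sx.iterrows()}
        return cls(
            transcript_ids=[str(t) for t in df.index],
            sample_ids=[str(s) for s in df.columns],
            sex_labels=labels,
            tpm=df.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tpm, index=self.transcript_ids, columns=self.sample_ids)


@dataclass
class FilterConfig:
    """Thresholds for the k-mer sieve and expression filters.

    Defaults follow the discovery pipeline this package implements:
    16-mers for the male/female presence-absence sieve, mean male TPM > 10
    with zero TPM in every female sample for the strict filter, and
    log2FC >= 1 at BH FDR <= 0.05 for the male-bias test.
    """

    k: int = 16
    min_male_mean_tpm: float = 10.0
    max_female_tpm: float = 0.0
    min_log2fc: float = 1.0
    max_fdr: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be >= 4")
        for name in ("min_male_mean_tpm", "max_female_tpm", "min_log2fc",
                     "max_fdr", "pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Gametolog alignments


class ColumnClass(str, enum.Enum):
    identical = "identical"
    substitution = "substitution"
    indel = "indel"


@dataclass
class GametologAlignment:
    """Pairwise (optionally multi-cultivar) alignment of the X and Y copies
    of a gene, with per-column classification and coordinate maps."""

    x_row: str
    y_row: str
    extra_rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_row = self.x_row.upper()
        self.y_row = self.y_row.upper()
        self.extra_rows = {k: v.upper() for k, v in self.extra_rows.items()}
        rows = [self.x_row, self.y_row, *self.extra_rows.values()]
        if len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows have unequal lengths")
        for r in rows:
            _check_alphabet(r, allow_gap=True)
        if not self.x_row:
            raise ValueError("empty alignment")

    def __len__(self) -> int:
        return len(self.x_row)

    @property
    def x_seq(self) -> str:
        return self.x_row.replace(GAP, "")

    @property
    def y_seq(self) -> str:
        return self.y_row.replace(GAP, "")

    @property
    def column_classes(self) -> list[ColumnClass]:
        """Classification of each column from the X/Y rows alone."""
        out = []
        for a, b in zip(self.x_row, self.y_row):
            if a == GAP or b == GAP:
                out.append(ColumnClass.indel)
            elif a == b:
                out.append(ColumnClass.identical)
            else:
                out.append(ColumnClass.substitution)
        return out

    def conservation_classes(self) -> list[ColumnClass]:
        """Column classes over every row (X, Y and extra cultivars); used
        when hunting conserved primer windows across cultivars."""
        rows = [self.x_row, self.y_row, *self.extra_rows.values()]
        out = []
        for col in zip(*rows):
            if GAP in col:
                out.append(ColumnClass.indel)
            elif len(set(col)) == 1:
                out.append(ColumnClass.identical)
            else:
                out.append(ColumnClass.substitution)
        return out

    def all_rows(self) -> dict[str, str]:
        return {"X": self.x_row, "Y": self.y_row, **self.extra_rows}

    def col_to_pos(self, row: str) -> list[int | None]:
        """Map alignment column -> 0-based ungapped position (None at gaps)."""
        out: list[int | None] = []
        pos = 0
        for c in row:
            if c == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out

    @property
    def col_to_x(self) -> list[int | None]:
        return self.col_to_pos(self.x_row)

    @property
    def col_to_y(self) -> list[int | None]:
        return self.col_to_pos(self.y_row)

    def divergence(self) -> float:
        """(substitution + indel columns) / alignment length, X vs Y.

        Each indel column counts once regardless of gap length.
        """
        classes = self.column_classes
        diff = sum(1 for c in classes if c != ColumnClass.identical)
        return diff / len(classes)

    @classmethod
    def from_fasta(cls, path: str | Path, x_id: str | None = None,
                   y_id: str | None = None) -> "GametologAlignment":
        """Load a gapped FASTA alignment.

        Rows are assigned by id: the X row is ``x_id`` if given, else the
        first id containing 'X' (case-insensitive, e.g. 'chrX'); likewise
        for Y. Remaining rows become extra cultivar rows.
        """
        records = read_fasta(path, keep_gaps=True)
        by_id = {r.id: r.seq for r in records}
        if x_id is None:
            x_id = next((i for i in by_id if "X" in i.upper()), records[0].id)
        if y_id is None:
            y_id = next((i for i in by_id if "Y" in i.upper() and i != x_id),
                        records[1].id if len(records) > 1 else records[0].id)
        extra = {i: s for i, s in by_id.items() if i not in (x_id, y_id)}
        return cls(x_row=by_id[x_id], y_row=by_id[y_id], extra_rows=extra)


# ---------------------------------------------------------------------------
# Band patterns


@dataclass(frozen=True)
class BandPattern:
    """Multiset of DNA fragment lengths (bp) seen as bands on a gel."""

    bands: tuple[int, ...]
    genotype_call: Genotype | None = None

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.bands):
            raise ValueError("fragment lengths must be >= 1 bp")
        object.__setattr__(self, "bands", tuple(sorted(self.bands)))

    def __iter__(self):
        return iter(self.bands)

    def total(self) -> int:
        return sum(self.bands)
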