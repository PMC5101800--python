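"""Frame-aware codon counting for coding sequences.

The per-gene codon frequency vector is the basic observable of every
downstream statistic: for gene *g* and sense codon *c*,

    x_{g,c} = count_{g,c} / (number of sense codons counted in g).

Frequencies are defined over the 61 sense codons only.  Stop triplets --
which occur at CDS ends and, abundantly, in artificially frameshifted
readings -- are counted but excluded from the frequency vector, so that
frame-0 and frameshift-control analyses share the same 61-codon support.

Frameshift controls re-read a CDS after skipping one or two nucleotides at
the 5' end.  They destroy codon identity while approximately preserving
nucleotide composition, which is what makes them a control for
codon-specific effects.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
#: canonical column order of every frequency matrix: the 61 sense codons,
#: alphabetical.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: amino acid -> tuple of synonymous sense codons (standard code)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD_CODE.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)


class CdsError(ValueError):
    """Raised for malformed coding sequences or FASTA input."""


@dataclass(frozen=True)
class FrameShift:
    """Number of nucleotides skipped at the 5' end before re-reading triplets."""

    offset: int = 0

    def __post_init__(self) -> None:
        if self.offset not in (0, 1, 2):
            raise ValueError(f"frameshift offset must be 0, 1 or 2, got {self.offset}")


@dataclass(frozen=True)
class CodingSequence:
    """A single CDS; the sequence is uppercased A/C/G/T, length >= 3."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise CdsError(f"{self.gene_id}: CDS shorter than one codon ({len(seq)} nt)")
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise CdsError(f"{self.gene_id}: non-ACGT characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self, shift: FrameShift | int = 0) -> Iterator[str]:
        """Yield complete triplets read from ``shift.offset``; a trailing
        partial triplet is dropped."""
        offset = shift.offset if isinstance(shift, FrameShift) else FrameShift(shift).offset
        seq = self.sequence
        for i in range(offset, len(seq) - 2, 3):
            yield seq[i : i + 3]

    def validate_orf(self) -> list[str]:
        """Return a list of strict-mode violations of the frame-0 reading
        (non-triplet length, internal stop codons)."""
        problems = []
        if len(self.sequence) % 3 != 0:
            problems.append(f"length {len(self.sequence)} not a multiple of 3")
        triplets = list(self.codons(0))
        for j, t in enumerate(triplets[:-1]):
            if t in STOP_CODONS:
                problems.append(f"internal stop {t} at codon {j + 1}")
                break
        return problems


@dataclass
class CodonProfile:
    """Codon usage of one gene in one reading frame.

    ``counts`` covers all 64 triplets, ``n_counted`` is the total number of
    complete triplets read, and ``frequencies`` covers the sense codons with
    denominator ``n_sense`` (= n_counted minus stop triplets).
    """

    gene_id: str
    counts: Mapping[str, int]
    n_counted: int
    frame: FrameShift = field(default_factory=FrameShift)

    @property
    def n_sense(self) -> int:
        return self.n_counted - sum(self.counts.get(s, 0) for s in STOP_CODONS)

    @property
    def frequencies(self) -> dict[str, float]:
        ns = self.n_sense
        if ns == 0:
            return {c: float("nan") for c in SENSE_CODONS}
        return {c: self.counts.get(c, 0) / ns for c in SENSE_CODONS}

    def sense_counts(self) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in SENSE_CODONS}


def parse_cds(fasta_source, strict: bool = False) -> list[CodingSequence]:
    """Read coding sequences from FASTA (path or handle).

    Lowercase input is uppercased.  Duplicate record ids raise ``CdsError``.
    Records with non-ACGT characters are dropped with a warning (``strict``:
    error).  In strict mode the frame-0 reading must be a whole number of
    codons with no internal stop.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        warnings.warn("empty FASTA input: no coding sequences parsed", stacklevel=2)
        return []
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise CdsError(f"duplicate gene id {rec.id!r} in FASTA input")
        seen.add(rec.id)
        try:
            cds = CodingSequence(rec.id, str(rec.seq))
        except CdsError as exc:
            if strict:
                raise
            warnings.warn(f"dropping record: {exc}", stacklevel=2)
            continue
        problems = cds.validate_orf()
        if problems:
            msg = f"{cds.gene_id}: " + "; ".join(problems)
            if strict:
                raise CdsError(msg)
            warnings.warn(msg, stacklevel=2)
        out.append(cds)
    return out


def codon_counts(seq: CodingSequence, shift: FrameShift | int = 0) -> CodonProfile:
    """Count triplets of ``seq`` read in the given frame.

    Counts cover all 64 triplets; stop triplets contribute to ``n_counted``
    but not to the frequency vector.
    """
    fs = shift if isinstance(shift, FrameShift) else FrameShift(shift)
    if len(seq) - fs.offset < 3:
        raise CdsError(
            f"{seq.gene_id}: no complete codon after +{fs.offset} shift "
            f"(length {len(seq)})"
        )
    counts = Counter(seq.codons(fs))
    return CodonProfile(
        gene_id=seq.gene_id,
        counts=dict(counts),
        n_counted=sum(counts.values()),
        frame=fs,
    )


def codon_frequency_matrix(profiles: Iterable[CodonProfile]) -> pd.DataFrame:
    """Stack per-gene sense-codon frequencies into a gene x 61 matrix.

    Rows are ordered by gene id, columns by the canonical (alphabetical)
    sense-codon order; a gene with no sense codons yields an all-NaN row.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no codon profiles supplied")
    rows = {p.gene_id: p.frequencies for p in profiles}
    mat = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    mat = mat.reindex(columns=list(SENSE_CODONS)).sort_index()
    mat.index.name = "gene_id"
    return mat


def count_matrix(profiles: Iterable[CodonProfile]) -> pd.DataFrame:
    """Gene x 61 matrix of raw sense-codon counts (same ordering contract as
    :func:`codon_frequency_matrix`)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no codon profiles supplied")
    rows = {p.gene_id: p.sense_counts() for p in profiles}
    mat = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    mat = mat.reindex(columns=list(SENSE_CODONS)).sort_index()
    mat.index.name = "gene_id"
    return mat


def frequency_matrix_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a sense-codon count matrix to frequencies."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts.to_numpy(dtype=float) / totals[:, None]
    return pd.DataFrame(freq, index=counts.index, columns=counts.columns)


def write_frequency_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.10g")


def read_frequency_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
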