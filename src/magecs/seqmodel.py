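"""Core sequence and codon machinery.

Coordinate conventions used across the package:

* internally everything is 0-based, half-open ``[start, end)``;
* every user-facing report converts to 1-based inclusive coordinates;
* circular records wrap: slices and windows may cross the origin, and all
  stored feature coordinates are normalised into ``[0, len)``.

Sequences are uppercase DNA over ``{A, C, G, T}``.  IUPAC ambiguity codes
are rejected by default because a design computed on an ambiguous base is
unverifiable; a permissive mode keeps them in the record but they can never
participate in a PAM or protospacer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DNA_ALPHABET",
    "CODON_TABLE",
    "GenomeRecord",
    "Feature",
    "EditSpec",
    "CodonContext",
    "InputError",
    "AmbiguousSequenceError",
    "revcomp",
    "translate",
    "synonymous_codons",
    "hamming",
    "apply_edits",
    "read_genome",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGT")
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Standard genetic code (NCBI table 1) — the E. coli context this toolkit
# targets uses the standard table; alternates are supplied via config.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_by_aa: dict[str, set[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _by_aa.setdefault(_aa, set()).add(_codon)
_SYNONYMS: dict[str, frozenset[str]] = {
    c: frozenset(_by_aa[a]) for c, a in CODON_TABLE.items()
}


class InputError(ValueError):
    """Invalid user input (bad characters, lengths, coordinates)."""


class AmbiguousSequenceError(InputError):
    """Sequence contains IUPAC ambiguity codes and permissive mode is off."""


def _check_dna(seq: str, *, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        if bad <= AMBIGUITY_CODES:
            raise AmbiguousSequenceError(
                f"{what} contains ambiguity codes {sorted(bad)}; "
                "pass allow_ambiguous=True to keep them (they are excluded "
                "from PAM/protospacer eligibility)"
            )
        raise InputError(f"{what} contains non-DNA characters {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string.  Involution: revcomp(revcomp(s)) == s."""
    s = seq.upper()
    if not set(s) <= (DNA_ALPHABET | AMBIGUITY_CODES):
        raise InputError(f"non-DNA character in {seq!r}")
    return s.translate(_COMPLEMENT)[::-1]


def translate(seq: str, table: dict[str, str] | None = None) -> str:
    """Translate a DNA string (length divisible by 3) to one-letter protein.

    Stop codons render as ``*``.  The standard genetic code is the default.
    """
    s = _check_dna(seq, what="coding sequence")
    if len(s) % 3 != 0:
        raise InputError(f"length {len(s)} is not a multiple of 3")
    tbl = table or CODON_TABLE
    return "".join(tbl[s[i : i + 3]] for i in range(0, len(s), 3))


def synonymous_codons(codon: str, table: dict[str, str] | None = None) -> frozenset[str]:
    """All codons (the input included) encoding the same amino acid."""
    c = _check_dna(codon, what="codon")
    if len(c) != 3:
        raise InputError(f"codon must be a triplet, got {codon!r}")
    if table is None:
        return _SYNONYMS[c]
    aa = table[c]
    return frozenset(k for k, v in table.items() if v == aa)


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise InputError(f"unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


@dataclass(frozen=True)
class Feature:
    """A labelled region of a genome, ``[start, end)`` on ``strand``."""

    label: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class GenomeRecord:
    """A named linear or circular DNA sequence with optional features.

    ``seq`` is normalised to uppercase and validated against the DNA
    alphabet on construction.  Circular records may be sliced across the
    origin with :meth:`fetch`.
    """

    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)
    allow_ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError("empty sequence")
        if self.topology not in ("linear", "circular"):
            raise InputError(f"topology must be linear|circular, got {self.topology!r}")
        if self.allow_ambiguous:
            s = self.seq.upper()
            bad = set(s) - DNA_ALPHABET - AMBIGUITY_CODES
            if bad:
                raise InputError(f"non-DNA characters {sorted(bad)}")
            self.seq = s
        else:
            self.seq = _check_dna(self.seq, what=f"record {self.id!r}")
        n = len(self.seq)
        for f in self.features:
            if self.topology == "linear":
                if not (0 <= f.start < f.end <= n):
                    raise InputError(f"feature {f.label!r} outside [0, {n})")
            else:
                if not (0 <= f.start < n and 0 < f.end - f.start <= n):
                    raise InputError(f"feature {f.label!r} not normalisable on length {n}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def normalize(self, pos: int) -> int:
        """Map a coordinate into ``[0, len)`` (circular) or validate (linear)."""
        n = len(self.seq)
        if self.circular:
            return pos % n
        if not 0 <= pos <= n:
            raise InputError(f"position {pos} outside linear record of length {n}")
        return pos

    def fetch(self, start: int, end: int) -> str:
        """Slice ``[start, end)``; wraps across the origin when circular."""
        n = len(self.seq)
        if end < start:
            raise InputError(f"inverted interval [{start}, {end})")
        if end - start > n:
            raise InputError(f"interval [{start}, {end}) longer than the record")
        if self.circular:
            span = end - start
            s = start % n
            e = s + span
            if e <= n:
                return self.seq[s:e]
            return self.seq[s:] + self.seq[: e - n]
        if start < 0 or end > n:
            raise InputError(f"interval [{start}, {end}) outside linear record of length {n}")
        return self.seq[start:end]

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise InputError(f"no feature named {label!r} in record {self.id!r}")



@dataclass(frozen=True)
class EditSpec:
    """A same-length substitution at a genomic position (forward strand).

    ``ref`` must match the genome at ``position`` when applied; indels are
    out of scope — MAGE oligos in this toolkit carry substitutions only.
    """

    position: int
    ref: str
    alt: str
    role: str = "desired"  # desired | counterselection

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _check_dna(self.ref, what="ref"))
        object.__setattr__(self, "alt", _check_dna(self.alt, what="alt"))
        if len(self.ref) != len(self.alt) or len(self.ref) < 1:
            raise InputError(
                f"substitutions only: len(ref)={len(self.ref)} must equal "
                f"len(alt)={len(self.alt)} and be >= 1"
            )
        if self.role not in ("desired", "counterselection"):
            raise InputError(f"unknown role {self.role!r}")

    @property
    def end(self) -> int:
        return self.position + len(self.ref)

    def changed_positions(self) -> list[int]:
        """Genomic positions where alt actually differs from ref."""
        return [self.position + i for i, (r, a) in enumerate(zip(self.ref, self.alt)) if r != a]

    def inverse(self) -> "EditSpec":
        return EditSpec(self.position, self.alt, self.ref, self.role)


def apply_edits(genome: GenomeRecord, edits: Iterable[EditSpec]) -> str:
    """Return the genome sequence with all edits applied.

    Each edit's ``ref`` is verified against the current wild-type sequence;
    overlapping edits are rejected.
    """
    seq = list(genome.seq)
    n = len(seq)
    touched: set[int] = set()
    for e in edits:
        for i, (r, a) in enumerate(zip(e.ref, e.alt)):
            pos = genome.normalize(e.position + i) if genome.circular else e.position + i
            if not 0 <= pos < n:
                raise InputError(f"edit at {e.position} runs outside the record")
            if genome.seq[pos] != r:
                raise InputError(
                    f"ref mismatch at {pos}: genome has {genome.seq[pos]}, edit expects {r}"
                )
            if pos in touched and seq[pos] != a:
                raise InputError(f"conflicting edits at position {pos}")
            seq[pos] = a
            touched.add(pos)
    return "".join(seq)


@dataclass(frozen=True)
class CodonContext:
    """Reading-frame context: a CDS at ``[cds_start, cds_end)`` on ``strand``.

    For strand ``-`` codon 0 starts at ``cds_end`` and runs leftwards; the
    codon sequence is the reverse complement of its genomic footprint.
    A CDS whose translation contains an internal stop gets a warning, not
    an error — partial regions are legitimate design inputs.
    """

    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be +|-, got {self.strand!r}")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise InputError(
                f"CDS length {self.cds_end - self.cds_start} not divisible by 3"
            )
        if self.cds_end <= self.cds_start:
            raise InputError("empty CDS")

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    def codon_footprint(self, index: int) -> tuple[int, int]:
        """Genomic ``[start, end)`` of 0-based codon ``index``."""
        if not 0 <= index < self.n_codons:
            raise InputError(f"codon index {index} outside CDS of {self.n_codons} codons")
        if self.strand == "+":
            s = self.cds_start + 3 * index
        else:
            s = self.cds_end - 3 * (index + 1)
        return s, s + 3

    def codon_seq(self, genome: GenomeRecord, index: int) -> str:
        s, e = self.codon_footprint(index)
        frag = genome.fetch(s, e)
        return frag if self.strand == "+" else revcomp(frag)

    def cds_seq(self, genome: GenomeRecord) -> str:
        frag = genome.fetch(self.cds_start, self.cds_end)
        return frag if self.strand == "+" else revcomp(frag)

    def validate(self, genome: GenomeRecord) -> None:
        prot = translate(self.cds_seq(genome))
        if "*" in prot[:-1]:
            warnings.warn(
                f"CDS [{self.cds_start}, {self.cds_end}) on {self.strand} contains "
                "an internal stop codon",
                stacklevel=2,
            )


def read_genome(path: str | Path, *, topology: str | None = None,
                allow_ambiguous: bool = False) -> GenomeRecord:
    """Read the first record of a FASTA or GenBank file.

    Format is inferred from the extension (``.gb/.gbk/.genbank`` → GenBank,
    anything else → FASTA).  GenBank features populate
    :attr:`GenomeRecord.features`; a circular GenBank topology is honoured
    unless ``topology`` overrides it.
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    rec: SeqRecord = next(SeqIO.parse(str(path), fmt))
    feats: list[Feature] = []
    topo = topology
    if fmt == "genbank":
        if topo is None:
            topo = rec.annotations.get("topology", "linear")
        for f in rec.features:
            if f.type in ("source",):
                continue
            label = (
                f.qualifiers.get("label", [None])[0]
                or f.qualifiers.get("gene", [None])[0]
                or f.qualifiers.get("locus_tag", [f.type])[0]
            )
            strand = "-" if f.location.strand == -1 else "+"
            feats.append(Feature(str(label), int(f.location.start), int(f.location.end), strand))
    return GenomeRecord(
        id=rec.id,
        seq=str(rec.seq),
        topology=topo or "linear",
        features=feats,
        allow_ambiguous=allow_ambiguous,
    )


def write_fasta(path: str | Path, entries: Sequence[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs as FASTA."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")
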