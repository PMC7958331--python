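"""Sequence and coordinate foundation.

Everything downstream speaks two currencies: :class:`NucleotideSequence`
(an uppercase IUPAC string tagged DNA or RNA) and :class:`GenomicInterval`
(1-based, inclusive at both ends, as GenBank and the printed promoter/CGI
tables use).  BED export converts to 0-based half-open at the boundary;
GFF3 stays 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

# IUPAC nucleotide codes -> set of concrete DNA bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
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

_DNA_ALPHABET = frozenset(IUPAC_CODES) - {"U"}
_RNA_ALPHABET = (frozenset(IUPAC_CODES) - {"T"}) | {"U"}

COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA or RNA sequence, case-normalized to uppercase.

    Parameters
    ----------
    identifier : str
        Record name (FASTA header word).
    residues : str
        Sequence over the IUPAC alphabet; lowercase input is uppercased
        at construction and carries no masking semantics.
    alphabet_kind : {"DNA", "RNA"}
    """

    identifier: str
    residues: str
    alphabet_kind: str = "DNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.alphabet_kind not in ("DNA", "RNA"):
            raise ValueError(f"alphabet_kind must be DNA or RNA, got {self.alphabet_kind!r}")
        allowed = _DNA_ALPHABET if self.alphabet_kind == "DNA" else _RNA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r}: illegal {self.alphabet_kind} "
                f"character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def as_dna(self) -> "NucleotideSequence":
        """Return a DNA view (U->T); identity if already DNA."""
        if self.alphabet_kind == "DNA":
            return self
        return NucleotideSequence(self.identifier, self.residues.replace("U", "T"), "DNA")

    def as_rna(self) -> "NucleotideSequence":
        """Return an RNA view (T->U); identity if already RNA."""
        if self.alphabet_kind == "RNA":
            return self
        return NucleotideSequence(self.identifier, self.residues.replace("T", "U"), "RNA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive span on a named sequence.

    ``start <= end`` always; descending printed coordinate pairs should be
    ingested via :func:`interval_from_printed`, which flips them to
    (min, max) with strand ``-``.
    """

    sequence_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates are 1-based positive, got ({self.start}, {self.end})")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}; use interval_from_printed for descending pairs")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_name == other.sequence_name
            and self.start <= other.end
            and other.start <= self.end
        )

    def touches_or_overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_name == other.sequence_name
            and self.start <= other.end + 1
            and other.start <= self.end + 1
        )


def interval_from_printed(sequence_name: str, a: int, b: int) -> GenomicInterval:
    """Build an interval from a printed coordinate pair.

    Ascending pairs keep strand "+"; descending pairs (minus-strand
    elements are conventionally printed 5'->3', i.e. descending on the
    forward axis) are normalized to (min, max) with strand "-".
    """
    if a <= b:
        return GenomicInterval(sequence_name, a, b, "+")
    return GenomicInterval(sequence_name, b, a, "-")


@dataclass
class FeatureAnnotation:
    """Ordered, non-overlapping feature tiling of a transcript.

    Features are (label, interval) pairs in transcript-local 1-based
    coordinates, e.g. ``("5'UTR", 1..26), ("CDS", 27..707), ("3'UTR", ...)``.
    """

    transcript_id: str
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        feats = sorted(self.features, key=lambda f: f[1].start)
        for (la, a), (lb, b) in zip(feats, feats[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"{self.transcript_id}: features {la} and {lb} overlap"
                )
        self.features = feats

    def label_at(self, position: int) -> str | None:
        """Label of the feature containing a 1-based transcript position."""
        for label, iv in self.features:
            if iv.start <= position <= iv.end:
                return label
        return None


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement; ambiguity codes map to their complements."""
    if seq.alphabet_kind == "DNA":
        rc = str(Seq(seq.residues).reverse_complement())
    else:
        rc = str(Seq(seq.residues).reverse_complement_rna())
    return NucleotideSequence(seq.identifier, rc, seq.alphabet_kind)


def reverse_complement_str(residues: str) -> str:
    """Reverse complement of a bare DNA/IUPAC string."""
    return "".join(COMPLEMENT[c] for c in reversed(residues.upper()))


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def interval_length(iv: GenomicInterval) -> int:
    """Inclusive length in bp: end - start + 1."""
    return len(iv)


def interval_union(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals on one sequence into a minimal sorted list.

    Touching intervals (end + 1 == next start) merge; strand is ignored
    and the merged intervals are unstranded.
    """
    if not ivs:
        return []
    names = {iv.sequence_name for iv in ivs}
    if len(names) > 1:
        raise ValueError(f"interval_union requires one sequence, got {sorted(names)}")
    name = ivs[0].sequence_name
    merged: list[list[int]] = []
    for iv in sorted(ivs, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(name, s, e) for s, e in merged]


def local_to_genome(anchor: GenomicInterval, local_pos: int) -> int:
    """Map a 1-based position local to *anchor* onto genomic coordinates."""
    if not 1 <= local_pos <= len(anchor):
        raise ValueError(
            f"local position {local_pos} outside [1, {len(anchor)}] of anchor {anchor}"
        )
    return anchor.start + local_pos - 1


def genome_to_local(anchor: GenomicInterval, genome_pos: int) -> int:
    """Inverse of :func:`local_to_genome`."""
    if not anchor.start <= genome_pos <= anchor.end:
        raise ValueError(f"genomic position {genome_pos} outside anchor {anchor}")
    return genome_pos - anchor.start + 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet_kind: str | None = None) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file.

    The alphabet is inferred per record (presence of U and absence of T
    flags RNA) unless *alphabet_kind* forces one.  Illegal characters
    raise :class:`ParseError` naming the first offending line.
    """
    from Bio import SeqIO

    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython is permissive
        raise ParseError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not parsed and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found (missing '>' header?)")
    for rec in parsed:
        residues = str(rec.seq).upper()
        kind = alphabet_kind
        if kind is None:
            kind = "RNA" if ("U" in residues and "T" not in residues) else "DNA"
        try:
            records.append(NucleotideSequence(rec.id, residues, kind))
        except ValueError as exc:
            line = _find_bad_line(path, kind)
            raise ParseError(f"{path}:{line}: {exc}") from exc
    return records


def _find_bad_line(path: Path, kind: str) -> int:
    allowed = _DNA_ALPHABET if kind == "DNA" else _RNA_ALPHABET
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">") or line.startswith(";"):
                continue
            if set(line.upper()) - allowed:
                return lineno
    return 0


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.identifier}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def write_bed(path: str | Path, rows: Iterable[tuple[GenomicInterval, str, float]]) -> None:
    """Write BED6; converts 1-based inclusive to 0-based half-open.

    *rows* are (interval, name, score) triples; output is sorted by
    (sequence, start, name) for determinism.
    """
    out = sorted(
        (iv.sequence_name, iv.start - 1, iv.end, name, score, iv.strand if iv.strand != "." else ".")
        for iv, name, score in rows
    )
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in out:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score:g}\t{strand}\n")


def write_gff3(
    path: str | Path,
    rows: Iterable[tuple[GenomicInterval, str, str, float, dict[str, str]]],
    source: str = "regscan",
) -> None:
    """Write GFF3 (1-based inclusive); rows are (interval, type, name, score, attrs)."""
    out = sorted(
        (iv.sequence_name, iv.start, iv.end, ftype, name, score, iv.strand, attrs)
        for iv, ftype, name, score, attrs in rows
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, ftype, name, score, strand, attrs in out:
            attr_s = ";".join([f"Name={name}"] + [f"{k}={v}" for k, v in sorted(attrs.items())])
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{s}\t{e}\t{score:g}\t"
                f"{strand if strand != '.' else '.'}\t.\t{attr_s}\n"
            )


def read_feature_table(path: str | Path) -> dict[str, FeatureAnnotation]:
    """Read transcript feature annotations from TSV.

    Columns: transcript_id, label, start, end (1-based inclusive,
    transcript-local). Returns one FeatureAnnotation per transcript.
    """
    by_tx: dict[str, list[tuple[str, GenomicInterval]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "transcript_id":  # header
                continue
            if len(row) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            tx, label, start, end = row[0], row[1], int(row[2]), int(row[3])
            by_tx.setdefault(tx, []).append((label, GenomicInterval(tx, start, end)))
    return {tx: FeatureAnnotation(tx, feats) for tx, feats in by_tx.items()}
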