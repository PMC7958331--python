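"""Degenerate-consensus motif catalog and scanner.

Scans DNA for IUPAC consensus patterns with a per-motif Hamming mismatch
budget and optional absolute exclusion patterns (a window matching any
exclusion at zero mismatches is discarded even if it fits the main
pattern — the TATA-532 element is defined this way).  Minus-strand
scanning runs on the reverse complement and maps hits back to
forward-strand intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .seqcore import (
    IUPAC_CODES,
    GenomicInterval,
    NucleotideSequence,
    reverse_complement_str,
)


def iupac_match(base: str, code: str) -> bool:
    """True iff *base* is in the IUPAC *code*'s allowed set (case-insensitive).

    An N in the subject matches nothing except pattern N: masked input
    must not produce spurious hits.
    """
    base_u, code_u = base.upper(), code.upper()
    if base_u not in IUPAC_CODES or code_u not in IUPAC_CODES:
        bad = base if base_u not in IUPAC_CODES else code
        raise ValueError(f"undefined IUPAC character {bad!r}")
    if code_u == "N":
        return True
    if base_u == "N":
        return False
    return base_u in IUPAC_CODES[code_u]


def _mismatch_count(window: str, pattern: str, budget: int) -> int:
    """Hamming mismatches of *window* against IUPAC *pattern*; early exit past budget."""
    mm = 0
    for b, c in zip(window, pattern):
        if c != "N" and (b == "N" or b not in IUPAC_CODES[c]):
            mm += 1
            if mm > budget:
                return mm
    return mm


@dataclass(frozen=True)
class ConsensusMotif:
    """Named degenerate consensus with optional exclusions and mismatch budget."""

    name: str
    pattern: str
    exclusion_patterns: tuple[str, ...] = ()
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        object.__setattr__(
            self, "exclusion_patterns", tuple(p.upper() for p in self.exclusion_patterns)
        )
        if not pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        for p in (pattern,) + self.exclusion_patterns:
            bad = set(p) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"motif {self.name!r}: undefined IUPAC code(s) {sorted(bad)}")
        for p in self.exclusion_patterns:
            if len(p) != len(pattern):
                raise ValueError(
                    f"motif {self.name!r}: exclusion {p} length {len(p)} != pattern length {len(pattern)}"
                )
        if self.max_mismatches < 0:
            raise ValueError(f"motif {self.name!r}: negative mismatch budget")


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    interval: GenomicInterval
    matched_subsequence: str  # as on the forward strand
    mismatch_count: int


def scan(
    seq: NucleotideSequence,
    motif: ConsensusMotif,
    strands: str = "both",
) -> list[MotifHit]:
    """Report every window within the mismatch budget that hits no exclusion.

    Parameters
    ----------
    strands : {"+", "-", "both"}
        Minus-strand windows are matched on the reverse complement and
        reported as forward-strand intervals with strand "-".

    Hits are sorted by (start, strand); overlapping hits are all kept.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    dna = seq.as_dna()
    text = dna.residues
    L = len(motif.pattern)
    hits: list[MotifHit] = []
    if len(text) < L:
        return hits
    todo = []
    if strands in ("+", "both"):
        todo.append(("+", text))
    if strands in ("-", "both"):
        todo.append(("-", reverse_complement_str(text)))
    n = len(text)
    for strand, s in todo:
        for i in range(n - L + 1):
            window = s[i : i + L]
            mm = _mismatch_count(window, motif.pattern, motif.max_mismatches)
            if mm > motif.max_mismatches:
                continue
            if any(
                _mismatch_count(window, ex, 0) == 0 for ex in motif.exclusion_patterns
            ):
                continue
            if strand == "+":
                start = i + 1
            else:
                start = n - (i + L) + 1
            iv = GenomicInterval(seq.identifier, start, start + L - 1, strand)
            hits.append(
                MotifHit(motif.name, iv, text[start - 1 : start + L - 1], mm)
            )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand, h.motif_name))
    return hits


def scan_catalog(
    seq: NucleotideSequence,
    catalog: list[ConsensusMotif],
    strands: str = "both",
) -> list[MotifHit]:
    """Scan every motif of a catalog; globally sorted by (start, strand, name)."""
    if not catalog:
        raise ValueError("empty motif catalog")
    names = [m.name for m in catalog]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate motif name(s) in catalog: {sorted(dupes)}")
    hits: list[MotifHit] = []
    for motif in catalog:
        hits.extend(scan(seq, motif, strands))
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand, h.motif_name))
    return hits


def count_distinct_sites(hits: list[MotifHit], mode: str = "all") -> int:
    """Count hits either raw or as clusters of mutually overlapping same-strand hits.

    ``merge_overlapping`` collapses nested/overlapping windows (a GAGAGA
    window and the GAGAG windows inside it count as one site).
    """
    if mode == "all":
        return len(hits)
    if mode != "merge_overlapping":
        raise ValueError(f"mode must be 'all' or 'merge_overlapping', got {mode!r}")
    clusters = 0
    by_strand: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_strand.setdefault(h.interval.strand, []).append(h)
    for strand_hits in by_strand.values():
        strand_hits.sort(key=lambda h: (h.interval.start, h.interval.end))
        current_end = -1
        for h in strand_hits:
            if h.interval.start > current_end:
                clusters += 1
                current_end = h.interval.end
            else:
                current_end = max(current_end, h.interval.end)
    return clusters


# ---------------------------------------------------------------------------
# built-in catalog
# ---------------------------------------------------------------------------
# Core-promoter and response-element consensus strings; TATA-532 carries
# absolute exclusions.  SP1/AP1/GRE/ERE have no single printed consensus in
# the promoter maps they were taken from, so canonical defaults are used;
# override any entry via a YAML catalog file.
BUILTIN_CATALOG: list[ConsensusMotif] = [
    ConsensusMotif("TATA-8a", "TATAWA"),
    ConsensusMotif("TATA-8b", "TATAWAWR"),
    ConsensusMotif(
        "TATA-532",
        "HWHWWWWR",
        exclusion_patterns=("HTYTTTWR", "CAYTTTWR", "MAMAAAAR", "CTYAAAAR"),
    ),
    ConsensusMotif("INR", "YYANWYY"),
    ConsensusMotif("DTIE", "GBBRDNHGG"),
    ConsensusMotif("CCAAT", "CCAAT"),
    ConsensusMotif("CCAAT-inverted", "TAACC"),
    ConsensusMotif("BRE", "SSRCGCC"),
    ConsensusMotif("DPE", "RGWCGTG"),
    ConsensusMotif("ARE", "TGACNNNGC"),
    ConsensusMotif("E-box", "CACGTG"),
    ConsensusMotif("GAF-5", "GAGAG"),
    ConsensusMotif("GAF-6", "GAGAGA"),
    ConsensusMotif("CTCF-MGMT", "TTACCTCTAGGTGCCAGCC"),
    ConsensusMotif("SP1", "GGGCGG"),
    ConsensusMotif("AP1", "TGACTCA"),
    ConsensusMotif("GRE", "AGAACANNNTGTTCT"),
    ConsensusMotif("ERE", "GGTCANNNTGACC"),
]


def load_catalog(path: str | Path) -> list[ConsensusMotif]:
    """Load a motif catalog from YAML.

    Format: a list of mappings with keys ``name``, ``pattern`` and optional
    ``exclusions`` (list) and ``max_mismatches`` (int).
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{path}: catalog must be a YAML list of motif entries")
    motifs = []
    for e in entries:
        motifs.append(
            ConsensusMotif(
                name=e["name"],
                pattern=e["pattern"],
                exclusion_patterns=tuple(e.get("exclusions", ())),
                max_mismatches=int(e.get("max_mismatches", 0)),
            )
        )
    return motifs


def save_catalog(path: str | Path, catalog: list[ConsensusMotif]) -> None:
    entries = [
        {
            "name": m.name,
            "pattern": m.pattern,
            **({"exclusions": list(m.exclusion_patterns)} if m.exclusion_patterns else {}),
            **({"max_mismatches": m.max_mismatches} if m.max_mismatches else {}),
        }
        for m in catalog
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
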