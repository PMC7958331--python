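"""Spaced-dimer p53 response-element search.

A canonical p53 response element is two RRRCWWGYYY decamer half-sites
separated by a 0-13 nt spacer of arbitrary bases.  The finder enumerates
every (offset, spacer) placement on the requested strands, counts IUPAC
mismatches per half-site, and reports placements within a total budget.
``best_match`` clips the spacer range to what the sequence length
permits, so a printed element string shorter than two decamers plus the
nominal spacer still yields its optimum.

The half-site class RRRCWWGYYY is reverse-complement symmetric, so the
minimum mismatch count of a sequence equals that of its reverse
complement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifscan import _mismatch_count
from .seqcore import GenomicInterval, NucleotideSequence, reverse_complement_str

P53_HALF_SITE = "RRRCWWGYYY"


@dataclass(frozen=True)
class DimerConsensus:
    half_pattern: str = P53_HALF_SITE
    spacer_min: int = 0
    spacer_max: int = 13
    max_total_mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "half_pattern", self.half_pattern.upper())
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError(
                f"need 0 <= spacer_min <= spacer_max, got ({self.spacer_min}, {self.spacer_max})"
            )
        if self.max_total_mismatches < 0:
            raise ValueError("negative mismatch budget")

    @property
    def half_len(self) -> int:
        return len(self.half_pattern)


@dataclass(frozen=True)
class DimerHit:
    interval: GenomicInterval
    spacer_length: int
    mismatches_half1: int
    mismatches_half2: int
    matched_subsequence: str  # as on the forward strand

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_half1 + self.mismatches_half2


def _enumerate(
    seq: NucleotideSequence,
    consensus: DimerConsensus,
    strands: str,
    budget: int,
) -> list[DimerHit]:
    text = seq.as_dna().residues
    n = len(text)
    h = consensus.half_len
    hits: list[DimerHit] = []
    todo = []
    if strands in ("+", "both"):
        todo.append(("+", text))
    if strands in ("-", "both"):
        todo.append(("-", reverse_complement_str(text)))
    for strand, s in todo:
        for spacer in range(consensus.spacer_min, consensus.spacer_max + 1):
            L = 2 * h + spacer
            if L > n:
                break
            for i in range(n - L + 1):
                mm1 = _mismatch_count(s[i : i + h], consensus.half_pattern, budget)
                if mm1 > budget:
                    continue
                mm2 = _mismatch_count(
                    s[i + h + spacer : i + L], consensus.half_pattern, budget - mm1
                )
                if mm1 + mm2 > budget:
                    continue
                start = i + 1 if strand == "+" else n - (i + L) + 1
                iv = GenomicInterval(seq.identifier, start, start + L - 1, strand)
                hits.append(
                    DimerHit(iv, spacer, mm1, mm2, text[start - 1 : start + L - 1])
                )
    return hits


def find_dimer_sites(
    seq: NucleotideSequence,
    consensus: DimerConsensus | None = None,
    strands: str = "both",
) -> list[DimerHit]:
    """All placements within the mismatch budget on the requested strands.

    Sorted by (total mismatches, start, spacer length); minus-strand hits
    are reported as forward-strand intervals with strand "-".
    """
    if consensus is None:
        consensus = DimerConsensus()
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    hits = _enumerate(seq, consensus, strands, consensus.max_total_mismatches)
    hits.sort(
        key=lambda d: (
            d.total_mismatches,
            d.interval.start,
            d.spacer_length,
            d.interval.strand,
        )
    )
    return hits


def best_match(seq: NucleotideSequence, consensus: DimerConsensus | None = None) -> DimerHit:
    """The placement with the fewest total mismatches on either strand.

    The spacer range is clipped to what the sequence length allows; ties
    break toward smaller spacer, then smaller start, then the + strand.
    Raises if the sequence cannot hold even two half-sites.
    """
    if consensus is None:
        consensus = DimerConsensus()
    n = len(seq.residues)
    max_spacer_possible = n - 2 * consensus.half_len
    if max_spacer_possible < consensus.spacer_min:
        raise ValueError(
            f"sequence length {n} cannot hold two {consensus.half_len}-mers "
            f"with spacer >= {consensus.spacer_min}"
        )
    clipped = DimerConsensus(
        consensus.half_pattern,
        consensus.spacer_min,
        min(consensus.spacer_max, max_spacer_possible),
        consensus.max_total_mismatches,
    )
    best: DimerHit | None = None
    budget = 2 * clipped.half_len  # unbounded search: every placement scored
    for hit in _enumerate(seq, clipped, "both", budget):
        key = (
            hit.total_mismatches,
            hit.spacer_length,
            hit.interval.start,
            0 if hit.interval.strand == "+" else 1,
        )
        if best is None or key < best_key:
            best, best_key = hit, key
    assert best is not None
    return best
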