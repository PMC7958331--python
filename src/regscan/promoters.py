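"""Alternative-promoter bookkeeping.

Ingests promoter records (database source, id, genomic interval, printed
span), verifies printed spans against computed lengths, builds the union
envelope of a set of overlapping/touching promoters, and maps
promoter-local annotations (CpG islands, binding sites) to genomic
coordinates.

The module ships the published coordinate set for the human MGMT exon-1
alternative promoters on hg38 chr10 as ready-made records: five
overlapping promoters from PrESSTo/FANTOM, EPD, NCBI and Ensembl whose
union forms the revised 2019-bp exon-1 promoter, plus the distant
TRED-5071 exon-2 promoter-like sequence (which is disconnected from the
exon-1 cluster and must not enter the union).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .seqcore import (
    GenomicInterval,
    genome_to_local,
    interval_length,
    local_to_genome,
)


@dataclass(frozen=True)
class PromoterRecord:
    source: str
    promoter_id: str
    interval: GenomicInterval
    declared_span: int | None = None


@dataclass
class RevisedPromoter:
    interval: GenomicInterval
    members: list[PromoterRecord]
    local_annotations: list[tuple[str, GenomicInterval]] = field(default_factory=list)


# Published hg38 coordinates of the MGMT exon-1 alternative promoters and
# the exon-2 promoter-like sequence (all + strand, chr10).
MGMT_EXON1_PROMOTERS: list[PromoterRecord] = [
    PromoterRecord("PrESSTo/FANTOM", "P1@MGMT", GenomicInterval("chr10", 129466944, 129467344, "+"), 401),
    PromoterRecord("PrESSTo/FANTOM", "P2@MGMT", GenomicInterval("chr10", 129466905, 129467305, "+"), 401),
    PromoterRecord("EPD", "MGMT_1", GenomicInterval("chr10", 129466745, 129467344, "+"), 600),
    PromoterRecord("NCBI/Nucleotide", "X61657.1", GenomicInterval("chr10", 129466183, 129467339, "+"), 1157),
    PromoterRecord("Ensembl 84", "ENSR00001428452", GenomicInterval("chr10", 129466558, 129468201, "+"), 1644),
]

MGMT_REVISED_PROMOTER_RECORD = PromoterRecord(
    "this study", "MGMT-P1", GenomicInterval("chr10", 129466183, 129468201, "+"), 2019
)

TRED_EXON2_PROMOTER = PromoterRecord(
    "TRED", "TRED-5071", GenomicInterval("chr10", 129535540, 129536539, "+"), 1000
)


def build_revised_promoter(records: list[PromoterRecord]) -> RevisedPromoter:
    """Union envelope of a connected set of promoter records.

    All records must lie on one chromosome and form a single
    overlapping/touching cluster; a disconnected record (e.g. the distant
    exon-2 promoter) raises an error naming the offenders.
    """
    if not records:
        raise ValueError("no promoter records supplied")
    chroms = {r.interval.sequence_name for r in records}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    members = sorted(records, key=lambda r: (r.interval.start, r.interval.end))
    # single-cluster check by sweep
    reach = members[0].interval.end
    disconnected: list[str] = []
    for rec in members[1:]:
        if rec.interval.start > reach + 1:
            disconnected.append(rec.promoter_id)
        reach = max(reach, rec.interval.end)
    if disconnected:
        raise ValueError(
            "promoter records do not form one connected cluster; "
            f"disconnected: {disconnected}"
        )
    envelope = GenomicInterval(
        members[0].interval.sequence_name,
        min(r.interval.start for r in members),
        max(r.interval.end for r in members),
        "+",
    )
    return RevisedPromoter(envelope, members)


def verify_spans(
    records: list[PromoterRecord],
) -> list[tuple[str, int, int | None, bool]]:
    """Per record: (id, computed span, declared span, agreement flag)."""
    rows = []
    for rec in records:
        computed = interval_length(rec.interval)
        agree = rec.declared_span is None or computed == rec.declared_span
        rows.append((rec.promoter_id, computed, rec.declared_span, agree))
    return rows


def annotate_local(
    rp: RevisedPromoter, label: str, local_iv: GenomicInterval
) -> tuple[str, GenomicInterval]:
    """Map a promoter-local 1-based interval to genomic coordinates."""
    g_start = local_to_genome(rp.interval, local_iv.start)
    g_end = local_to_genome(rp.interval, local_iv.end)
    giv = GenomicInterval(rp.interval.sequence_name, g_start, g_end, rp.interval.strand)
    rp.local_annotations.append((label, local_iv))
    return label, giv


def local_of(rp: RevisedPromoter, genomic_iv: GenomicInterval) -> GenomicInterval:
    """Inverse of :func:`annotate_local`: genomic interval -> promoter-local."""
    return GenomicInterval(
        rp.interval.sequence_name,
        genome_to_local(rp.interval, genomic_iv.start),
        genome_to_local(rp.interval, genomic_iv.end),
        genomic_iv.strand,
    )


def read_promoter_table(path: str | Path) -> list[PromoterRecord]:
    """Read promoter records from TSV: source, id, chrom, start, end[, declared_span]."""
    records = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "source":
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            declared = int(row[5]) if len(row) > 5 and row[5] not in ("", "-") else None
            records.append(
                PromoterRecord(
                    row[0],
                    row[1],
                    GenomicInterval(row[2], int(row[3]), int(row[4]), "+"),
                    declared,
                )
            )
    return records
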