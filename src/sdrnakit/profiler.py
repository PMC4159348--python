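"""Read-to-locus assignment and per-compartment summary statistics.

Implements the biotype classification of aligned reads (strand-aware,
overlap-fraction based), the alignment summary table (raw/aligned/sRNA/rRNA
counts and percentages), the biotype breakdown relative to aligned sRNA
reads, and the read-length histogram of annotated reads.

Percentage conventions follow the published tables they mirror: %Aligned
and %Aligned-sRNA are relative to raw reads while %rRNA is relative to
aligned reads (an inconsistent but deliberate convention, switchable via
``uniform_denominator``); the biotype breakdown reports %miRNA at one
decimal and the remaining biotypes at two, with ties rounded away from
zero.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .annotation import (
    MISC_BIOTYPES,
    SRNA_BIOTYPES,
    AnnotationSet,
    Biotype,
    GeneFeature,
)
from ._util import round_half_away
from .ingest import Library, AlignedRead

log = logging.getLogger(__name__)


class AssignmentStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    UNANNOTATED = "unannotated"
    AMBIGUOUS = "ambiguous"  # exact overlap tie between distinct features


@dataclass
class ReadAssignment:
    read: AlignedRead
    status: AssignmentStatus
    feature_id: str | None = None
    biotype: Biotype | None = None
    rdna_segment: str | None = None
    overlap: int = 0


def _overlap(read: AlignedRead, feature: GeneFeature) -> int:
    return min(read.end, feature.end) - max(read.start, feature.start)


def assign_reads(
    library: Library,
    annotation: AnnotationSet,
    min_overlap_frac: float = 0.8,
) -> list[ReadAssignment]:
    """Assign each read to the annotated locus it best overlaps.

    A read is assignable to a feature iff it lies on the same contig and
    strand and at least ``min_overlap_frac`` of the read length overlaps
    the feature.  Among qualifying features the largest overlap wins; an
    exact tie is counted as AMBIGUOUS.  Reads on the rDNA contig are
    classified rRNA with their segment (5'ETS, 18S, ...) recorded.
    """
    out: list[ReadAssignment] = []
    for read in library.reads:
        if read.contig == annotation.rdna_contig:
            out.append(
                ReadAssignment(
                    read,
                    AssignmentStatus.ASSIGNED,
                    feature_id=None,
                    biotype=Biotype.RRNA,
                    rdna_segment=annotation.rdna_segment_for(read.start, read.end),
                    overlap=len(read),
                )
            )
            continue
        min_ov = min_overlap_frac * len(read)
        candidates = [
            (f, _overlap(read, f))
            for f in annotation.query(read.contig, read.strand, read.start, read.end)
        ]
        candidates = [(f, ov) for f, ov in candidates if ov >= min_ov]
        if not candidates:
            out.append(ReadAssignment(read, AssignmentStatus.UNANNOTATED))
            continue
        best_ov = max(ov for _, ov in candidates)
        best = [f for f, ov in candidates if ov == best_ov]
        if len(best) > 1:
            out.append(ReadAssignment(read, AssignmentStatus.AMBIGUOUS, overlap=best_ov))
        else:
            f = best[0]
            out.append(
                ReadAssignment(
                    read, AssignmentStatus.ASSIGNED, f.feature_id, f.biotype, overlap=best_ov
                )
            )
    return out


@dataclass
class AlignmentSummary:
    """One row of the alignment summary table."""

    compartment: str
    raw_reads: int
    aligned_reads: int
    aligned_srna_reads: int
    rrna_reads: int
    pct_aligned: float
    pct_aligned_srna: float
    pct_rrna: float

    @classmethod
    def from_counts(
        cls,
        compartment: str,
        raw_reads: int,
        aligned_reads: int,
        aligned_srna_reads: int,
        rrna_reads: int,
        decimals: int = 1,
        uniform_denominator: bool = False,
    ) -> "AlignmentSummary":
        if raw_reads == 0:
            raise ValueError(f"{compartment}: raw_read_count is zero")
        rrna_denom = raw_reads if uniform_denominator else aligned_reads
        if rrna_denom == 0:
            raise ValueError(f"{compartment}: no aligned reads, %rRNA undefined")
        return cls(
            compartment=compartment,
            raw_reads=raw_reads,
            aligned_reads=aligned_reads,
            aligned_srna_reads=aligned_srna_reads,
            rrna_reads=rrna_reads,
            pct_aligned=round_half_away(100.0 * aligned_reads / raw_reads, decimals),
            pct_aligned_srna=round_half_away(100.0 * aligned_srna_reads / raw_reads, decimals),
            pct_rrna=round_half_away(100.0 * rrna_reads / rrna_denom, decimals),
        )


def summarize_alignment(
    library: Library,
    assignments: list[ReadAssignment],
    decimals: int = 1,
    uniform_denominator: bool = False,
) -> AlignmentSummary:
    """Alignment summary for one compartment (raw/aligned/sRNA/rRNA)."""
    srna = sum(
        1
        for a in assignments
        if a.status is AssignmentStatus.ASSIGNED and a.biotype in SRNA_BIOTYPES
    )
    rrna = sum(1 for a in assignments if a.biotype is Biotype.RRNA)
    return AlignmentSummary.from_counts(
        library.compartment,
        library.raw_read_count,
        len(library.reads),
        srna,
        rrna,
        decimals=decimals,
        uniform_denominator=uniform_denominator,
    )


#: printed precision per biotype column in the breakdown table
_BREAKDOWN_DECIMALS = {"miRNA": 1, "snoRNA": 2, "snRNA": 2, "miscRNA": 2}


@dataclass
class BiotypeBreakdown:
    """Biotype composition of the aligned sRNA reads of one compartment."""

    compartment: str
    srna_reads: int
    counts: dict[str, int] = field(default_factory=dict)
    pct: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, compartment: str, counts: dict[str, int]) -> "BiotypeBreakdown":
        counts = {k: counts.get(k, 0) for k in _BREAKDOWN_DECIMALS}
        total = sum(counts.values())
        pct = {
            k: (round_half_away(100.0 * v / total, _BREAKDOWN_DECIMALS[k]) if total else 0.0)
            for k, v in counts.items()
        }
        return cls(compartment=compartment, srna_reads=total, counts=counts, pct=pct)


def biotype_breakdown(
    compartment: str, assignments: list[ReadAssignment]
) -> BiotypeBreakdown:
    """Count assigned sRNA reads per biotype (Y/vault/linc pooled as miscRNA)."""
    counts = {k: 0 for k in _BREAKDOWN_DECIMALS}
    for a in assignments:
        if a.status is not AssignmentStatus.ASSIGNED or a.biotype not in SRNA_BIOTYPES:
            continue
        if a.biotype in MISC_BIOTYPES:
            counts["miscRNA"] += 1
        else:
            counts[a.biotype.value] += 1
    return BiotypeBreakdown.from_counts(compartment, counts)


@dataclass
class SizeHistogram:
    """Read-length spectrum of annotated sRNA reads (10-40 nt)."""

    compartment: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def modes(self, rel_threshold: float = 0.5) -> list[int]:
        """Modal length(s): every length whose count reaches ``rel_threshold``
        of the maximum (reports both peaks of a bimodal spectrum)."""
        if not self.counts:
            return []
        peak = max(self.counts.values())
        return sorted(n for n, c in self.counts.items() if c >= rel_threshold * peak)


def size_histogram(compartment: str, assignments: list[ReadAssignment]) -> SizeHistogram:
    """Length histogram over reads assigned to annotated sRNA loci."""
    counts: dict[int, int] = {}
    for a in assignments:
        if a.status is AssignmentStatus.ASSIGNED and a.biotype in SRNA_BIOTYPES:
            n = len(a.read)
            counts[n] = counts.get(n, 0) + 1
    return SizeHistogram(compartment=compartment, counts=dict(sorted(counts.items())))
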