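"""snoRNA-derived small RNA (sdRNA) characterization.

For every read assigned to a snoRNA locus this module determines

* the *end of origin* — whether the fragment derives from the 5' or 3'
  half of the mature snoRNA (midpoint rule, strand-aware, in
  mature-transcript coordinates);
* retained box C/D motifs — a Hamming scan of the read sequence against
  the box C core consensus TGATGA (one mismatch tolerated) and box D
  consensus CTGA (no mismatch).  C and C' (likewise D and D') match the
  same consensus and are pooled, as in the box-frequency reporting this
  mirrors; positional comparison with the annotated box intervals is
  available as an extra label;
* guide-region retention — whether the read fully contains an annotated
  antisense guide element;

and aggregates calls into a per-(locus, compartment) table with 5'-read
fractions and box tallies, the >=10-read locus filter, cross-compartment
Pearson correlations of per-locus counts, and paired 5'-fraction
comparisons.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, BoxKind, SnoRecord
from .ingest import AlignedRead
from .profiler import AssignmentStatus, ReadAssignment
from .annotation import Biotype

log = logging.getLogger(__name__)

BOX_C_CONSENSUS = "TGATGA"
BOX_D_CONSENSUS = "CTGA"


class EndClass(str, enum.Enum):
    FIVE_PRIME = "FIVE_PRIME"
    THREE_PRIME = "THREE_PRIME"
    AMBIGUOUS = "AMBIGUOUS"


def classify_end(read: AlignedRead, sno: SnoRecord, rule: str = "midpoint") -> EndClass:
    """Classify a snoRNA-assigned read as a 5'-end or 3'-end fragment.

    The read interval is converted to mature-relative, strand-aware
    coordinates.  Under the default midpoint rule the read is FIVE_PRIME
    when its midpoint falls in the 5' half of the mature transcript,
    THREE_PRIME in the 3' half, AMBIGUOUS exactly at the centre.  The
    alternative rule ``"edge:k"`` calls the end whose terminus the read
    starts within k nt of.

    Raises ``ValueError`` for reads entirely outside the mature interval
    (flanking fragments are not sdRNAs).
    """
    rel_start, rel_end = sno.mature_relative(read.start, read.end)
    if rel_end <= 0 or rel_start >= sno.mature_len:
        raise ValueError(
            f"read {read.read_id} lies outside the mature interval of {sno.feature_id}"
        )
    if rule == "midpoint":
        m = (rel_start + rel_end) / 2.0
        h = sno.mature_len / 2.0
        if m < h:
            return EndClass.FIVE_PRIME
        if m > h:
            return EndClass.THREE_PRIME
        return EndClass.AMBIGUOUS
    if rule.startswith("edge:"):
        k = int(rule.split(":", 1)[1])
        near5 = rel_start <= k
        near3 = sno.mature_len - rel_end <= k
        if near5 and not near3:
            return EndClass.FIVE_PRIME
        if near3 and not near5:
            return EndClass.THREE_PRIME
        return EndClass.AMBIGUOUS
    raise ValueError(f"unknown end rule {rule!r}")


@dataclass
class BoxHit:
    kind: str  # "C" or "D" (C/C' and D/D' pooled)
    offset: int  # 0-based offset of the motif window within the read
    mismatches: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_boxes(
    seq: str,
    c_consensus: str = BOX_C_CONSENSUS,
    d_consensus: str = BOX_D_CONSENSUS,
    c_max_mismatch: int = 1,
    d_max_mismatch: int = 0,
) -> list[BoxHit]:
    """Scan a read sequence for box C and box D motif windows.

    Every full window of each consensus length is tested by Hamming
    distance (N mismatches at its position); all qualifying windows are
    reported, C hits and D hits independently, overlapping hits included.
    An empty sequence yields an empty hit list.
    """
    seq = seq.upper()
    hits: list[BoxHit] = []
    for kind, consensus, max_mm in (
        ("C", c_consensus.upper(), c_max_mismatch),
        ("D", d_consensus.upper(), d_max_mismatch),
    ):
        k = len(consensus)
        for off in range(len(seq) - k + 1):
            mm = _hamming(seq[off : off + k], consensus)
            if mm <= max_mm:
                hits.append(BoxHit(kind, off, mm))
    return hits


_no_guide_warned: set[str] = set()


def guide_retention(read: AlignedRead, sno: SnoRecord) -> bool:
    """True iff the read's mature-relative interval fully contains at least
    one annotated guide region.  Loci without guide annotations yield False
    (warned once per locus)."""
    if not sno.guides:
        if sno.feature_id not in _no_guide_warned:
            _no_guide_warned.add(sno.feature_id)
            log.warning("%s has no guide annotations; guide retention is False", sno.feature_id)
        return False
    rel_start, rel_end = sno.mature_relative(read.start, read.end)
    return any(rel_start <= g.start and g.end <= rel_end for g in sno.guides)


@dataclass
class SdrnaCall:
    """Per-read sdRNA classification."""

    read_id: str
    sno_id: str
    compartment: str
    end_class: EndClass
    box_hits: list[BoxHit] = field(default_factory=list)
    guide_retained: bool = False
    read_length: int = 0
    mature_rel_start: int = 0
    mature_rel_end: int = 0

    @property
    def boxes_found(self) -> frozenset[str]:
        return frozenset(h.kind for h in self.box_hits)

    def box_position_labels(self, sno: SnoRecord) -> list[str]:
        """Label each hit 'annotated' when it coincides with an annotated
        box interval of the matching family, else 'novel'."""
        pooled = {BoxKind.C: "C", BoxKind.CPRIME: "C", BoxKind.D: "D", BoxKind.DPRIME: "D"}
        planted = {
            (pooled[b.kind], b.start) for b in sno.boxes if b.kind in pooled
        }
        out = []
        for h in self.box_hits:
            rel = self.mature_rel_start + h.offset
            tag = "annotated" if (h.kind, rel) in planted else "novel"
            out.append(f"{h.kind}@{rel}:{tag}")
        return out


def call_reads(
    assignments: Iterable[ReadAssignment],
    annotation: AnnotationSet,
    compartment: str,
    end_rule: str = "midpoint",
) -> tuple[list[SdrnaCall], int]:
    """sdRNA calls for all snoRNA-assigned reads of one compartment.

    Returns the calls plus the number of snoRNA-assigned reads that fell
    entirely outside the mature interval (flanking, not called).
    """
    calls: list[SdrnaCall] = []
    n_flanking = 0
    for a in assignments:
        if a.status is not AssignmentStatus.ASSIGNED or a.biotype is not Biotype.SNORNA:
            continue
        sno = annotation.features.get(a.feature_id)
        if not isinstance(sno, SnoRecord):
            continue  # plain snoRNA feature without sub-annotations: not callable
        read = a.read
        try:
            end = classify_end(read, sno, rule=end_rule)
        except ValueError:
            n_flanking += 1
            continue
        rel_start, rel_end = sno.mature_relative(read.start, read.end)
        calls.append(
            SdrnaCall(
                read_id=read.read_id,
                sno_id=sno.feature_id,
                compartment=compartment,
                end_class=end,
                box_hits=scan_boxes(read.seq) if read.seq else [],
                guide_retained=guide_retention(read, sno),
                read_length=len(read),
                mature_rel_start=rel_start,
                mature_rel_end=rel_end,
            )
        )
    return calls, n_flanking


LOCUS_TABLE_COLUMNS = [
    "sno_id",
    "compartment",
    "read_count",
    "five_prime_count",
    "five_prime_fraction",
    "n_with_C",
    "n_with_D",
    "n_with_both",
    "n_guide_retained",
]


def build_locus_table(calls: Iterable[SdrnaCall]) -> pd.DataFrame:
    """Aggregate sdRNA calls into a per-(locus, compartment) table.

    ``five_prime_fraction`` is five_prime_count / read_count.  Rows are
    ordered deterministically by (sno_id, compartment).
    """
    rows: dict[tuple[str, str], dict] = {}
    for c in calls:
        key = (c.sno_id, c.compartment)
        row = rows.setdefault(
            key,
            {
                "sno_id": c.sno_id,
                "compartment": c.compartment,
                "read_count": 0,
                "five_prime_count": 0,
                "n_with_C": 0,
                "n_with_D": 0,
                "n_with_both": 0,
                "n_guide_retained": 0,
            },
        )
        row["read_count"] += 1
        boxes = c.boxes_found
        row["five_prime_count"] += c.end_class is EndClass.FIVE_PRIME
        row["n_with_C"] += "C" in boxes
        row["n_with_D"] += "D" in boxes
        row["n_with_both"] += boxes >= {"C", "D"}
        row["n_guide_retained"] += c.guide_retained
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["sno_id"], r["compartment"])))
    if df.empty:
        return pd.DataFrame(columns=LOCUS_TABLE_COLUMNS)
    df["five_prime_fraction"] = df["five_prime_count"] / df["read_count"]
    return df[LOCUS_TABLE_COLUMNS]


def filter_loci(
    table: pd.DataFrame,
    min_reads: int = 10,
    scope: str = "any_compartment",
    compartments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keep loci meeting the read-count threshold.

    ``scope="any_compartment"`` keeps a locus (all its rows) when any
    compartment reaches ``min_reads``; ``scope="each_listed_compartment"``
    requires every compartment in ``compartments`` to reach it.
    """
    if table.empty:
        return table.copy()
    if scope == "any_compartment":
        keep = table.groupby("sno_id")["read_count"].max()
        loci = set(keep[keep >= min_reads].index)
    elif scope == "each_listed_compartment":
        if not compartments:
            raise ValueError("each_listed_compartment scope requires a compartment list")
        loci = None
        for comp in compartments:
            sub = table[(table["compartment"] == comp) & (table["read_count"] >= min_reads)]
            ids = set(sub["sno_id"])
            loci = ids if loci is None else loci & ids
        loci = loci or set()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return table[table["sno_id"].isin(loci)].reset_index(drop=True)


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    n_loci: int
    loci: list[str]
    counts_a: list[int]
    counts_b: list[int]


def compartment_correlation(
    table: pd.DataFrame,
    comp_a: str,
    comp_b: str,
    locus_scope: str = "union_detected",
    min_reads: int = 10,
) -> CorrelationResult:
    """Pearson correlation of per-locus read counts between two compartments.

    ``union_detected`` pairs every locus with at least one read in either
    compartment (absent -> 0); ``filter_first`` restricts to loci at
    ``min_reads`` or more in at least one of the two.  Fewer than three
    loci, or a zero-variance count vector, is an error.
    """
    a = table[table["compartment"] == comp_a].set_index("sno_id")["read_count"]
    b = table[table["compartment"] == comp_b].set_index("sno_id")["read_count"]
    loci = sorted(set(a.index) | set(b.index))
    if locus_scope == "filter_first":
        loci = [l for l in loci if max(a.get(l, 0), b.get(l, 0)) >= min_reads]
    elif locus_scope != "union_detected":
        raise ValueError(f"unknown locus_scope {locus_scope!r}")
    if len(loci) < 3:
        raise ValueError(
            f"need >=3 loci to correlate {comp_a} with {comp_b}, have {len(loci)}"
        )
    xa = [int(a.get(l, 0)) for l in loci]
    xb = [int(b.get(l, 0)) for l in loci]
    if len(set(xa)) == 1 or len(set(xb)) == 1:
        raise ValueError(
            f"zero variance in per-locus counts ({comp_a} vs {comp_b}); "
            "Pearson correlation is undefined"
        )
    r = float(stats.pearsonr(xa, xb).statistic)
    return CorrelationResult(
        r=r, r_squared=r * r, n_loci=len(loci), loci=loci, counts_a=xa, counts_b=xb
    )


def five_prime_fraction_comparison(
    table: pd.DataFrame,
    comp_a: str,
    comp_b: str,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-locus paired 5'-read fractions for loci with ``min_reads`` or more
    reads in *both* compartments.  Columns: sno_id, fraction_a, fraction_b,
    read_count_a, read_count_b."""
    a = table[(table["compartment"] == comp_a) & (table["read_count"] >= min_reads)]
    b = table[(table["compartment"] == comp_b) & (table["read_count"] >= min_reads)]
    merged = a.merge(b, on="sno_id", suffixes=("_a", "_b"))
    out = merged[
        ["sno_id", "five_prime_fraction_a", "five_prime_fraction_b", "read_count_a", "read_count_b"]
    ].rename(
        columns={
            "five_prime_fraction_a": "fraction_a",
            "five_prime_fraction_b": "fraction_b",
        }
    )
    return out.sort_values("sno_id").reset_index(drop=True)
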