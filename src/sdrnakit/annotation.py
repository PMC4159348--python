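"""Annotation data model for small-RNA loci.

Holds gene features (miRNA, snoRNA, snRNA, Y/vault/linc RNA, ...), snoRNA
records with their sub-annotations (mature-transcript interval, box
C/C'/D/D' motifs, guide regions, host gene) and labelled segments of an
rDNA reference contig, plus readers/writers for the on-disk representation
(GFF3 or BED6 feature rows + a TSV sidecar carrying the snoRNA
sub-annotations, which no standard format expresses).

Coordinate conventions
----------------------
All genomic coordinates are 0-based half-open (BED convention); GFF3 input
is converted on read.  Box and guide coordinates are *mature-relative*:
measured in nucleotides from the 5' end of the mature transcript in
transcript orientation, so they are strand-independent.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

SIDECAR_COLUMNS = ["feature_id", "record_kind", "kind", "rel_start", "rel_end", "extra"]


class Biotype(str, enum.Enum):
    MIRNA = "miRNA"
    SNORNA = "snoRNA"
    SNRNA = "snRNA"
    YRNA = "yRNA"
    VAULTRNA = "vaultRNA"
    LINCRNA = "lincRNA"
    RRNA = "rRNA"
    OTHER = "other"


#: biotypes pooled as "sRNA" in library summaries (rRNA is accounted separately)
SRNA_BIOTYPES = frozenset(
    {Biotype.MIRNA, Biotype.SNORNA, Biotype.SNRNA, Biotype.YRNA, Biotype.VAULTRNA, Biotype.LINCRNA}
)
#: biotypes pooled as "misc RNA" in breakdown tables
MISC_BIOTYPES = frozenset({Biotype.YRNA, Biotype.VAULTRNA, Biotype.LINCRNA})


class SnoClass(str, enum.Enum):
    CD = "CD"
    HACA = "HACA"
    SCARNA = "SCARNA"


class BoxKind(str, enum.Enum):
    C = "C"
    CPRIME = "Cprime"
    D = "D"
    DPRIME = "Dprime"
    H = "H"
    ACA = "ACA"


#: fixed motif lengths per box kind (C/C' RUGAUGA core scanned as 6-mer TGATGA,
#: D/D' CUGA, H AnAnnA, ACA)
BOX_MOTIF_LENGTH = {
    BoxKind.C: 6,
    BoxKind.CPRIME: 6,
    BoxKind.D: 4,
    BoxKind.DPRIME: 4,
    BoxKind.H: 6,
    BoxKind.ACA: 3,
}

_STRANDS = ("+", "-")


@dataclass
class BoxAnnotation:
    """A box motif occurrence, mature-relative, 0-based half-open."""

    kind: BoxKind
    start: int
    end: int

    def __post_init__(self):
        self.kind = BoxKind(self.kind)
        if self.end - self.start != BOX_MOTIF_LENGTH[self.kind]:
            raise ValueError(
                f"box {self.kind.value} interval [{self.start},{self.end}) does not have "
                f"the motif length {BOX_MOTIF_LENGTH[self.kind]}"
            )


@dataclass
class GuideRegion:
    """Antisense guide element (mature-relative) with its modification target."""

    start: int
    end: int
    target_label: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"guide interval [{self.start},{self.end}) is empty")


@dataclass
class GeneFeature:
    feature_id: str
    biotype: Biotype
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        self.biotype = Biotype(self.biotype)
        if self.strand not in _STRANDS:
            raise ValueError(f"{self.feature_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.feature_id}: malformed coordinates start={self.start} end={self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SnoRecord(GeneFeature):
    """A snoRNA locus with mature-transcript interval and sub-annotations."""

    sno_class: SnoClass = SnoClass.CD
    mature_start: int = -1
    mature_end: int = -1
    boxes: list[BoxAnnotation] = field(default_factory=list)
    guides: list[GuideRegion] = field(default_factory=list)
    host_gene: Optional[str] = None

    def __post_init__(self):
        self.biotype = Biotype.SNORNA
        super().__post_init__()
        self.sno_class = SnoClass(self.sno_class)
        if not (self.start <= self.mature_start < self.mature_end <= self.end):
            raise ValueError(
                f"{self.feature_id}: mature interval [{self.mature_start},{self.mature_end}) "
                f"not contained in feature [{self.start},{self.end})"
            )
        for box in self.boxes:
            if not (0 <= box.start and box.end <= self.mature_len):
                raise ValueError(
                    f"{self.feature_id}: box {box.kind.value} interval [{box.start},{box.end}) "
                    f"outside the {self.mature_len} nt mature transcript"
                )
        for i, a in enumerate(self.boxes):
            for b in self.boxes[i + 1 :]:
                if a.start < b.end and b.start < a.end:
                    raise ValueError(
                        f"{self.feature_id}: overlapping boxes {a.kind.value} and {b.kind.value}"
                    )
        for g in self.guides:
            if not (0 <= g.start and g.end <= self.mature_len):
                raise ValueError(
                    f"{self.feature_id}: guide [{g.start},{g.end}) outside mature transcript"
                )

    @property
    def mature_len(self) -> int:
        return self.mature_end - self.mature_start

    def mature_relative(self, start: int, end: int) -> tuple[int, int]:
        """Convert a genomic interval to mature-relative transcript coordinates."""
        if self.strand == "+":
            return start - self.mature_start, end - self.mature_start
        return self.mature_end - end, self.mature_end - start

    def mature_to_genomic(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """Inverse of :meth:`mature_relative`."""
        if self.strand == "+":
            return self.mature_start + rel_start, self.mature_start + rel_end
        return self.mature_end - rel_end, self.mature_end - rel_start


@dataclass
class RdnaSegment:
    """A labelled segment of the rDNA reference contig (5'ETS, 18S, ...)."""

    segment_id: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"rDNA segment {self.segment_id}: start >= end")


class AnnotationSet:
    """Indexed collection of gene features plus rDNA segment labels.

    Supports strand-aware stabbing queries by (contig, strand, interval)
    through per-(contig, strand) interval trees.
    """

    def __init__(
        self,
        features: Iterable[GeneFeature] = (),
        rdna_contig: str = "rDNA",
        rdna_segments: Iterable[RdnaSegment] = (),
    ):
        self.features: dict[str, GeneFeature] = {}
        for f in features:
            self.add(f)
        self.rdna_contig = rdna_contig
        self.rdna_segments = sorted(rdna_segments, key=lambda s: s.start)
        for a, b in zip(self.rdna_segments, self.rdna_segments[1:]):
            if b.start < a.end:
                raise ValueError(f"rDNA segments {a.segment_id} and {b.segment_id} overlap")
        self._trees: dict[tuple[str, str], IntervalTree] | None = None

    def add(self, feature: GeneFeature) -> None:
        if feature.feature_id in self.features:
            raise ValueError(f"duplicate feature_id {feature.feature_id!r}")
        self.features[feature.feature_id] = feature
        self._trees = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features.values())

    def _index(self) -> dict[tuple[str, str], IntervalTree]:
        if self._trees is None:
            trees: dict[tuple[str, str], IntervalTree] = {}
            for f in self.features.values():
                trees.setdefault((f.contig, f.strand), IntervalTree()).addi(
                    f.start, f.end, f.feature_id
                )
            self._trees = trees
        return self._trees

    def query(self, contig: str, strand: str, start: int, end: int) -> list[GeneFeature]:
        """All features on (contig, strand) overlapping [start, end)."""
        tree = self._index().get((contig, strand))
        if tree is None:
            return []
        return [self.features[iv.data] for iv in tree.overlap(start, end)]

    def rdna_segment_for(self, start: int, end: int) -> Optional[str]:
        """Label of the rDNA segment with the largest overlap with [start, end)."""
        best, best_ov = None, 0
        for seg in self.rdna_segments:
            ov = min(end, seg.end) - max(start, seg.start)
            if ov > best_ov:
                best, best_ov = seg.segment_id, ov
        return best

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.features == other.features
            and self.rdna_contig == other.rdna_contig
            and self.rdna_segments == other.rdna_segments
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_gff3_features(path: Path) -> list[tuple[str, Biotype, str, str, int, int]]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    rows = []
    for f in db.all_features():
        biotype = Biotype(f.attributes.get("biotype", ["other"])[0])
        start, end = f.start - 1, f.end  # GFF3 is 1-based inclusive
        if start >= end:
            raise ValueError(f"{path}: malformed coordinates for feature {f.id!r}")
        if f.strand not in _STRANDS:
            raise ValueError(f"{path}: feature {f.id!r} lacks a strand")
        rows.append((f.id, biotype, f.seqid, f.strand, start, end))
    return rows


def _read_bed6_features(path: Path) -> list[tuple[str, Biotype, str, str, int, int]]:
    # BED6 name column carries "feature_id|biotype"; a bare name gets biotype
    # "other".  Coordinates are already 0-based half-open.
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["contig", "start", "end", "name", "score", "strand"],
            dtype={"contig": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return []
    rows = []
    for idx, rec in df.iterrows():
        name = str(rec["name"])
        fid, _, bio = name.partition("|")
        biotype = Biotype(bio) if bio else Biotype.OTHER
        start, end = int(rec["start"]), int(rec["end"])
        if start >= end or start < 0:
            raise ValueError(f"{path} line {idx + 1}: malformed coordinates {start}..{end}")
        rows.append((fid, biotype, str(rec["contig"]), str(rec["strand"]), start, end))
    return rows


def _read_sidecar(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "kind": str, "extra": str})
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sidecar missing columns {sorted(missing)}")
    return df


def load_annotation(
    gff_or_bed_path: str | Path,
    sidecar_tsv_path: str | Path | None = None,
    rdna_segments_path: str | Path | None = None,
    rdna_contig: str = "rDNA",
) -> AnnotationSet:
    """Load an annotation set from GFF3 (or BED6) plus the optional sidecar.

    Every snoRNA feature that has sidecar rows is promoted to a
    :class:`SnoRecord`; sidecar rows referencing unknown features, or box/
    guide intervals escaping the mature transcript, are hard errors.
    """
    path = Path(gff_or_bed_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        raw = _read_bed6_features(path)
    else:
        raw = _read_gff3_features(path)

    sidecar = None
    if sidecar_tsv_path is not None:
        sidecar = _read_sidecar(Path(sidecar_tsv_path))
        known = {fid for fid, *_ in raw}
        unknown = set(sidecar["feature_id"]) - known
        if unknown:
            raise ValueError(f"sidecar references unknown feature_id(s): {sorted(unknown)}")

    features: list[GeneFeature] = []
    for fid, biotype, contig, strand, start, end in raw:
        rows = None
        if sidecar is not None:
            rows = sidecar[sidecar["feature_id"] == fid]
            if len(rows) == 0:
                rows = None
        if biotype is Biotype.SNORNA and rows is not None:
            mature = rows[rows["record_kind"] == "mature"]
            if len(mature) != 1:
                raise ValueError(f"{fid}: sidecar must carry exactly one 'mature' row")
            m = mature.iloc[0]
            host = None if pd.isna(m["extra"]) or m["extra"] == "." else str(m["extra"])
            boxes = [
                BoxAnnotation(BoxKind(r["kind"]), int(r["rel_start"]), int(r["rel_end"]))
                for _, r in rows[rows["record_kind"] == "box"].iterrows()
            ]
            guides = [
                GuideRegion(
                    int(r["rel_start"]),
                    int(r["rel_end"]),
                    "" if pd.isna(r["kind"]) else str(r["kind"]),
                )
                for _, r in rows[rows["record_kind"] == "guide"].iterrows()
            ]
            features.append(
                SnoRecord(
                    feature_id=fid,
                    biotype=Biotype.SNORNA,
                    contig=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    sno_class=SnoClass(str(m["kind"])),
                    mature_start=start + int(m["rel_start"]),
                    mature_end=start + int(m["rel_end"]),
                    boxes=boxes,
                    guides=guides,
                    host_gene=host,
                )
            )
        else:
            features.append(GeneFeature(fid, biotype, contig, strand, start, end))

    segments: list[RdnaSegment] = []
    if rdna_segments_path is not None:
        seg_df = pd.read_csv(Path(rdna_segments_path), sep="\t")
        segments = [
            RdnaSegment(str(r["segment_id"]), int(r["start"]), int(r["end"]))
            for _, r in seg_df.iterrows()
        ]
    return AnnotationSet(features, rdna_contig=rdna_contig, rdna_segments=segments)


def write_annotation(annotation: AnnotationSet, out_prefix: str | Path) -> dict[str, Path]:
    """Write GFF3 + sidecar TSV (+ rDNA segment TSV); round-trips with
    :func:`load_annotation`."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gff_path = prefix.with_suffix(".gff3")
    sidecar_path = Path(str(prefix) + ".sidecar.tsv")
    paths = {"gff3": gff_path, "sidecar": sidecar_path}

    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for f in sorted(annotation, key=lambda f: (f.contig, f.start, f.feature_id)):
            gff.write(
                "\t".join(
                    [
                        f.contig,
                        "sdrnakit",
                        "ncRNA",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id};biotype={f.biotype.value}",
                    ]
                )
                + "\n"
            )

    rows = []
    for f in annotation:
        if not isinstance(f, SnoRecord):
            continue
        rows.append(
            {
                "feature_id": f.feature_id,
                "record_kind": "mature",
                "kind": f.sno_class.value,
                "rel_start": f.mature_start - f.start,
                "rel_end": f.mature_end - f.start,
                "extra": f.host_gene if f.host_gene is not None else ".",
            }
        )
        for box in f.boxes:
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "record_kind": "box",
                    "kind": box.kind.value,
                    "rel_start": box.start,
                    "rel_end": box.end,
                    "extra": ".",
                }
            )
        for g in f.guides:
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "record_kind": "guide",
                    "kind": g.target_label,
                    "rel_start": g.start,
                    "rel_end": g.end,
                    "extra": ".",
                }
            )
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(sidecar_path, sep="\t", index=False)

    if annotation.rdna_segments:
        rdna_path = Path(str(prefix) + ".rdna.tsv")
        pd.DataFrame(
            [
                {"segment_id": s.segment_id, "start": s.start, "end": s.end}
                for s in annotation.rdna_segments
            ]
        ).to_csv(rdna_path, sep="\t", index=False)
        paths["rdna"] = rdna_path
    return paths
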