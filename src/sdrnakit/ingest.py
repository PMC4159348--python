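"""Per-compartment library ingest.

Reads alignment files (SAM/BAM or BED6 + FASTQ/FASTA sequences), collapses
multiple placements of the same read into one logical read carrying a hit
count, and applies the unique-position filter (only reads with a single
reported placement are analyzed downstream).

``AlignedRead.seq`` is always the *sense* of the sequenced read: SAM stores
sequences in reference orientation, so minus-strand SAM records are
reverse-complemented on ingest; BED sequences come straight from the
FASTQ/FASTA record.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

#: expected insert size range after the gel size selection
MIN_READ_LEN, MAX_READ_LEN = 10, 40


@dataclass
class AlignedRead:
    read_id: str
    contig: str
    strand: str
    start: int
    end: int
    seq: str | None = None
    n_hits: int = 1

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"read {self.read_id}: malformed interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")
        if self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits must be >= 1")
        if self.seq is not None and len(self.seq) != len(self):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.seq)} != aligned span {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Library:
    """Reads of one compartment library plus its pre-alignment raw total."""

    compartment: str
    reads: list[AlignedRead] = field(default_factory=list)
    raw_read_count: int = 0

    def __post_init__(self):
        if self.raw_read_count < len(self.reads):
            raise ValueError(
                f"{self.compartment}: raw_read_count {self.raw_read_count} < "
                f"{len(self.reads)} aligned reads"
            )

    def __len__(self) -> int:
        return len(self.reads)


def _warn_length_outliers(reads: list[AlignedRead], label: str) -> None:
    n_out = sum(1 for r in reads if not MIN_READ_LEN <= len(r) <= MAX_READ_LEN)
    if n_out:
        log.warning(
            "%s: %d read(s) outside the %d-%d nt size-selection window (kept)",
            label, n_out, MIN_READ_LEN, MAX_READ_LEN,
        )


def _load_sam(path: Path) -> list[AlignedRead]:
    placements: dict[str, list[tuple[AlignedRead, int | None]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.reference_start < 0:
                raise ValueError(f"{path}: negative coordinate for read {rec.query_name}")
            seq = rec.query_sequence
            strand = "-" if rec.is_reverse else "+"
            if seq is not None and strand == "-":
                seq = reverse_complement(seq)
            start, end = rec.reference_start, rec.reference_end
            if seq is not None and len(seq) != end - start:
                log.warning(
                    "%s: read %s sequence length %d != aligned span %d; sequence dropped",
                    path, rec.query_name, len(seq), end - start,
                )
                seq = None
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            read = AlignedRead(
                read_id=rec.query_name,
                contig=rec.reference_name,
                strand=strand,
                start=start,
                end=end,
                seq=seq,
            )
            placements.setdefault(rec.query_name, []).append((read, nh))
    return _collapse(placements)


def _collapse(placements: dict[str, list[tuple[AlignedRead, int | None]]]) -> list[AlignedRead]:
    # multiplicity precedence: explicit NH-style tag > repeated read_id > 1
    reads = []
    for _, entries in placements.items():
        first, _ = entries[0]
        tags = [nh for _, nh in entries if nh is not None]
        n_hits = max(tags) if tags else len(entries)
        reads.append(replace(first, n_hits=max(n_hits, len(entries))))
    return reads


def _load_bed(path: Path, seq_source: Path | None) -> list[AlignedRead]:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["contig", "start", "end", "read_id", "score", "strand"],
            dtype={"contig": str, "read_id": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return []
    seqs = {}
    if seq_source is not None:
        fmt = "fastq" if Path(seq_source).suffix.lower() in {".fastq", ".fq"} else "fasta"
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(seq_source), fmt)}
    placements: dict[str, list[tuple[AlignedRead, int | None]]] = {}
    for idx, rec in df.iterrows():
        start, end = int(rec["start"]), int(rec["end"])
        if start < 0:
            raise ValueError(f"{path} line {idx + 1}: negative coordinate")
        rid = str(rec["read_id"])
        seq = None
        if seq_source is not None:
            if rid not in seqs:
                raise KeyError(f"{path}: read {rid!r} absent from sequence source {seq_source}")
            seq = seqs[rid]
        read = AlignedRead(
            read_id=rid, contig=str(rec["contig"]), strand=str(rec["strand"]),
            start=start, end=end, seq=seq,
        )
        placements.setdefault(rid, []).append((read, None))
    return _collapse(placements)


def load_library(
    alignment_path: str | Path,
    compartment: str,
    raw_read_count: int,
    seq_source: str | Path | None = None,
) -> Library:
    """Load one compartment library from SAM/BAM or BED6 (+ FASTQ/FASTA).

    Unmapped records are excluded.  Multiple placements of one read_id are
    collapsed into a single logical read whose ``n_hits`` reflects the
    NH-style tag when present, else the number of placements seen.
    """
    path = Path(alignment_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        reads = _load_bed(path, Path(seq_source) if seq_source else None)
    else:
        reads = _load_sam(path)
    _warn_length_outliers(reads, f"{compartment}:{path.name}")
    log.info("%s: loaded %d aligned reads (raw total %d)", compartment, len(reads), raw_read_count)
    return Library(compartment=compartment, reads=reads, raw_read_count=raw_read_count)


def filter_unique(library: Library) -> Library:
    """Keep only reads mapping to a unique position (n_hits == 1).

    Returns a new :class:`Library`; the input is unmodified.  Idempotent.
    """
    kept = [r for r in library.reads if r.n_hits == 1]
    dropped = len(library.reads) - len(kept)
    log.info(
        "%s: unique-position filter kept %d, dropped %d multi-mapped",
        library.compartment, len(kept), dropped,
    )
    return Library(
        compartment=library.compartment, reads=kept, raw_read_count=library.raw_read_count
    )
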