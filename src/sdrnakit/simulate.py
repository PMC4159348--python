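"""Synthetic reference + compartment-library generator.

Builds a toy genome with annotated sRNA loci (snoRNAs carrying planted box
C/C'/D/D' motifs and a guide region, miRNAs, snRNA/misc loci, an rDNA
contig with labelled 5'ETS/18S segments) and draws per-compartment read
libraries with the statistical structure the downstream analysis assumes:
compartment -> biotype -> locus -> end class (Bernoulli p5, fragment
anchored at the mature 5' or 3' terminus) -> length mixture -> substitution
errors -> emitted FASTQ + BED alignment + a truth row.

Everything is driven by one integer seed; outputs are byte-identical
across runs with the same config.

Truth-table box flags come in two flavours: ``boxes_planted`` (annotated
box interval fully inside the read, by construction) and
``boxes_detected`` (an independent vectorized Hamming scan of the emitted
sequence — uniform background sequence can legitimately contain motif
windows that were not planted, and errors can destroy planted ones).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    Biotype,
    BoxAnnotation,
    BoxKind,
    GeneFeature,
    GuideRegion,
    RdnaSegment,
    SnoClass,
    SnoRecord,
    write_annotation,
)
from .ingest import AlignedRead, Library

log = logging.getLogger(__name__)

COMPARTMENTS = ("cellular", "cytoplasm", "nucleus", "nucleolus")
_BIOTYPE_KEYS = ("miRNA", "snoRNA", "snRNA", "misc", "rRNA", "unannotated")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Full generative description of a synthetic experiment."""

    seed: int = 0
    depth: dict[str, int] = field(
        default_factory=lambda: {c: 5000 for c in COMPARTMENTS}
    )
    #: per-compartment weights over miRNA/snoRNA/snRNA/misc/rRNA/unannotated
    biotype_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            c: {"miRNA": 0.6, "snoRNA": 0.3, "snRNA": 0.02, "misc": 0.03,
                "rRNA": 0.02, "unannotated": 0.03}
            for c in COMPARTMENTS
        }
    )
    #: per-compartment weight vector over the snoRNA loci (len n_sno_loci)
    sno_weights: dict[str, list[float]] = field(default_factory=dict)
    #: per-locus probability that an sdRNA derives from the 5' end
    p5: list[float] = field(default_factory=list)
    sdrna_len_mix: dict[int, float] = field(
        default_factory=lambda: {19: 0.35, 20: 0.25, 25: 0.3, 26: 0.1}
    )
    #: per-locus-index overrides of the sdRNA length mixture
    sdrna_len_mix_per_locus: dict[int, dict[int, float]] = field(default_factory=dict)
    mirna_len_mix: dict[int, float] = field(
        default_factory=lambda: {21: 0.1, 22: 0.45, 23: 0.4, 24: 0.05}
    )
    epsilon: float = 0.0  # per-base substitution error rate
    multimap_frac: float = 0.0  # fraction of reads emitted with a second placement
    #: fraction of raw reads that aligned, used to back out raw_read_count metadata
    aligned_frac: dict[str, float] = field(
        default_factory=lambda: {c: 0.7 for c in COMPARTMENTS}
    )
    n_sno_loci: int = 24
    n_mirna_loci: int = 24
    n_snrna_loci: int = 2
    n_misc_loci: int = 3

    def __post_init__(self):
        rng = np.random.default_rng(self.seed + 1)
        if not self.sno_weights:
            w = np.exp(-np.arange(self.n_sno_loci) / 4.0)
            self.sno_weights = {c: list(w / w.sum()) for c in self.depth}
        if not self.p5:
            self.p5 = list(np.round(rng.uniform(0.1, 0.9, self.n_sno_loci), 2))
        self.validate()

    def validate(self) -> None:
        for comp, n in self.depth.items():
            if n <= 0:
                raise ValueError(f"depth for {comp} must be > 0")
        if not 0.0 <= self.epsilon <= 0.1:
            raise ValueError("epsilon must lie in [0, 0.1]")
        for comp, mix in self.biotype_mix.items():
            unknown = set(mix) - set(_BIOTYPE_KEYS)
            if unknown:
                raise ValueError(f"{comp}: unknown biotype keys {sorted(unknown)}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{comp}: biotype mixture does not sum to 1")
        for comp, w in self.sno_weights.items():
            if len(w) != self.n_sno_loci or abs(sum(w) - 1.0) > 1e-6:
                raise ValueError(f"{comp}: snoRNA locus weights invalid")
        for mix in [self.sdrna_len_mix, self.mirna_len_mix, *self.sdrna_len_mix_per_locus.values()]:
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError("length mixture does not sum to 1")
        if len(self.p5) != self.n_sno_loci:
            raise ValueError("p5 must have one entry per snoRNA locus")


def preset_paper_like() -> SimConfig:
    """Study-condition preset: three miRNA-dominated 22-23 nt libraries and a
    box C/D sdRNA-dominated nucleolar library with 19/25 nt fragment lengths
    and one locus (SNORD44-like) carrying 71% of the nucleolar snoRNA weight,
    emitted exclusively as 5'-end fragments.
    """
    n_sno = 24
    depth = {"cellular": 40000, "cytoplasm": 40000, "nucleus": 40000, "nucleolus": 20000}

    # conditional sRNA composition per compartment (biotype | sRNA), scaled by
    # the fraction of aligned reads mapping to annotated sRNA loci (~75% in
    # the non-nucleolar libraries); the remainder is unannotated + rDNA.
    def _mix(mirna, sno, snrna, misc, srna_share, rrna):
        s = mirna + sno + snrna + misc
        mix = {
            "miRNA": mirna / s * srna_share,
            "snoRNA": sno / s * srna_share,
            "snRNA": snrna / s * srna_share,
            "misc": misc / s * srna_share,
            "rRNA": rrna,
        }
        mix["unannotated"] = 1.0 - sum(mix.values())
        return mix

    biotype_mix = {
        "cellular": _mix(0.990, 0.0048, 0.0001, 0.0053, 0.75, 0.003),
        "cytoplasm": _mix(0.996, 0.0006, 0.0001, 0.0035, 0.72, 0.003),
        "nucleus": _mix(0.976, 0.0207, 0.0005, 0.0026, 0.72, 0.007),
        "nucleolus": {"miRNA": 0.068, "snoRNA": 0.93, "snRNA": 0.001, "misc": 0.001,
                      "rRNA": 0.0, "unannotated": 0.0},
    }

    # nucleolus: dominant locus 0 at 71% of snoRNA weight, rest exponential
    tail = np.exp(-np.arange(n_sno - 1) / 4.0)
    tail = 0.29 * tail / tail.sum()
    nucleolar_w = [0.71, *tail]
    # nuclear/cellular/cytoplasmic libraries share a different, heavy-tailed
    # locus profile (the dominant nucleolar locus sits mid-rank there)
    ranks = (np.arange(n_sno) + 5) % n_sno
    other = np.exp(-ranks / 4.0)
    other_w = list(other / other.sum())
    sno_weights = {
        "cellular": other_w,
        "cytoplasm": other_w,
        "nucleus": other_w,
        "nucleolus": nucleolar_w,
    }

    # heterogeneous 5'-end biases: the dominant locus is 5'-only; a few loci
    # are 3'-only, the rest intermediate
    p5 = [1.0, 0.9, 0.0, 0.8, 0.6, 1.0, 0.3, 0.0, 0.7, 0.5, 0.85, 0.4,
          0.95, 0.2, 0.75, 0.55, 0.0, 0.65, 0.9, 0.35, 0.8, 0.45, 0.6, 0.25]

    return SimConfig(
        seed=0,
        depth=depth,
        biotype_mix=biotype_mix,
        sno_weights=sno_weights,
        p5=p5,
        sdrna_len_mix={19: 0.35, 20: 0.25, 25: 0.3, 26: 0.1},
        sdrna_len_mix_per_locus={0: {19: 0.5, 25: 0.5}},
        mirna_len_mix={21: 0.1, 22: 0.45, 23: 0.4, 24: 0.05},
        epsilon=0.005,
        multimap_frac=0.02,
        aligned_frac={"cellular": 0.717, "cytoplasm": 0.695, "nucleus": 0.682,
                      "nucleolus": 0.577},
        n_sno_loci=n_sno,
    )


@dataclass
class Reference:
    genome: dict[str, str]
    annotation: AnnotationSet
    mature_seqs: dict[str, str]  # snoRNA id -> mature transcript sequence
    transcript_seqs: dict[str, str]  # non-sno feature id -> transcript sequence
    intergenic: list[tuple[str, int, int]]
    sno_ids: list[str]
    mirna_ids: list[str]
    other_ids: list[str]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_FLANK = 8  # nt of feature sequence either side of the mature snoRNA


def _make_sno_transcript(rng: np.random.Generator, mature_len: int):
    """Random mature sequence with box C, C', D', guide and D planted at
    fixed mature-relative positions."""
    L = mature_len
    seq = list(_random_seq(rng, L))
    layout = [
        (BoxKind.C, 5, "TGATGA"),
        (BoxKind.CPRIME, L // 2 - 10, "TGATGA"),
        (BoxKind.DPRIME, L // 2, "CTGA"),
        (BoxKind.D, L - 8, "CTGA"),
    ]
    boxes = []
    for kind, start, motif in layout:
        seq[start : start + len(motif)] = motif
        boxes.append(BoxAnnotation(kind, start, start + len(motif)))
    guide = GuideRegion(L - 20, L - 8, target_label=f"18S:{int(rng.integers(100, 1800))}")
    return "".join(seq), boxes, guide


def make_reference(config: SimConfig) -> Reference:
    """Generate the synthetic genome + annotation described by ``config``."""
    rng = np.random.default_rng(config.seed)
    features: list[GeneFeature] = []
    mature_seqs: dict[str, str] = {}
    transcript_seqs: dict[str, str] = {}
    intergenic: list[tuple[str, int, int]] = []
    sno_ids, mirna_ids, other_ids = [], [], []

    def build_contig(name, specs):
        """specs: list of (feature factory, transcript length incl. flanks)."""
        parts, pos = [], 0
        for make_feature, span in specs:
            gap = int(rng.integers(60, 150))
            if gap > 12:
                intergenic.append((name, pos + 5, pos + gap - 5))
            parts.append(_random_seq(rng, gap))
            pos += gap
            parts.append(make_feature(pos))
            pos += span
        tail = int(rng.integers(60, 150))
        intergenic.append((name, pos + 5, pos + tail - 5))
        parts.append(_random_seq(rng, tail))
        return "".join(parts)

    # --- snoRNA contig -----------------------------------------------------
    sno_specs = []
    for i in range(config.n_sno_loci):
        fid = f"snoS{i + 1:02d}"
        sno_ids.append(fid)
        mature_len = int(rng.integers(61, 101))
        strand = "+" if i % 2 == 0 else "-"
        mature, boxes, guide = _make_sno_transcript(rng, mature_len)
        mature_seqs[fid] = mature
        window = _random_seq(rng, _FLANK) + mature + _random_seq(rng, _FLANK)
        span = len(window)
        host = ["GAS5", "SHG1", "NOL5A"][i % 3]

        def factory(pos, fid=fid, strand=strand, window=window, mature_len=mature_len,
                    boxes=boxes, guide=guide, host=host):
            features.append(
                SnoRecord(
                    feature_id=fid, biotype=Biotype.SNORNA, contig="chrA", strand=strand,
                    start=pos, end=pos + len(window),
                    sno_class=SnoClass.CD,
                    mature_start=pos + _FLANK, mature_end=pos + _FLANK + mature_len,
                    boxes=list(boxes), guides=[guide], host_gene=host,
                )
            )
            return window if strand == "+" else _revcomp(window)

        sno_specs.append((factory, span))
    genome = {"chrA": build_contig("chrA", sno_specs)}

    # --- miRNA / snRNA / misc contig --------------------------------------
    other_specs = []

    def simple_locus(fid, biotype, length, strand, id_list):
        id_list.append(fid)
        seq = _random_seq(rng, length)
        transcript_seqs[fid] = seq

        def factory(pos, fid=fid, biotype=biotype, strand=strand, seq=seq):
            features.append(
                GeneFeature(fid, biotype, "chrB", strand, pos, pos + len(seq))
            )
            return seq if strand == "+" else _revcomp(seq)

        return factory, length

    for i in range(config.n_mirna_loci):
        other_specs.append(
            simple_locus(f"mirS{i + 1:02d}", Biotype.MIRNA, int(rng.integers(23, 26)),
                         "+" if i % 2 else "-", mirna_ids)
        )
    for i in range(config.n_snrna_loci):
        other_specs.append(
            simple_locus(f"snrS{i + 1}", Biotype.SNRNA, int(rng.integers(90, 150)), "+", other_ids)
        )
    misc_biotypes = [Biotype.YRNA, Biotype.VAULTRNA, Biotype.LINCRNA]
    for i in range(config.n_misc_loci):
        other_specs.append(
            simple_locus(f"miscS{i + 1}", misc_biotypes[i % 3], int(rng.integers(90, 200)),
                         "+", other_ids)
        )
    genome["chrB"] = build_contig("chrB", other_specs)

    # --- rDNA contig -------------------------------------------------------
    genome["rDNA"] = _random_seq(rng, 2000)
    segments = [RdnaSegment("5ETS", 0, 800), RdnaSegment("18S", 800, 2000)]

    annotation = AnnotationSet(features, rdna_contig="rDNA", rdna_segments=segments)
    _check_no_overlap(annotation)
    return Reference(
        genome=genome, annotation=annotation, mature_seqs=mature_seqs,
        transcript_seqs=transcript_seqs, intergenic=intergenic,
        sno_ids=sno_ids, mirna_ids=mirna_ids, other_ids=other_ids,
    )


def _check_no_overlap(annotation: AnnotationSet) -> None:
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in annotation:
        by_contig.setdefault(f.contig, []).append(f)
    for contig, feats in by_contig.items():
        feats.sort(key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            if b.start < a.end:
                raise ValueError(f"{contig}: loci {a.feature_id} and {b.feature_id} overlap")


def write_reference(reference: Reference, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA + GFF3/sidecar/rDNA-segment annotation files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name in sorted(reference.genome):
            fh.write(f">{name}\n")
            seq = reference.genome[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths = write_annotation(reference.annotation, outdir / "annotation")
    paths["genome"] = fasta
    return paths


# ---------------------------------------------------------------------------
# library simulation


def _detect_boxes(seq: str) -> set[str]:
    """Truth-side motif detector: vectorized Hamming scan, independent of the
    classifier's implementation."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found = set()
    for label, motif, max_mm in (("C", b"TGATGA", 1), ("D", b"CTGA", 0)):
        m = np.frombuffer(motif, dtype=np.uint8)
        if len(arr) >= len(m):
            windows = np.lib.stride_tricks.sliding_window_view(arr, len(m))
            if ((windows != m).sum(axis=1) <= max_mm).any():
                found.add(label)
    return found


TRUTH_COLUMNS = [
    "read_id", "compartment", "feature_id", "biotype", "contig", "strand",
    "start", "end", "length", "end_class", "boxes_planted", "boxes_detected",
    "guide_planted", "n_hits", "n_errors", "error_positions",
]


@dataclass
class SimOutput:
    libraries: dict[str, Library]
    truth: pd.DataFrame
    paths: dict[str, dict[str, Path]] = field(default_factory=dict)


def _apply_errors(rng: np.random.Generator, seq: str, epsilon: float) -> tuple[str, list[int]]:
    if epsilon <= 0:
        return seq, []
    n_err = int(rng.binomial(len(seq), epsilon))
    if n_err == 0:
        return seq, []
    positions = sorted(rng.choice(len(seq), size=n_err, replace=False).tolist())
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out), positions


def _draw_length(rng, mix_lens, mix_probs, upper):
    """Draw from the length mixture, resampling lengths exceeding ``upper``."""
    n_resampled = 0
    for _ in range(100):
        L = int(rng.choice(mix_lens, p=mix_probs))
        if L <= upper:
            return L, n_resampled
        n_resampled += 1
    raise ValueError("length mixture incompatible with locus length")


def simulate_libraries(
    config: SimConfig, reference: Reference, outdir: str | Path | None = None
) -> SimOutput:
    """Draw all compartment libraries plus the ground-truth table.

    When ``outdir`` is given, FASTQ + BED6 alignments per compartment and
    the truth TSV are also written (byte-identical under a fixed seed).
    """
    rng = np.random.default_rng(config.seed + 10_000)
    ann = reference.annotation
    truth_rows: list[dict] = []
    libraries: dict[str, Library] = {}
    n_resampled_total = 0

    sdrna_mixes = {}
    for idx in range(config.n_sno_loci):
        mix = config.sdrna_len_mix_per_locus.get(idx, config.sdrna_len_mix)
        lens = np.array(sorted(mix))
        probs = np.array([mix[l] for l in lens], dtype=float)
        sdrna_mixes[idx] = (lens, probs / probs.sum())
    mir_lens = np.array(sorted(config.mirna_len_mix))
    mir_probs = np.array([config.mirna_len_mix[l] for l in mir_lens], dtype=float)
    mir_probs /= mir_probs.sum()

    inter_lens = np.array([e - s for _, s, e in reference.intergenic], dtype=float)
    inter_probs = inter_lens / inter_lens.sum()

    for comp in config.depth:
        n = config.depth[comp]
        mix = config.biotype_mix[comp]
        bio_keys = list(_BIOTYPE_KEYS)
        bio_probs = np.array([mix.get(k, 0.0) for k in bio_keys], dtype=float)
        bio_probs /= bio_probs.sum()
        bio_draws = rng.choice(len(bio_keys), size=n, p=bio_probs)
        sno_w = np.array(config.sno_weights[comp], dtype=float)
        sno_w /= sno_w.sum()

        reads: list[AlignedRead] = []
        extra_placements: list[tuple[str, str, int, int, str]] = []
        for i in range(n):
            rid = f"{comp}_{i:07d}"
            kind = bio_keys[bio_draws[i]]
            end_class = ""
            boxes_planted: set[str] = set()
            guide_planted = False
            feature_id = ""

            if kind == "snoRNA":
                j = int(rng.choice(len(sno_w), p=sno_w))
                feature_id = reference.sno_ids[j]
                sno: SnoRecord = ann.features[feature_id]  # type: ignore[assignment]
                lens, probs = sdrna_mixes[j]
                L, n_res = _draw_length(rng, lens, probs, sno.mature_len)
                n_resampled_total += n_res
                five = bool(rng.random() < config.p5[j])
                end_class = "FIVE_PRIME" if five else "THREE_PRIME"
                rel = (0, L) if five else (sno.mature_len - L, sno.mature_len)
                seq = reference.mature_seqs[feature_id][rel[0] : rel[1]]
                start, end = sno.mature_to_genomic(*rel)
                contig, strand = sno.contig, sno.strand
                pooled = {BoxKind.C: "C", BoxKind.CPRIME: "C",
                          BoxKind.D: "D", BoxKind.DPRIME: "D"}
                boxes_planted = {
                    pooled[b.kind] for b in sno.boxes
                    if b.kind in pooled and rel[0] <= b.start and b.end <= rel[1]
                }
                guide_planted = any(
                    rel[0] <= g.start and g.end <= rel[1] for g in sno.guides
                )
            elif kind == "miRNA":
                fid = reference.mirna_ids[int(rng.integers(len(reference.mirna_ids)))]
                feature_id = fid
                feat = ann.features[fid]
                L, n_res = _draw_length(rng, mir_lens, mir_probs, len(feat))
                n_resampled_total += n_res
                seq = reference.transcript_seqs[fid][:L]  # anchored at transcript 5' end
                contig, strand = feat.contig, feat.strand
                start, end = (feat.start, feat.start + L) if strand == "+" else (feat.end - L, feat.end)
            elif kind in ("snRNA", "misc"):
                pool = reference.other_ids
                fid = pool[int(rng.integers(len(pool)))]
                feat = ann.features[fid]
                if (kind == "snRNA") != (feat.biotype is Biotype.SNRNA):
                    fid = next(
                        f for f in pool
                        if (ann.features[f].biotype is Biotype.SNRNA) == (kind == "snRNA")
                    )
                    feat = ann.features[fid]
                feature_id = fid
                L = int(rng.integers(20, 31))
                off = int(rng.integers(0, len(feat) - L + 1))
                seq = reference.transcript_seqs[fid][off : off + L]
                contig, strand = feat.contig, feat.strand
                if strand == "+":
                    start, end = feat.start + off, feat.start + off + L
                else:
                    start, end = feat.end - off - L, feat.end - off
            elif kind == "rRNA":
                seg = ann.rdna_segments[0 if rng.random() < 0.8 else 1]
                feature_id = seg.segment_id
                L = int(rng.integers(20, 31))
                start = int(rng.integers(seg.start, seg.end - L))
                end = start + L
                contig, strand = ann.rdna_contig, "+"
                seq = reference.genome[contig][start:end]
            else:  # unannotated background
                k = int(rng.choice(len(inter_probs), p=inter_probs))
                contig, g_start, g_end = reference.intergenic[k]
                L = int(rng.integers(20, 31))
                L = min(L, g_end - g_start)
                start = int(rng.integers(g_start, g_end - L + 1))
                end = start + L
                strand = "+"
                seq = reference.genome[contig][start:end]

            seq, err_pos = _apply_errors(rng, seq, config.epsilon)
            n_hits = 1
            if config.multimap_frac > 0 and rng.random() < config.multimap_frac:
                n_hits = 2
                k = int(rng.choice(len(inter_probs), p=inter_probs))
                c2, s2, e2 = reference.intergenic[k]
                L2 = min(len(seq), e2 - s2)
                p2 = int(rng.integers(s2, e2 - L2 + 1))
                extra_placements.append((rid, c2, p2, p2 + L2, "+"))

            reads.append(
                AlignedRead(rid, contig, strand, start, end, seq=seq, n_hits=n_hits)
            )
            truth_rows.append(
                {
                    "read_id": rid, "compartment": comp, "feature_id": feature_id,
                    "biotype": {"misc": "misc", "unannotated": ""}.get(kind, kind),
                    "contig": contig, "strand": strand, "start": start, "end": end,
                    "length": len(seq), "end_class": end_class,
                    "boxes_planted": ",".join(sorted(boxes_planted)),
                    "boxes_detected": ",".join(sorted(_detect_boxes(seq))),
                    "guide_planted": guide_planted, "n_hits": n_hits,
                    "n_errors": len(err_pos),
                    "error_positions": ",".join(map(str, err_pos)),
                }
            )

        raw = int(round(n / config.aligned_frac.get(comp, 0.7)))
        libraries[comp] = Library(compartment=comp, reads=reads, raw_read_count=raw)
        libraries[comp]._extra_placements = extra_placements  # type: ignore[attr-defined]

    if n_resampled_total:
        log.info("resampled %d length draws exceeding the mature length", n_resampled_total)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    out = SimOutput(libraries=libraries, truth=truth)
    if outdir is not None:
        out.paths = _write_libraries(libraries, truth, Path(outdir))
    return out


def _write_libraries(
    libraries: dict[str, Library], truth: pd.DataFrame, outdir: Path
) -> dict[str, dict[str, Path]]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for comp, lib in libraries.items():
        fastq = outdir / f"{comp}.fastq"
        bed = outdir / f"{comp}.bed"
        with open(fastq, "w") as fq, open(bed, "w") as bd:
            for r in lib.reads:
                fq.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
                bd.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")
            for rid, contig, start, end, strand in getattr(lib, "_extra_placements", []):
                bd.write(f"{contig}\t{start}\t{end}\t{rid}\t0\t{strand}\n")
        paths[comp] = {"fastq": fastq, "bed": bed, "raw_read_count": lib.raw_read_count}
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = {"tsv": truth_path}
    return paths


def apply_overrides(config: SimConfig, overrides: dict) -> SimConfig:
    """Return a copy of ``config`` with dataclass-field overrides applied."""
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown SimConfig keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    merged = {}
    for key, value in overrides.items():
        current = getattr(config, key)
        if isinstance(current, dict) and isinstance(value, dict) and key in (
            "depth", "biotype_mix", "aligned_frac", "sno_weights"
        ):
            value = {**current, **value}
        merged[key] = value
    return replace(config, **merged)
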