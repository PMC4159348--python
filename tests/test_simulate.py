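"""Synthetic reference and library generator: determinism, construction
guarantees, statistical recovery, end-to-end truth agreement."""
import numpy as np
import pytest
from scipy import stats

from sdrnakit.annotation import BoxKind, SnoRecord
from sdrnakit.classifier import call_reads
from sdrnakit.ingest import filter_unique, load_library
from sdrnakit.profiler import assign_reads
from sdrnakit.simulate import (
    SimConfig,
    apply_overrides,
    make_reference,
    preset_paper_like,
    simulate_libraries,
    write_reference,
)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="module")
def small_config():
    return apply_overrides(
        SimConfig(seed=3),
        {"depth": {c: 1500 for c in ("cellular", "cytoplasm", "nucleus", "nucleolus")}},
    )


@pytest.fixture(scope="module")
def small_reference(small_config):
    return make_reference(small_config)


class TestMakeReference:
    def test_planted_box_c_matches_consensus(self, small_reference):
        for fid in small_reference.sno_ids:
            rec = small_reference.annotation.features[fid]
            mature = small_reference.mature_seqs[fid]
            for box in rec.boxes:
                motif = mature[box.start : box.end]
                if box.kind in (BoxKind.C, BoxKind.CPRIME):
                    assert _hamming(motif, "TGATGA") <= 1
                elif box.kind in (BoxKind.D, BoxKind.DPRIME):
                    assert motif == "CTGA"

    def test_loci_do_not_overlap(self, small_reference):
        by_contig = {}
        for f in small_reference.annotation:
            by_contig.setdefault(f.contig, []).append((f.start, f.end))
        for ivs in by_contig.values():
            ivs.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(ivs, ivs[1:]))

    def test_genome_sequence_matches_annotation(self, small_reference):
        """The genomic slice at each snoRNA mature interval equals the mature
        transcript (reverse-complemented on the - strand)."""
        comp = str.maketrans("ACGT", "TGCA")
        for fid in small_reference.sno_ids:
            rec: SnoRecord = small_reference.annotation.features[fid]
            genomic = small_reference.genome[rec.contig][rec.mature_start : rec.mature_end]
            expected = small_reference.mature_seqs[fid]
            if rec.strand == "-":
                expected = expected.translate(comp)[::-1]
            assert genomic == expected

    def test_same_seed_byte_identical_fasta(self, small_config, tmp_path):
        p1 = write_reference(make_reference(small_config), tmp_path / "a")["genome"]
        p2 = write_reference(make_reference(small_config), tmp_path / "b")["genome"]
        assert p1.read_bytes() == p2.read_bytes()

    def test_minimum_locus_counts(self, small_reference):
        assert len(small_reference.sno_ids) >= 20
        assert len(small_reference.mirna_ids) >= 20
        assert small_reference.annotation.rdna_segments[0].segment_id == "5ETS"


class TestSimulateLibraries:
    def test_pure_snorna_error_free_reads_are_mature_substrings(self):
        config = apply_overrides(
            SimConfig(seed=5, epsilon=0.0),
            {
                "depth": {"nucleolus": 800},
                "biotype_mix": {
                    "nucleolus": {"miRNA": 0.0, "snoRNA": 1.0, "snRNA": 0.0,
                                  "misc": 0.0, "rRNA": 0.0, "unannotated": 0.0}
                },
                "aligned_frac": {"nucleolus": 0.6},
            },
        )
        ref = make_reference(config)
        sim = simulate_libraries(config, ref)
        for read in sim.libraries["nucleolus"].reads:
            fid = sim.truth.loc[sim.truth["read_id"] == read.read_id, "feature_id"].iloc[0]
            assert read.seq in ref.mature_seqs[fid]

    def test_p5_one_yields_only_five_prime_truth(self):
        config = apply_overrides(
            SimConfig(seed=5),
            {
                "depth": {"nucleolus": 500},
                "biotype_mix": {
                    "nucleolus": {"miRNA": 0.0, "snoRNA": 1.0, "snRNA": 0.0,
                                  "misc": 0.0, "rRNA": 0.0, "unannotated": 0.0}
                },
                "p5": [1.0] * 24,
            },
        )
        ref = make_reference(config)
        sim = simulate_libraries(config, ref)
        sdrna = sim.truth[(sim.truth["compartment"] == "nucleolus")
                          & (sim.truth["biotype"] == "snoRNA")]
        assert len(sdrna) == 500
        assert (sdrna["end_class"] == "FIVE_PRIME").all()

    def test_biotype_fraction_within_binomial_ci(self):
        """Observed snoRNA fraction lies in the 99% binomial CI of the
        generated mixture weight (n = 5,000)."""
        p, n = 0.93, 5000
        config = apply_overrides(
            SimConfig(seed=9),
            {
                "depth": {"nucleolus": n},
                "biotype_mix": {
                    "nucleolus": {"miRNA": 0.068, "snoRNA": p, "snRNA": 0.001,
                                  "misc": 0.001, "rRNA": 0.0, "unannotated": 0.0}
                },
            },
        )
        ref = make_reference(config)
        sim = simulate_libraries(config, ref)
        observed = (
            (sim.truth["compartment"] == "nucleolus") & (sim.truth["biotype"] == "snoRNA")
        ).sum()
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= observed <= hi

    def test_determinism_byte_identical_outputs(self, tmp_path):
        config = apply_overrides(SimConfig(seed=4, epsilon=0.01, multimap_frac=0.05),
                                 {"depth": {c: 400 for c in SimConfig().depth}})
        for d in ("run1", "run2"):
            simulate_libraries(config, make_reference(config), outdir=tmp_path / d)
        for name in ("nucleolus.fastq", "nucleolus.bed", "cellular.fastq", "truth.tsv"):
            assert (tmp_path / "run1" / name).read_bytes() == (
                tmp_path / "run2" / name
            ).read_bytes()

    def test_written_files_round_trip_through_ingest(self, tmp_path):
        """BED + FASTQ emitted by the simulator reload into the same logical
        reads (coordinates, strand, sense sequence, hit counts)."""
        config = apply_overrides(SimConfig(seed=8, multimap_frac=0.1),
                                 {"depth": {c: 300 for c in SimConfig().depth}})
        ref = make_reference(config)
        sim = simulate_libraries(config, ref, outdir=tmp_path)
        lib = sim.libraries["nucleus"]
        loaded = load_library(
            tmp_path / "nucleus.bed", "nucleus", lib.raw_read_count,
            seq_source=tmp_path / "nucleus.fastq",
        )
        by_id = {r.read_id: r for r in loaded.reads}
        assert len(loaded.reads) == len(lib.reads)
        for r in lib.reads:
            q = by_id[r.read_id]
            assert (q.contig, q.strand, q.start, q.end, q.seq) == (
                r.contig, r.strand, r.start, r.end, r.seq
            )
            assert q.n_hits == r.n_hits


def _classify_compartment(config, comp="nucleolus"):
    ref = make_reference(config)
    sim = simulate_libraries(config, ref)
    unique = filter_unique(sim.libraries[comp])
    assignments = assign_reads(unique, ref.annotation)
    calls, n_flanking = call_reads(assignments, ref.annotation, comp)
    assert n_flanking == 0
    return ref, sim, calls


class TestTruthRecovery:
    def test_error_free_recovery_is_exact(self):
        """At epsilon = 0 (and no multi-mapping) the classifier reproduces the
        truth table's end classes and detected box flags for every sdRNA read."""
        config = apply_overrides(
            preset_paper_like(),
            {"seed": 2, "epsilon": 0.0, "multimap_frac": 0.0,
             "depth": {"cellular": 500, "cytoplasm": 500, "nucleus": 1000,
                       "nucleolus": 3000}},
        )
        _, sim, calls = _classify_compartment(config)
        truth = sim.truth.set_index("read_id")
        sdrna_truth = truth[(truth["compartment"] == "nucleolus")
                            & (truth["biotype"] == "snoRNA")]
        assert len(calls) == len(sdrna_truth)
        for c in calls:
            row = truth.loc[c.read_id]
            assert c.end_class.value == row["end_class"]
            detected = set(row["boxes_detected"].split(",")) - {""}
            assert set(c.boxes_found) == detected
            assert c.guide_retained == bool(row["guide_planted"])

    def test_error_rate_bounds_box_flag_disagreement(self):
        """With epsilon > 0, planted motifs can only be missed when errors hit
        the motif window: a C hit survives one error (tolerance 1), so misses
        need >=2 errors in its 6-mer; a D hit dies with any error in its 4-mer.
        Observed miss rates are bounded by those probabilities (x2 slack)."""
        eps = 0.05
        config = apply_overrides(
            preset_paper_like(),
            {"seed": 6, "epsilon": eps, "multimap_frac": 0.0,
             "depth": {"cellular": 200, "cytoplasm": 200, "nucleus": 200,
                       "nucleolus": 8000}},
        )
        _, sim, calls = _classify_compartment(config)
        found = {c.read_id: c.boxes_found for c in calls}
        truth = sim.truth[(sim.truth["compartment"] == "nucleolus")
                          & (sim.truth["biotype"] == "snoRNA")]
        misses = {"C": [0, 0], "D": [0, 0]}  # [missed, planted]
        for _, row in truth.iterrows():
            planted = set(row["boxes_planted"].split(",")) - {""}
            for kind in planted:
                misses[kind][1] += 1
                misses[kind][0] += kind not in found[row["read_id"]]
        p_miss_c = 1 - (1 - eps) ** 6 - 6 * eps * (1 - eps) ** 5  # >=2 errors in 6
        p_miss_d = 1 - (1 - eps) ** 4  # >=1 error in 4
        assert misses["C"][0] / misses["C"][1] <= 2 * p_miss_c
        assert misses["D"][0] / misses["D"][1] <= 2 * p_miss_d

    def test_motif_recovery_rate_at_least_planted_rate(self):
        """Mismatch tolerance can only add hits: the detected box C rate is at
        least the planted inclusion rate."""
        config = apply_overrides(
            preset_paper_like(),
            {"seed": 2, "epsilon": 0.0, "multimap_frac": 0.0,
             "depth": {"cellular": 200, "cytoplasm": 200, "nucleus": 200,
                       "nucleolus": 4000}},
        )
        _, sim, calls = _classify_compartment(config)
        truth = sim.truth[(sim.truth["compartment"] == "nucleolus")
                          & (sim.truth["biotype"] == "snoRNA")]
        planted_rate = truth["boxes_planted"].str.contains("C").mean()
        detected_rate = np.mean([("C" in c.boxes_found) for c in calls])
        assert detected_rate >= planted_rate


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="epsilon"):
        SimConfig(seed=0, epsilon=0.5)
    with pytest.raises(ValueError, match="sum to 1"):
        apply_overrides(
            SimConfig(seed=0),
            {"biotype_mix": {"nucleolus": {"miRNA": 0.9, "snoRNA": 0.9, "snRNA": 0.0,
                                           "misc": 0.0, "rRNA": 0.0, "unannotated": 0.0}}},
        )
    with pytest.raises(ValueError, match="unknown SimConfig keys"):
        apply_overrides(SimConfig(seed=0), {"not_a_key": 1})
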