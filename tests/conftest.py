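import pytest

from sdrnakit.annotation import (
    AnnotationSet,
    Biotype,
    BoxAnnotation,
    BoxKind,
    GeneFeature,
    GuideRegion,
    RdnaSegment,
    SnoClass,
    SnoRecord,
)
from sdrnakit.simulate import (
    apply_overrides,
    make_reference,
    preset_paper_like,
    simulate_libraries,
)


@pytest.fixture
def sno_plus():
    """61 nt mature snoRNA on the + strand, mature interval [100, 161)."""
    return SnoRecord(
        feature_id="snoP",
        biotype=Biotype.SNORNA,
        contig="chr1",
        strand="+",
        start=90,
        end=170,
        sno_class=SnoClass.CD,
        mature_start=100,
        mature_end=161,
        boxes=[BoxAnnotation(BoxKind.C, 5, 11), BoxAnnotation(BoxKind.D, 53, 57)],
        guides=[GuideRegion(30, 42, "18S:1678")],
    )


@pytest.fixture
def sno_minus():
    """Mirror image of sno_plus on the - strand (same mature-relative layout)."""
    return SnoRecord(
        feature_id="snoM",
        biotype=Biotype.SNORNA,
        contig="chr1",
        strand="-",
        start=90,
        end=170,
        sno_class=SnoClass.CD,
        mature_start=100,
        mature_end=161,
        boxes=[BoxAnnotation(BoxKind.C, 5, 11), BoxAnnotation(BoxKind.D, 53, 57)],
        guides=[GuideRegion(30, 42, "18S:1678")],
    )


@pytest.fixture
def tiny_annotation(sno_plus, sno_minus):
    features = [
        sno_plus,
        sno_minus,
        GeneFeature("mir1", Biotype.MIRNA, "chr2", "+", 500, 523),
        GeneFeature("y1", Biotype.YRNA, "chr2", "+", 800, 900),
    ]
    return AnnotationSet(
        features,
        rdna_contig="rDNA",
        rdna_segments=[RdnaSegment("5ETS", 0, 800), RdnaSegment("18S", 800, 2000)],
    )


@pytest.fixture(scope="session")
def preset_sim():
    """Study-condition simulation: fixed seed, 20,000 nucleolar reads, with
    the non-nucleolar libraries scaled down for runtime."""
    config = apply_overrides(
        preset_paper_like(),
        {
            "seed": 1,
            "depth": {
                "cellular": 4000,
                "cytoplasm": 3000,
                "nucleus": 6000,
                "nucleolus": 20000,
            },
        },
    )
    reference = make_reference(config)
    sim = simulate_libraries(config, reference)
    return config, reference, sim


@pytest.fixture(scope="session")
def preset_analysis(preset_sim):
    """Unique-filtering + assignment + sdRNA calls on the preset simulation."""
    from sdrnakit.classifier import build_locus_table, call_reads
    from sdrnakit.ingest import filter_unique
    from sdrnakit.profiler import assign_reads

    config, reference, sim = preset_sim
    assignments, calls = {}, {}
    for comp, lib in sim.libraries.items():
        unique = filter_unique(lib)
        assignments[comp] = assign_reads(unique, reference.annotation)
        calls[comp], _ = call_reads(assignments[comp], reference.annotation, comp)
    locus_table = build_locus_table([c for cs in calls.values() for c in cs])
    return {
        "config": config,
        "reference": reference,
        "sim": sim,
        "assignments": assignments,
        "calls": calls,
        "locus_table": locus_table,
    }
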