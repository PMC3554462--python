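"""Synthetic genomes, layered annotation with truth, and reference fixtures."""

import math

import numpy as np
import pytest

from locusconvert import GenomicInterval, OverlapParams, convert_ids, qualifies
from locusconvert.synth import (
    AnnotationLayerSpec,
    REFERENCE_OUTCOMES,
    SyntheticGenomeSpec,
    build_registry,
    generate_genome,
    generate_layers,
    probe_transcript_example,
    reference_overlap_example,
    solve_reference_example,
)


class TestGenerateGenome:
    def test_determinism_under_seed(self):
        spec = SyntheticGenomeSpec(n_chroms=2, chrom_length=500, seed=1)
        assert generate_genome(spec) == generate_genome(spec)

    def test_different_seeds_differ(self):
        a = generate_genome(SyntheticGenomeSpec(chrom_length=500, seed=1))
        b = generate_genome(SyntheticGenomeSpec(chrom_length=500, seed=2))
        assert a != b

    def test_gc_content_within_binomial_bound(self):
        n = 100_000
        g = generate_genome(SyntheticGenomeSpec(chrom_length=n, seed=7, gc_fraction=0.5))
        gc = sum(c in "GC" for c in g["chr1"]) / n
        assert abs(gc - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_skewed_gc(self):
        n = 50_000
        g = generate_genome(SyntheticGenomeSpec(chrom_length=n, seed=7, gc_fraction=0.2))
        gc = sum(c in "GC" for c in g["chr1"]) / n
        assert abs(gc - 0.2) < 3 * math.sqrt(0.2 * 0.8 / n)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(n_chroms=0)
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chrom_length=0)
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(gc_fraction=1.5)


@pytest.fixture(scope="module")
def layered():
    genome = generate_genome(SyntheticGenomeSpec(n_chroms=2, chrom_length=50_000, seed=11))
    coarse = AnnotationLayerSpec("tx", 60, 800, 2500, role="transcript")
    fine = AnnotationLayerSpec("probe", 300, 25, 25, role="probe", p_inside=0.9)
    return generate_layers(genome, coarse, fine, seed=11)


class TestGenerateLayers:
    def test_truth_is_consistent_with_containment_predicate(self, layered):
        coarse, fine, truth = layered
        spans = {c.id: c.intervals[0] for c in coarse}
        within = OverlapParams("within")
        for fr in fine:
            fiv = fr.intervals[0]
            expect = {
                cid
                for cid, civ in spans.items()
                if civ.chrom == fiv.chrom and qualifies(fiv, civ, within)
            }
            assert truth[fr.id] == expect

    def test_nesting_produces_multi_target_probes(self, layered):
        """Coarse features may overlap, so some probe has >= 2 truth targets
        (the n-m relation) and most probes have >= 1 (placed inside)."""
        _, fine, truth = layered
        sizes = [len(truth[f.id]) for f in fine]
        assert max(sizes) >= 2
        assert sum(s >= 1 for s in sizes) / len(sizes) > 0.7

    def test_forced_nesting_is_n_to_1(self):
        genome = generate_genome(SyntheticGenomeSpec(chrom_length=5000, seed=3))
        coarse = AnnotationLayerSpec("tx", 1, 3000, 4000)
        fine = AnnotationLayerSpec("probe", 20, 25, 25, p_inside=1.0)
        _, fine_recs, truth = generate_layers(genome, coarse, fine, seed=3)
        assert all(truth[f.id] == {"tx_1"} for f in fine_recs)

    def test_pipeline_on_generated_truth_is_perfectly_accurate(self, layered):
        from locusconvert.evaluate import accuracy, evaluate_conversion

        coarse, fine, truth = layered
        reg = build_registry(coarse, fine)
        rep = convert_ids(reg, [f.id for f in fine], "probe", ["tx"], OverlapParams("within"))
        res = evaluate_conversion(rep, truth, [f.id for f in fine])
        assert accuracy(res.counts) == 100.0

    def test_fine_must_be_smaller_than_coarse(self):
        genome = generate_genome(SyntheticGenomeSpec(chrom_length=1000, seed=0))
        with pytest.raises(ValueError):
            generate_layers(
                genome,
                AnnotationLayerSpec("a", 5, 50, 100),
                AnnotationLayerSpec("b", 5, 100, 200),
            )


class TestReferenceOverlapExample:
    def test_frozen_fixture_satisfies_all_outcome_statements(self):
        subjects, queries = reference_overlap_example()
        for p, want in REFERENCE_OUTCOMES.items():
            for qn, q in queries.items():
                got = {sn for sn, s in subjects.items() if qualifies(q, s, p)}
                assert got == want[qn], (qn, p)

    def test_search_recovers_the_frozen_solution(self):
        """The exhaustive coordinate search must find a solution (otherwise
        the overlap semantics are wrong) and, taking the lexicographically
        smallest, exactly the frozen one."""
        sol = solve_reference_example()
        assert sol is not None
        subjects, queries = sol
        frozen_s, frozen_q = reference_overlap_example()
        assert subjects == {n: (iv.start, iv.end) for n, iv in frozen_s.items()}
        assert queries == {n: (iv.start, iv.end) for n, iv in frozen_q.items()}

    def test_tree_engine_reproduces_hit_sets(self):
        """The interval-tree search, not just the pairwise predicate, yields
        the published hit sets."""
        from locusconvert import IntervalTree

        subjects, queries = reference_overlap_example()
        tree = IntervalTree("ref")
        for name, iv in subjects.items():
            tree.insert(iv, name)
        for p, want in REFERENCE_OUTCOMES.items():
            for qn, q in queries.items():
                got = {pl for _, pl in tree.search_overlaps(q, p)}
                assert got == want[qn]


class TestProbeTranscriptExample:
    def test_conversion_outcome(self):
        reg = probe_transcript_example()
        rep = convert_ids(reg, ["probe_A"], "probe", ["transcript"])
        assert {h.subject_id for h in rep.hits} == {"transcript2", "transcript3"}

    def test_empty_query_list(self):
        reg = probe_transcript_example()
        rep = convert_ids(reg, [], "probe", ["transcript"])
        assert rep.hits == [] and rep.unconverted == []

    def test_oracle_recount(self):
        """Recount hits directly from exon coordinates."""
        reg = probe_transcript_example()
        probe = reg.intervals_for_id("probe_A", "probe")[0]
        expected = set()
        for tid, rec in reg.namespaces["transcript"].items():
            shared = sum(
                max(0, min(probe.end, ex.end) - max(probe.start, ex.start) + 1)
                for ex in rec.intervals
            )
            if shared >= 1:
                expected.add(tid)
        rep = convert_ids(reg, ["probe_A"], "probe", ["transcript"])
        assert {h.subject_id for h in rep.hits} == expected == {"transcript2", "transcript3"}
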