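"""Short-sequence mapping: hits, report modes, suppression, fragmentation."""

import random

import pytest

from locusconvert import filter_best_fraction, fragment_sequence, map_sequence
from locusconvert.mapping import reverse_complement


def brute_force_hits(genome, read, max_mismatch):
    """Independent oracle: Hamming scan over every offset and both strands."""
    out = []
    read = read.upper()
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for strand, pat in (("+", read), ("-", reverse_complement(read))):
            for off in range(len(seq) - len(pat) + 1):
                mm = sum(
                    1
                    for a, b in zip(pat, seq[off : off + len(pat)])
                    if a != b or a == "N" or b == "N"
                )
                if mm <= max_mismatch:
                    out.append((chrom, off + 1, strand, mm))
    out.sort(key=lambda t: (t[0], t[1], t[2] != "+"))
    return out


@pytest.fixture(scope="module")
def genome():
    rng = random.Random(99)
    return {
        "chrA": "".join(rng.choice("ACGT") for _ in range(2500)),
        "chrB": "".join(rng.choice("ACGT") for _ in range(1500)),
    }


class TestMapSequence:
    def test_planted_exact_match(self, genome):
        read = genome["chrA"][99:149]
        res = map_sequence(genome, read, max_mismatch=0)
        exact = [h for h in res.hits if h.interval.chrom == "chrA" and h.interval.strand == "+"]
        assert any((h.interval.start, h.interval.end) == (100, 149) for h in exact)

    def test_all_best_keeps_only_minimum_stratum(self):
        rng = random.Random(5)
        base = "".join(rng.choice("ACGT") for _ in range(60))
        mutated = list(base)
        mutated[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[30]]
        g = {"chr1": base + "TTTTTTTTTT" + "".join(mutated)}
        res = map_sequence(g, base, max_mismatch=1, report_mode="all_best")
        assert [(h.interval.start, h.mismatches) for h in res.hits if h.interval.strand == "+"] == [(1, 0)]
        res_all = map_sequence(g, base, max_mismatch=1, report_mode="all")
        starts = {(h.interval.start, h.mismatches) for h in res_all.hits if h.interval.strand == "+"}
        assert starts == {(1, 0), (71, 1)}

    def test_reverse_complement_reported_on_minus_strand(self, genome):
        read = reverse_complement(genome["chrB"][200:240])
        res = map_sequence(genome, read, max_mismatch=0)
        assert any(
            h.interval.chrom == "chrB"
            and (h.interval.start, h.interval.end) == (201, 240)
            and h.interval.strand == "-"
            for h in res.hits
        )

    @pytest.mark.parametrize("mode", ["all", "all_best", "k", "k_best"])
    @pytest.mark.parametrize("mm", [0, 1, 2, 3])
    def test_agrees_with_hamming_scan(self, genome, mode, mm):
        rng = random.Random(mm * 17 + 1)
        for _ in range(6):
            chrom = rng.choice(["chrA", "chrB"])
            off = rng.randint(0, len(genome[chrom]) - 40)
            read = list(genome[chrom][off : off + 35])
            for _ in range(rng.randint(0, 3)):
                read[rng.randint(0, 34)] = rng.choice("ACGTN")
            read = "".join(read)
            oracle = brute_force_hits(genome, read, mm)
            res = map_sequence(genome, read, max_mismatch=mm, report_mode=mode, k=3)
            got = [
                (h.interval.chrom, h.interval.start, h.interval.strand, h.mismatches)
                for h in res.hits
            ]
            if mode == "all":
                assert got == oracle
            elif mode == "all_best":
                best = min((m for *_, m in oracle), default=0)
                assert got == [o for o in oracle if o[3] == best]
            elif mode == "k":
                assert got == oracle[:3]
            else:
                best = min((m for *_, m in oracle), default=0)
                assert got == [o for o in oracle if o[3] == best][:3]
            assert res.total_found == len(oracle)

    def test_raising_max_mismatch_is_monotone(self, genome):
        read = genome["chrA"][500:535]
        prev: set = set()
        for mm in range(4):
            res = map_sequence(genome, read, max_mismatch=mm, report_mode="all")
            cur = {(h.interval.chrom, h.interval.start, h.interval.strand) for h in res.hits}
            assert prev <= cur
            prev = cur

    def test_suppression_triggers_strictly_above_threshold(self):
        unit = "ACGGTTCAAGGTCCAATGGA"
        sep = "T" * 25
        g = {"chr1": sep.join([unit] * 7)}
        total = map_sequence(g, unit, report_mode="all").total_found
        assert total == 7  # forward copies only; unit is not its own revcomp
        suppressed = map_sequence(g, unit, suppress_more_than=total - 1)
        assert suppressed.suppressed and suppressed.hits == []
        kept = map_sequence(g, unit, suppress_more_than=total)
        assert not kept.suppressed and kept.total_found == total

    def test_invalid_reads_rejected(self, genome):
        with pytest.raises(ValueError):
            map_sequence(genome, "ACGU")
        with pytest.raises(ValueError):
            map_sequence(genome, "")
        with pytest.raises(ValueError):
            map_sequence(genome, "ACGT", max_mismatch=4)

    def test_read_longer_than_every_chromosome_maps_nowhere(self):
        g = {"chr1": "ACGTACGT"}
        res = map_sequence(g, "A" * 20, max_mismatch=3)
        assert res.hits == [] and not res.suppressed


class TestFragmentation:
    def test_tiling_offsets_and_suffixes(self):
        frags = fragment_sequence("geneX", "A" * 100, window=50, step=25)
        assert [n for n, _ in frags] == ["geneX_1", "geneX_2", "geneX_3"]
        assert all(len(s) == 50 for _, s in frags)

    def test_exact_window_length_yields_one(self):
        assert len(fragment_sequence("g", "C" * 50)) == 1

    def test_shorter_than_window_yields_none(self):
        assert fragment_sequence("g", "C" * 49) == []

    def test_fragments_reassemble_source(self):
        seq = "".join(random.Random(1).choice("ACGT") for _ in range(175))
        frags = fragment_sequence("g", seq)
        for i, (_, sub) in enumerate(frags):
            assert seq[i * 25 : i * 25 + 50] == sub

    def test_invalid_window_step(self):
        with pytest.raises(ValueError):
            fragment_sequence("g", "ACGT", window=0)
        with pytest.raises(ValueError):
            fragment_sequence("g", "ACGT", window=10, step=11)


class TestBestFractionFilter:
    def test_five_percent_cutoff(self):
        kept = filter_best_fraction(["a", "b", "c"], [100, 96, 94], 0.05)
        assert kept == ["a", "b"]

    def test_single_alignment_kept(self):
        assert filter_best_fraction(["a"], [7.0]) == ["a"]

    def test_all_equal_scores_all_kept(self):
        assert filter_best_fraction(list("abcd"), [5, 5, 5, 5]) == list("abcd")

    def test_empty_input(self):
        assert filter_best_fraction([], []) == []

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            filter_best_fraction(["a"], [-1])
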