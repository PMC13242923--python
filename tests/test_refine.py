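"""Shift equivalence and annotation-guided realignment.

The independent oracle used throughout: a placement (s+k, e+k) of intron
(s, e) is sequence-equivalent iff excising it from the chromosome leaves
the identical spliced string; candidate ranges are scanned contiguously
outward from k=0, and the best placement is the argmax of the stated
scoring key recomputed from scratch.
"""

import random

import pytest
from hypothesis import given, settings, strategies as st

from sjcaller.annotation import JunctionCatalog, SpliceSiteIndex
from sjcaller.evidence import Junction
from sjcaller.refine import realign_all, realign_junction, shift_range


def spliced(seq: str, s: int, e: int) -> str:
    """The chromosome with intron (s, e) (1-based inclusive) excised."""
    return seq[: s - 1] + seq[e:]


def oracle_range(seq: str, s: int, e: int, span: int = 50) -> tuple[int, int]:
    """Contiguous equivalent slide range by whole-string comparison."""
    base = spliced(seq, s, e)
    right = 0
    for k in range(1, span + 1):
        if e + k > len(seq) or spliced(seq, s + k, e + k) != base:
            break
        right = k
    left = 0
    for k in range(1, span + 1):
        if s - k < 1 or spliced(seq, s - k, e - k) != base:
            break
        left = k
    return left, right


def random_case(rng: random.Random, alphabet: str = "ACGT"):
    n = rng.randint(60, 200)
    seq = "".join(rng.choice(alphabet) for _ in range(n))
    s = rng.randint(10, n - 30)
    e = s + rng.randint(4, 20)
    return seq, s, e


class TestShiftRange:
    def test_non_repeating_boundaries_pin_the_gap(self):
        #        1234567890123
        seq = "AACCGTTTTAGCAT"
        # intron 5..11 = GTTTTAG; base after end is C != first intronic G
        r = shift_range({"chr": seq}, Junction("chr", 5, 11))
        assert (r.max_left, r.max_right) == (0, 0)

    def test_repeated_boundary_allows_slide(self):
        # bases at intron start "GT" equal the two bases after intron end
        seq = "ACGT" + "GTAAGTTTTTAG" + "GTCC"
        # intron = positions 5..16 ("GTAAGTTTTTAG"); genome[17:18]="GT"
        r = shift_range({"chr": seq}, Junction("chr", 5, 16))
        assert r.max_right >= 2

    def test_out_of_bounds_junction_raises(self):
        with pytest.raises(ValueError):
            shift_range({"chr": "ACGTACGT"}, Junction("chr", 3, 20))

    @pytest.mark.parametrize("alphabet", ["ACGT", "AC"])
    def test_matches_brute_force_on_random_sequences(self, alphabet):
        rng = random.Random(17 if alphabet == "ACGT" else 18)
        for _ in range(300):
            seq, s, e = random_case(rng, alphabet)
            left, right = oracle_range(seq, s, e)
            r = shift_range({"chr": seq}, Junction("chr", s, e))
            assert (r.max_left, r.max_right) == (left, right)

    def test_homopolymer_run_spans_both_boundaries(self):
        rng = random.Random(4)
        for _ in range(50):
            seq, s, e = random_case(rng)
            seq = seq[: s - 4] + "T" * 8 + seq[s + 4 :]  # run across left boundary
            left, right = oracle_range(seq, s, e)
            r = shift_range({"chr": seq}, Junction("chr", s, e))
            assert (r.max_left, r.max_right) == (left, right)
            assert r.max_left + r.max_right >= 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=60, max_size=120),
        data=st.data(),
    )
    def test_every_reported_shift_preserves_spliced_sequence(self, seq, data):
        s = data.draw(st.integers(10, len(seq) - 30))
        e = s + data.draw(st.integers(4, 15))
        r = shift_range({"chr": seq}, Junction("chr", s, e))
        base = spliced(seq, s, e)
        for k in range(-r.max_left, r.max_right + 1):
            assert spliced(seq, s + k, e + k) == base


def oracle_best_placement(seq, s, e, strand, index, catalog, chrom="chr"):
    """Exhaustive argmax over the equivalent range under the stated key."""
    left, right = oracle_range(seq, s, e)

    def key(k):
        s2, e2 = s + k, e + k
        n_sites = int(index.has_site(chrom, s2, "left", strand)) + int(
            index.has_site(chrom, e2, "right", strand)
        )
        in_cat = int(catalog.contains(chrom, s2, e2, strand))
        donor, acceptor = seq[s2 - 1 : s2 + 1], seq[e2 - 2 : e2]
        fwd = donor == "GT" and acceptor == "AG"
        rev = donor == "CT" and acceptor == "AC"
        canonical = {"+": fwd, "-": rev}.get(strand, fwd or rev)
        return (n_sites, in_cat, int(canonical), -abs(k), -k)

    best = max(range(-left, right + 1), key=key)
    return s + best, e + best


class TestRealign:
    def _random_annotation(self, rng, seq, s, e):
        """Annotate a random placement of this intron (possibly none)."""
        index = SpliceSiteIndex()
        catalog = JunctionCatalog()
        left, right = oracle_range(seq, s, e)
        if rng.random() < 0.7 and (left or right):
            k = rng.randint(-left, right)
            index.add("chr", s + k, "left", "+", "G")
            if rng.random() < 0.6:
                index.add("chr", e + k, "right", "+", "G")
                if rng.random() < 0.5:
                    catalog.add("chr", s + k, e + k, "+")
        # decoy sites elsewhere
        for _ in range(rng.randint(0, 3)):
            index.add("chr", rng.randint(1, len(seq)), rng.choice(["left", "right"]),
                      "+", "D")
        return index, catalog

    def test_matches_exhaustive_argmax_on_random_fixtures(self):
        rng = random.Random(23)
        for _ in range(400):
            seq, s, e = random_case(rng, rng.choice(["ACGT", "AC"]))
            strand = rng.choice(["+", "."])
            index, catalog = self._random_annotation(rng, seq, s, e)
            junction = Junction("chr", s, e, strand=strand, split_reads=3)
            got = realign_junction(junction, {"chr": seq}, index, catalog)
            # the early return for doubly-annotated junctions is part of
            # the contract: such placements are already maximal
            if index.has_site("chr", s, "left", strand) and index.has_site(
                "chr", e, "right", strand
            ):
                assert (got.intron_start, got.intron_end) == (s, e)
                continue
            expected = oracle_best_placement(seq, s, e, strand, index, catalog)
            assert (got.intron_start, got.intron_end) == expected
            assert got.split_reads == 3
            assert spliced(seq, got.intron_start, got.intron_end) == spliced(seq, s, e)

    def test_catalog_junction_returned_identical(self):
        seq = "A" * 40
        index = SpliceSiteIndex()
        catalog = JunctionCatalog()
        index.add("chr", 10, "left", "+", "G")
        index.add("chr", 20, "right", "+", "G")
        catalog.add("chr", 10, 20, "+")
        junction = Junction("chr", 10, 20, strand="+", split_reads=7)
        got = realign_junction(junction, {"chr": seq}, index, catalog)
        assert got is junction

    def test_shift_toward_annotated_donor(self):
        # gap slidable by +2; the +2 placement hits an annotated donor
        seq = "ACGTACGTAC" + "GTGTTTTTGT" + "GTACGTACGT"
        s, e = 11, 20
        left, right = oracle_range(seq, s, e)
        assert right >= 2
        index = SpliceSiteIndex()
        catalog = JunctionCatalog()
        index.add("chr", s + 2, "left", "+", "G")
        junction = Junction("chr", s, e, strand="+")
        got = realign_junction(junction, {"chr": seq}, index, catalog)
        assert (got.intron_start, got.intron_end) == (s + 2, e + 2)
        assert got.shift_applied == 2

    def test_leftmost_tiebreak_without_annotation_or_motif(self):
        # fully ambiguous homopolymer, no annotation, no canonical motif:
        # zero shift wins on |k|, and leftmost breaks remaining ties
        seq = "T" * 40
        junction = Junction("chr", 15, 24)
        got = realign_junction(junction, {"chr": seq}, SpliceSiteIndex(), JunctionCatalog())
        assert (got.intron_start, got.intron_end) == (15, 24)

    def test_idempotent(self):
        rng = random.Random(29)
        for _ in range(100):
            seq, s, e = random_case(rng)
            index, catalog = self._random_annotation(rng, seq, s, e)
            junction = Junction("chr", s, e, strand="+")
            once = realign_junction(junction, {"chr": seq}, index, catalog)
            twice = realign_junction(once, {"chr": seq}, index, catalog)
            assert (twice.intron_start, twice.intron_end) == (
                once.intron_start, once.intron_end
            )

    def test_annotated_site_count_never_decreases(self):
        rng = random.Random(31)
        for _ in range(200):
            seq, s, e = random_case(rng)
            index, catalog = self._random_annotation(rng, seq, s, e)

            def n_sites(s2, e2):
                return int(index.has_site("chr", s2, "left", "+")) + int(
                    index.has_site("chr", e2, "right", "+")
                )

            junction = Junction("chr", s, e, strand="+")
            got = realign_junction(junction, {"chr": seq}, index, catalog)
            assert n_sites(got.intron_start, got.intron_end) >= n_sites(s, e)

    def test_colliding_placements_merge_evidence(self):
        seq = "T" * 60
        index = SpliceSiteIndex()
        index.add("chr", 12, "left", "+", "G")
        index.add("chr", 21, "right", "+", "G")
        catalog = JunctionCatalog()
        j1 = Junction("chr", 10, 19, strand="+", split_reads=4)
        j2 = Junction("chr", 14, 23, strand="+", split_reads=6)
        merged = realign_all(
            {j1.key: j1, j2.key: j2}, {"chr": seq}, index, catalog
        )
        assert set(merged) == {("chr", 12, 21)}
        assert merged[("chr", 12, 21)].split_reads == 10
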