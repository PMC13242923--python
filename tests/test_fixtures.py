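"""The synthetic-fixture generator and the truth scorer."""

import re
from collections import Counter

import numpy as np
import pytest

from sjcaller.annotation import Exon, TranscriptModel
from sjcaller import fixtures as fx


def synthetic_models(n_genes, exons=4, exon_len=120, intron_len=90):
    """Plain transcript models without a genome (plant_events needs no bases)."""
    models = []
    pos = 1000
    for g in range(n_genes):
        ex = []
        tx = f"G{g}.t1"
        for _ in range(exons):
            ex.append(Exon("chr1", pos, pos + exon_len - 1, "+", tx, f"G{g}"))
            pos += exon_len + intron_len
        pos += 500
        models.append(TranscriptModel(tx, f"G{g}", f"G{g}", "chr1", "+", tuple(ex)))
    return models


class TestMakeReference:
    def test_seeded_runs_are_byte_identical(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            ref = fx.make_reference(seed=1, n_genes=3)
            fasta = tmp_path / f"{tag}.fa"
            gtf = tmp_path / f"{tag}.gtf"
            ref.write_fasta(str(fasta))
            ref.write_gtf(str(gtf))
            paths.append((fasta.read_bytes(), gtf.read_bytes()))
        assert paths[0] == paths[1]

    def test_exon_line_count(self, tmp_path):
        ref = fx.make_reference(seed=2, n_genes=3, exons_per_gene=4)
        gtf = tmp_path / "x.gtf"
        ref.write_gtf(str(gtf))
        lines = gtf.read_text().splitlines()
        assert len(lines) == 12
        assert all("\texon\t" in line for line in lines)

    def test_every_intron_has_canonical_motif(self):
        ref = fx.make_reference(seed=3, n_genes=12, n_chroms=2)
        for model in ref.models:
            seq = ref.genome[model.chrom]
            for s, e in model.introns():
                donor = seq[s - 1 : s + 1]
                acceptor = seq[e - 2 : e]
                if model.strand == "+":
                    assert (donor, acceptor) == ("GT", "AG")
                else:
                    assert (donor, acceptor) == ("CT", "AC")

    def test_layout_too_long_for_explicit_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrom_len"):
            fx.make_reference(seed=1, n_genes=10, chrom_len=1000)


class TestPlantEvents:
    def test_all_none_probabilities_plant_nothing(self):
        models = synthetic_models(20)
        probs = {k: 0.0 for k in fx.DEFAULT_EVENT_PROBS} | {"none": 1.0}
        assert fx.plant_events(models, seed=5, event_probs=probs) == []

    def test_event_fraction_matches_binomial_expectation(self):
        models = synthetic_models(2000)
        events = fx.plant_events(models, seed=6)
        frac = len(events) / len(models)
        # 62.5% of genes host an event; 4 binomial SDs at n=2000
        sd = np.sqrt(0.625 * 0.375 / 2000)
        assert abs(frac - 0.625) < 4 * sd
        types = Counter(e.event_type for e in events)
        assert set(types) <= {"exon_skip", "multi_exon_skip", "intron_retention",
                              "alt5", "alt3"}
        assert min(types.values()) > 0

    def test_alt_events_never_land_on_the_original_boundary(self):
        models = synthetic_models(400)
        events = fx.plant_events(models, seed=7)
        for e in events:
            if e.event_type in ("alt5", "alt3"):
                s, e2 = e.base_intron
                js, je = e.junction
                delta = max(abs(js - s), abs(je - e2))
                assert delta >= 1

    def test_true_psi_within_requested_range(self):
        events = fx.plant_events(synthetic_models(200), seed=8, psi_range=(0.3, 0.4))
        assert events
        assert all(0.3 <= e.true_psi <= 0.4 for e in events)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            fx.plant_events(synthetic_models(5), seed=1, event_probs={"none": 0.5})


class TestSimulate:
    def test_seeded_runs_identical(self, tmp_path):
        ref = fx.make_reference(seed=9, n_genes=4)
        truth = fx.plant_events(ref.models, seed=10)
        texts = []
        for tag in ("a", "b"):
            path = tmp_path / f"{tag}.sam"
            fx.simulate_alignments(ref, truth, str(path), depth=20, seed=11)
            texts.append(path.read_bytes())
        assert texts[0] == texts[1]

    def test_full_psi_event_leaves_no_canonical_junction_reads(self, tmp_path):
        ref = fx.make_reference(seed=12, n_genes=1)
        probs = {k: 0.0 for k in fx.DEFAULT_EVENT_PROBS} | {
            "exon_skip": 1.0, "none": 0.0
        }
        truth = fx.plant_events(ref.models, seed=13, event_probs=probs,
                                psi_range=(1.0, 1.0))
        (event,) = truth
        sam = fx.simulate_alignments(ref, truth, str(tmp_path / "p.sam"),
                                     depth=40, seed=14)
        from sjcaller.evidence import extract_gaps

        junctions = extract_gaps(sam)
        skipped_introns = {
            (ref.models[0].chrom, s, e)
            for s, e in ref.models[0].introns()
            if event.junction[0] <= s and e <= event.junction[1]
        }
        assert not skipped_introns & set(junctions)
        assert event.junction in {(s, e) for _, s, e in junctions}

    def test_cigars_validated_by_independent_walk(self, tmp_path):
        """Every read's sequence equals the genome bases its M blocks claim,
        an end-to-end check of CIGAR/position bookkeeping."""
        ref = fx.make_reference(seed=15, n_genes=6)
        truth = fx.plant_events(ref.models, seed=16)
        sam = fx.simulate_alignments(ref, truth, str(tmp_path / "v.sam"),
                                     depth=15, seed=17)
        n = 0
        with open(sam) as handle:
            for line in handle:
                if line.startswith("@"):
                    continue
                fields = line.split("\t")
                chrom, pos, cigar, seq = fields[2], int(fields[3]), fields[5], fields[9]
                genome = ref.genome[chrom]
                ref_pos, query = pos - 1, []
                for length, op in re.findall(r"(\d+)([MN])", cigar):
                    length = int(length)
                    if op == "M":
                        query.append(genome[ref_pos : ref_pos + length])
                    ref_pos += length
                assert "".join(query) == seq
                assert re.fullmatch(r"(\d+[MN])+", cigar)
                n += 1
        assert n > 100

    def test_sorted_reference_dictionary_and_coordinates(self, tmp_path):
        ref = fx.make_reference(seed=18, n_genes=6, n_chroms=3)
        sam = fx.simulate_alignments(ref, [], str(tmp_path / "s.sam"),
                                     depth=5, seed=19)
        sq = []
        coords = []
        with open(sam) as handle:
            for line in handle:
                if line.startswith("@SQ"):
                    sq.append(dict(f.split(":", 1) for f in line.split("\t")[1:]
                                   if ":" in f)["SN"])
                elif not line.startswith("@"):
                    fields = line.split("\t")
                    coords.append((fields[2], int(fields[3])))
        assert sq == sorted(sq)
        assert coords == sorted(coords)


@pytest.fixture(scope="module")
def truth():
    return fx.plant_events(synthetic_models(60), seed=21)


class TestScorer:
    def _perfect_calls(self, truth):
        from sjcaller.events import EventRecord, JunctionClass

        calls = []
        for t in truth:
            if t.junction is not None:
                calls.append(EventRecord(
                    kind="junction", chrom=t.chrom, start=t.junction[0],
                    end=t.junction[1], strand="+", klass=JunctionClass.PLAUSIBLE,
                    split_reads=20, psi_left=0.5, psi_right=0.5,
                ))
            else:
                calls.append(EventRecord(
                    kind="nosplice", chrom=t.chrom, start=t.retained_intron[0],
                    end=t.retained_intron[0], strand="+",
                    klass=JunctionClass.NOSPLICE, split_reads=20, psi_left=0.5,
                ))
        return calls

    def test_perfect_calls_score_perfectly(self, truth):
        score = fx.score_calls(self._perfect_calls(truth), truth)
        assert score.recall() == 1.0
        assert score.recall(include_near=False) == 1.0
        assert score.precision() == 1.0
        assert score.spurious == []

    def test_shifted_call_is_a_near_match(self, truth):
        t = next(t for t in truth if t.junction is not None)
        calls = self._perfect_calls([t])
        calls[0].start += 4
        score = fx.score_calls(calls, [t])
        (m,) = score.matches
        assert m.status == "near" and m.coordinate_delta == 4
        calls[0].start += 20  # now beyond tolerance
        score = fx.score_calls(calls, [t])
        assert score.matches[0].status == "miss"
        assert len(score.spurious) == 1

    @pytest.mark.parametrize("k", [1, 5, 10])
    def test_recall_arithmetic_under_deleted_calls(self, truth, k):
        calls = self._perfect_calls(truth)
        score = fx.score_calls(calls[k:], truth)
        assert score.recall() == pytest.approx(1 - k / len(truth))

    def test_symmetric_under_permutation(self, truth):
        import random

        calls = self._perfect_calls(truth)
        base = fx.score_calls(calls, truth)
        rng = random.Random(22)
        for _ in range(3):
            shuffled_calls = calls[:]
            shuffled_truth = list(truth)
            rng.shuffle(shuffled_calls)
            rng.shuffle(shuffled_truth)
            score = fx.score_calls(shuffled_calls, shuffled_truth)
            assert Counter((m.gene_id, m.status) for m in score.matches) == Counter(
                (m.gene_id, m.status) for m in base.matches
            )
            assert len(score.spurious) == len(base.spurious)
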