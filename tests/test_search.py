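"""Translated search: frame translation, hit search, best-hit assignment."""

import numpy as np
import pytest
from Bio.Seq import Seq

from metallobsh.alignment import ProteinRecord, align_strings
from metallobsh.curation import ReferenceDB
from metallobsh.io import ReadRecord
from metallobsh.search import (
    SearchHit,
    SearchParams,
    assign_best,
    map_reads,
    search_read,
    six_frame_translate,
)
from metallobsh.simulate import (
    mutate_to_identity,
    random_protein,
    reverse_complement,
    reverse_translate,
    simulate_metagenome,
)


class TestSixFrameTranslate:
    def test_standard_code_lookup(self):
        frames = six_frame_translate(ReadRecord("r", "ATGGCC"))
        assert frames[1] == "MA"

    def test_reverse_complement_swaps_strand_frames(self):
        read = ReadRecord("r", "ATGGCCGTTAAC")
        rc = ReadRecord("rc", reverse_complement(read.seq))
        f1, f2 = six_frame_translate(read), six_frame_translate(rc)
        assert {f1[k] for k in (1, 2, 3)} == {f2[k] for k in (-1, -2, -3)}
        assert {f1[k] for k in (-1, -2, -3)} == {f2[k] for k in (1, 2, 3)}

    def test_random_read_against_independent_codon_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), 300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        frames = six_frame_translate(ReadRecord("r", seq))
        rc = reverse_complement(seq)
        for offset in range(3):
            for frame, strand_seq in ((offset + 1, seq), (-(offset + 1), rc)):
                expected_len = (300 - offset) // 3
                assert len(frames[frame]) == expected_len
                # codon-by-codon oracle via Biopython single-codon translation
                for c in range(expected_len):
                    codon = strand_seq[offset + 3 * c : offset + 3 * c + 3]
                    expected = "X" if "N" in codon else str(Seq(codon).translate())
                    assert frames[frame][c] == expected

    def test_too_short_read_yields_empty_frames_with_warning(self):
        with pytest.warns(UserWarning):
            frames = six_frame_translate(ReadRecord("r", "AT"))
        assert all(v == "" for v in frames.values())

    def test_stop_codons_appear_as_asterisk(self):
        assert six_frame_translate(ReadRecord("r", "TAAATG"))[1] == "*M"


@pytest.fixture(scope="module")
def tiny_db():
    rng = np.random.default_rng(99)
    target = random_protein(120, rng)
    target = ProteinRecord("tgt1", target.seq)
    homolog = mutate_to_identity(target, 70, rng, new_id="tgt2")
    decoy = random_protein(120, rng)
    decoy = ProteinRecord("dec1", decoy.seq)
    return ReferenceDB(targets=[target, homolog], decoys=[decoy])


class TestSearchRead:
    def test_error_free_read_hits_source_at_full_identity(self, tiny_db):
        cds = reverse_translate(tiny_db.targets[0])
        read = ReadRecord("r", cds[30 : 30 + 90])
        hits = search_read(read, tiny_db)
        best = max(hits, key=lambda h: h.identity_pct)
        assert best.target_id == "tgt1"
        assert best.identity_pct == 100.0

    def test_read_sharing_no_kmer_yields_no_hits(self, tiny_db):
        # poly-A read translates to poly-K in every frame; the random database
        # virtually never contains a KKKK stretch
        read = ReadRecord("r", "A" * 90)
        any_kkkk = any("KKKK" in r.seq for r in tiny_db.all_records())
        if not any_kkkk:
            assert search_read(read, tiny_db) == []

    def test_hits_match_no_prefilter_smith_waterman_oracle(self, tiny_db):
        """Kernel identities/scores equal the general local aligner's, for
        every frame x entry pair, with the prefilter disabled."""
        rng = np.random.default_rng(3)
        cds = {r.id: reverse_translate(r) for r in tiny_db.all_records()}
        reads, _ = simulate_metagenome(
            cds, {g: 1 / 3 for g in cds}, 12, rng, read_len=90, error_rate=0.02
        )
        params = SearchParams(k=0, min_score=40.0)
        for read in reads:
            hits = search_read(read, tiny_db, params)
            oracle = {}
            for frame, pep in six_frame_translate(read).items():
                if not pep:
                    continue
                for rec in tiny_db.all_records():
                    res = align_strings(pep, rec.seq, "local", gap_open=11, gap_extend=1)
                    if res.score >= 40.0:
                        oracle[(frame, rec.id)] = res
            assert {(h.frame, h.target_id) for h in hits} == set(oracle)
            for h in hits:
                res = oracle[(h.frame, h.target_id)]
                assert h.score == pytest.approx(res.score)
                assert h.identity_pct == pytest.approx(res.identity_pct)


class TestAssignBest:
    def _hit(self, read, target, ident, score=100.0, decoy=False):
        return SearchHit(read, target, 1, ident, score, 30, decoy)

    def test_single_passing_hit_is_assigned(self):
        res = assign_best([self._hit("r1", "t1", 95.0)])
        assert res.assigned["r1"].target_id == "t1"

    def test_decoy_best_read_is_discarded(self):
        res = assign_best([self._hit("r1", "d1", 95.0, decoy=True), self._hit("r1", "t1", 92.0)])
        assert "r1" not in res.assigned
        assert res.n_decoy_best == 1

    def test_identity_filter_is_strictly_greater(self):
        res = assign_best([self._hit("r1", "t1", 90.0)])
        assert not res.assigned
        assert res.n_filtered_identity == 1
        assert assign_best([self._hit("r1", "t1", 90.0 + 1e-9)]).assigned

    def test_ties_break_by_score_then_id(self):
        hits = [
            self._hit("r1", "tB", 95.0, score=50.0),
            self._hit("r1", "tA", 95.0, score=50.0),
            self._hit("r1", "tC", 95.0, score=60.0),
        ]
        assert assign_best(hits).assigned["r1"].target_id == "tC"
        hits = hits[:2]
        assert assign_best(hits).assigned["r1"].target_id == "tA"

    def test_raising_min_identity_never_increases_assignments(self, rng):
        hits = [
            self._hit(f"r{i}", "t1", float(rng.uniform(80, 100)), decoy=bool(rng.random() < 0.3))
            for i in range(50)
        ]
        previous = None
        for cutoff in (85.0, 90.0, 95.0, 99.0):
            n = len(assign_best(hits, min_identity=cutoff).assigned)
            if previous is not None:
                assert n <= previous
            previous = n

    def test_removing_decoys_never_decreases_target_counts(self, rng):
        hits = []
        for i in range(40):
            hits.append(self._hit(f"r{i}", "t1", float(rng.uniform(91, 100)), score=50.0))
            if rng.random() < 0.5:
                hits.append(self._hit(f"r{i}", "d1", float(rng.uniform(91, 100)), score=60.0, decoy=True))
        with_decoys = assign_best(hits).counts_by_target()
        without = assign_best([h for h in hits if not h.is_decoy]).counts_by_target()
        for t, n in with_decoys.items():
            assert without.get(t, 0) >= n

    def test_determinism(self, rng):
        hits = [
            self._hit(f"r{i % 7}", f"t{j}", float(rng.uniform(85, 100)))
            for i in range(30)
            for j in range(3)
        ]
        a = assign_best(hits)
        b = assign_best(list(reversed(hits)))
        assert a.assigned == b.assigned


def test_simulated_reads_map_to_true_source(tiny_db):
    """At 1% substitution error the vast majority of assigned reads hit
    their recorded source gene."""
    rng = np.random.default_rng(11)
    cds = {r.id: reverse_translate(r) for r in tiny_db.all_records()}
    reads, truth = simulate_metagenome(
        cds, {g: 1 / 3 for g in cds}, 300, rng, read_len=120, error_rate=0.01
    )
    result = map_reads(reads, tiny_db)
    source = dict(zip(truth.read_id, truth.source_gene))
    assert result.assigned, "no reads assigned"
    correct = sum(1 for rid, h in result.assigned.items() if source[rid] == h.target_id)
    assert correct / len(result.assigned) >= 0.95
    for h in result.assigned.values():
        assert h.identity_pct > 90.0
        assert not h.is_decoy
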