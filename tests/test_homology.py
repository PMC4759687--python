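"""Translated alignment: DP oracle equivalence, hit I/O, candidate rules."""

import random

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from prfscan.homology import (
    align_six_frames,
    default_scheme,
    find_frame_split_candidates,
    parse_tabular_hits,
    rank_candidates,
    search_hits,
    smith_waterman,
    write_tabular_hits,
    TranslatedHit,
)
from prfscan.seqcore import (
    EUPLOTID_CODE,
    NucleotideSequence,
    ProteinSequence,
    translate_str,
)

_BLOSUM = substitution_matrices.load("BLOSUM62")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def sw_score_oracle(q: str, s: str, go: int = 11, ge: int = 1) -> int:
    """Plain-Python affine-gap local-alignment DP, independent of the
    production kernel.  Gap of length k costs go + k*ge."""
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge)
            sub = int(_BLOSUM[q[i - 1], s[j - 1]])
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_short_peptides(self):
        sch = default_scheme()
        pep = "MKVLITDEQW"
        res = smith_waterman(sch.encode(pep), sch.encode(pep), sch)
        score, qs, qe, ss, se, n_id, aln = res
        assert (qs, qe, ss, se) == (0, 10, 0, 10)
        assert n_id == aln == 10
        assert score == sum(int(_BLOSUM[a, a]) for a in pep)

    def test_matches_python_dp_oracle_on_random_peptides(self):
        sch = default_scheme()
        rng = random.Random(20)
        for _ in range(40):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 35)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 35)))
            expected = sw_score_oracle(q, s)
            got = smith_waterman(sch.encode(q), sch.encode(s), sch)
            assert (0 if got is None else got[0]) == expected

    def test_matches_biopython_pairwise_aligner(self):
        sch = default_scheme()
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = _BLOSUM
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        rng = random.Random(21)
        for _ in range(30):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(8, 40)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(8, 40)))
            got = smith_waterman(sch.encode(q), sch.encode(s), sch)
            assert (0 if got is None else got[0]) == int(aligner.score(q, s))

    def test_self_score_dominates_mutated_copies(self):
        sch = default_scheme()
        rng = random.Random(5)
        pep = "".join(rng.choice(AA20) for _ in range(50))
        self_score = smith_waterman(sch.encode(pep), sch.encode(pep), sch)[0]
        for _ in range(20):
            mutated = list(pep)
            for pos in rng.sample(range(50), 10):
                mutated[pos] = rng.choice(AA20)
            got = smith_waterman(sch.encode("".join(mutated)),
                                 sch.encode(pep), sch)
            assert (0 if got is None else got[0]) <= self_score


class TestAlignSixFrames:
    def test_exact_encoding_gives_single_full_coverage_hit(self):
        # transcript encodes the protein exactly in frame 0
        rng = random.Random(9)
        prot = "M" + "".join(rng.choice(AA20) for _ in range(40))
        codons = {aa: [c for c, a in EUPLOTID_CODE.codon_map.items() if a == aa]
                  for aa in set(prot)}
        seq = "".join(rng.choice(codons[aa]) for aa in prot)
        t = NucleotideSequence("t", seq)
        p = ProteinSequence("p", prot)
        hits = align_six_frames(t, p, min_score=50)
        best = hits[0]
        assert best.frame == 0 and best.forward
        assert (best.s_start, best.s_end) == (0, len(prot))
        assert best.n_identities == best.aln_len == len(prot)
        assert (best.q_start, best.q_end) == (0, 3 * len(prot))

    def test_random_pairs_rarely_reach_min_score_50(self):
        rng = random.Random(33)
        n_hits = 0
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(150))
            prot = "".join(rng.choice(AA20) for _ in range(40))
            hits = align_six_frames(
                NucleotideSequence("t", seq), ProteinSequence("p", prot),
                min_score=50,
            )
            n_hits += bool(hits)
        assert n_hits <= 2  # chance homology at score >= 50 is very rare

    def test_score_invariant_under_id_relabeling(self):
        t = NucleotideSequence("a", "ATGAAAGTTTTAATTACTGATGAACAATGG")
        p = ProteinSequence("x", "MKVLITDEQW")
        h1 = align_six_frames(t, p, min_score=10)
        t2 = NucleotideSequence("zzz", t.residues)
        p2 = ProteinSequence("yyy", p.residues)
        h2 = align_six_frames(t2, p2, min_score=10)
        assert [h.raw_score for h in h1] == [h.raw_score for h in h2]

    def test_masking_yields_disjoint_hsps_per_frame(self, small_ds):
        t = small_ds.transcripts[0]
        rec = small_ds.truth[0]
        proteins = {p.id: p for p in small_ds.proteins}
        if rec.protein_id is None:
            return
        hits = align_six_frames(t, proteins[rec.protein_id], min_score=50)
        by_frame = {}
        for h in hits:
            by_frame.setdefault((h.forward, h.frame), []).append(h)
        for hs in by_frame.values():
            hs.sort(key=lambda h: h.q_start)
            for a, b in zip(hs, hs[1:]):
                assert a.q_end <= b.q_start + 2  # masking is aa-granular


class TestTabularIO:
    def _mk_hit(self, **kw):
        base = dict(
            query_id="q1", subject_id="s1", q_start=0, q_end=300, frame=0,
            forward=True, s_start=0, s_end=100, raw_score=200,
            bit_score=95.0, evalue=1e-20, n_identities=100, aln_len=100,
        )
        base.update(kw)
        return TranslatedHit(**base)

    def test_positive_frame_coordinate_conversion(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\ts1\t100.00\t100\t0\t0\t1\t300\t1\t100\t1e-20\t95.0\t1\n"
        )
        (h,) = parse_tabular_hits(p)
        assert (h.q_start, h.q_end, h.frame, h.forward) == (0, 300, 0, True)
        assert (h.s_start, h.s_end) == (0, 100)

    def test_negative_frame_converts_to_revcomp_coordinates(self, tmp_path):
        # 1-based plus-strand interval [101, 340] on a 400-nt query, qframe -2
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\ts1\t90.00\t80\t8\t0\t101\t340\t1\t80\t1e-10\t60.0\t-2\n"
        )
        (h,) = parse_tabular_hits(p, query_lengths={"q1": 400})
        L, lo, hi = 400, 101, 340
        assert h.q_start == L - hi  # index-arithmetic oracle
        assert h.q_end == L - lo + 1
        assert h.frame == (L - hi) % 3
        assert not h.forward

    def test_empty_file_gives_empty_hit_set(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert parse_tabular_hits(p) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\tnot\tenough\n")
        with pytest.raises(ValueError, match=":1:"):
            parse_tabular_hits(p)

    def test_write_parse_round_trip(self, tmp_path):
        hits = [
            self._mk_hit(),
            self._mk_hit(query_id="q2", q_start=2, q_end=302, frame=2,
                         forward=False),
        ]
        p = tmp_path / "hits.tsv"
        write_tabular_hits(hits, p, query_lengths={"q1": 400, "q2": 400})
        back = parse_tabular_hits(p, query_lengths={"q1": 400, "q2": 400})
        for a, b in zip(hits, back):
            assert (a.query_id, a.subject_id) == (b.query_id, b.subject_id)
            assert (a.q_start, a.q_end, a.frame, a.forward) == \
                   (b.q_start, b.q_end, b.frame, b.forward)
            assert (a.s_start, a.s_end, a.aln_len, a.n_identities) == \
                   (b.s_start, b.s_end, b.aln_len, b.n_identities)


class TestFrameSplitCandidates:
    def _hit(self, q_start, q_end, frame, s_start, s_end, score=200,
             evalue=1e-20, subject="s1"):
        return TranslatedHit(
            query_id="q1", subject_id=subject, q_start=q_start, q_end=q_end,
            frame=frame, forward=True, s_start=s_start, s_end=s_end,
            raw_score=score, bit_score=90.0, evalue=evalue,
            n_identities=(q_end - q_start) // 3, aln_len=(q_end - q_start) // 3,
        )

    def test_two_hits_in_different_frames_form_one_candidate(self):
        up = self._hit(0, 300, 0, 0, 100)
        down = self._hit(301, 601, 1, 100, 200)
        (cand,) = find_frame_split_candidates([up, down])
        assert cand.frame_delta == 1
        assert cand.upstream is up and cand.downstream is down

    def test_single_hit_yields_no_candidate(self):
        assert find_frame_split_candidates([self._hit(0, 300, 0, 0, 100)]) == []

    def test_same_frame_pair_yields_no_candidate(self):
        hits = [self._hit(0, 300, 0, 0, 100), self._hit(402, 702, 0, 100, 200)]
        assert find_frame_split_candidates(hits) == []

    def test_evalue_cutoff_filters_weak_hits(self):
        hits = [
            self._hit(0, 300, 0, 0, 100),
            self._hit(301, 601, 1, 100, 200, evalue=1e-3),
        ]
        assert find_frame_split_candidates(hits, evalue_cutoff=1e-5) == []

    def test_query_gap_limit(self):
        hits = [
            self._hit(0, 300, 0, 0, 100),
            self._hit(601, 901, 1, 100, 200),
        ]
        assert find_frame_split_candidates(hits, max_q_gap=200) == []
        assert len(find_frame_split_candidates(hits, max_q_gap=400)) == 1

    def test_ranking_prefers_total_score_then_evalue_then_subject(self):
        a = [self._hit(0, 300, 0, 0, 100, score=100, subject="sB"),
             self._hit(301, 601, 1, 100, 200, score=100, subject="sB")]
        b = [self._hit(0, 300, 0, 0, 100, score=300, subject="sA"),
             self._hit(301, 601, 1, 100, 200, score=300, subject="sA")]
        cands = find_frame_split_candidates(a + b)
        ranked = rank_candidates(cands)
        assert ranked[0].subject_id == "sA"


class TestSearchHits:
    def test_planted_transcripts_find_their_source_protein(self, small_ds):
        truth = {r.transcript_id: r for r in small_ds.truth}
        hits = search_hits(small_ds.transcripts[:20], small_ds.proteins)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, set()).add(h.subject_id)
        for t in small_ds.transcripts[:20]:
            rec = truth[t.id]
            if rec.protein_id is not None and not rec.is_nonhomologous_decoy:
                assert rec.protein_id in by_query.get(t.id, set())
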