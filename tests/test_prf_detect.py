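"""Unit tests for the detection stages: intron exclusion, site scan, fs-gene
construction and validation."""

import pytest

from prfscan.homology import FrameSplitCandidate, TranslatedHit
from prfscan.prf_detect import (
    build_fs_gene,
    exclude_intron_retention,
    scan_slippery_site,
    validate_fs_gene,
)
from prfscan.seqcore import EUPLOTID_CODE, NucleotideSequence
from prfscan.synthetic_data import SyntheticConfig, generate_dataset


def _hit(q_start, q_end, frame, s_start, s_end, score=300):
    return TranslatedHit(
        query_id="t", subject_id="p", q_start=q_start, q_end=q_end,
        frame=frame, forward=True, s_start=s_start, s_end=s_end,
        raw_score=score, bit_score=120.0, evalue=1e-30,
        n_identities=(q_end - q_start) // 3, aln_len=(q_end - q_start) // 3,
    )


def _cand(up, down):
    return FrameSplitCandidate(
        query_id="t", subject_id="p", upstream=up, downstream=down,
        frame_delta=(down.frame - up.frame) % 3,
        subject_gap=down.s_start - up.s_end,
        combined_evalue_rank=up.evalue * down.evalue,
    )


def _prf_cases(ds, calls):
    truth = {r.transcript_id: r for r in ds.truth}
    tx = {t.id: t for t in ds.transcripts}
    out = []
    for c in calls:
        rec = truth[c.transcript_id]
        if rec.is_prf and c.status == "confirmed":
            out.append((tx[c.transcript_id], rec, c))
    return out


class TestScanSlipperySite:
    def _transcript_with_junction(self, junction_codons):
        """Frame-0 CDS whose junction region is given codon by codon."""
        prefix = "ATGGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCT"  # 12 codons, no stops
        seq = prefix + "".join(junction_codons) + "GCTGCTGCTGCTGCTGCTGCTGCT"
        return NucleotideSequence("t", seq)

    def test_classical_aaa_taa_motif(self):
        t = self._transcript_with_junction(["GCT", "AAA", "TAA", "GCA"])
        up = _hit(0, 42, 0, 0, 14)
        down = _hit(43, 43 + 24, (43) % 3, 14, 22)
        site = scan_slippery_site(t, _cand(up, down))
        assert site is not None
        assert site.p_codon == "AAA"
        assert site.stop_codon == "TAA"
        assert site.motif_class == "AAA-TAR"
        assert t.residues[site.stop_pos : site.stop_pos + 3] == "TAA"

    def test_novel_ttt_tag_motif(self):
        t = self._transcript_with_junction(["GCT", "TTT", "TAG", "GCA"])
        up = _hit(0, 42, 0, 0, 14)
        down = _hit(43, 43 + 24, 1, 14, 22)
        site = scan_slippery_site(t, _cand(up, down))
        assert site.motif_class == "TTT-TAR"
        assert site.tetra == "TAGG"

    def test_no_in_frame_stop_returns_none(self):
        t = self._transcript_with_junction(["GCT", "AAA", "AAA", "GCA"])
        up = _hit(0, 42, 0, 0, 14)
        down = _hit(43, 43 + 24, 1, 14, 22)
        assert scan_slippery_site(t, _cand(up, down)) is None

    def test_first_in_frame_stop_wins(self):
        t = self._transcript_with_junction(
            ["GCT", "AAA", "TAA", "GCA", "TAG", "GCA"]
        )
        up = _hit(0, 42, 0, 0, 14)
        down = _hit(43, 43 + 24, 1, 14, 22)
        site = scan_slippery_site(t, _cand(up, down))
        assert site.stop_codon == "TAA"  # the earlier of the two stops

    def test_window_is_66nt_and_n_padded_at_edges(self):
        seq = "AAA" + "TAA" + "GCT" * 30
        t = NucleotideSequence("t", seq)
        up = _hit(0, 3, 0, 0, 1)
        down = _hit(7, 37, 1, 1, 11)
        site = scan_slippery_site(t, _cand(up, down))
        assert site is not None
        assert len(site.window) == 66
        assert site.window.startswith("N" * 30)  # no upstream context


class TestBuildFsGene:
    def test_t_deletion_example(self):
        t = NucleotideSequence("t", "AAATAAGCG")
        up = _hit(0, 3, 0, 0, 1)
        down = _hit(4, 7, 1, 1, 2)
        site = scan_slippery_site(t, _cand(up, down))
        assert site.stop_pos == 3
        fs = build_fs_gene(t, site)
        assert fs.fs_sequence.residues == "AAAAAGCG"
        assert len(fs.fs_sequence) == len(t) - 1

    def test_deletion_requires_t_at_site(self, small_ds, small_run):
        calls, _ = small_run
        for t, rec, call in _prf_cases(small_ds, calls):
            assert t.residues[call.site.stop_pos] == "T"
            fs = call.fs_gene
            assert len(fs.fs_sequence) == len(t) - 1
            assert fs.fs_sequence.residues == (
                t.residues[: call.site.stop_pos]
                + t.residues[call.site.stop_pos + 1 :]
            )

    def test_fs_translation_reproduces_source_protein(self, small_ds, small_run):
        calls, _ = small_run
        proteins = {p.id: p for p in small_ds.proteins}
        cases = _prf_cases(small_ds, calls)
        assert cases, "fixture must contain confirmed planted calls"
        for t, rec, call in cases:
            assert call.fs_gene.fs_protein.residues == \
                   proteins[rec.protein_id].residues


class TestIntronExclusion:
    def test_planted_retention_decoys_are_flagged(self, small_ds, small_run):
        calls, _ = small_run
        truth = {r.transcript_id: r for r in small_ds.truth}
        for c in calls:
            if truth[c.transcript_id].is_intron_retention_decoy:
                assert c.status == "rejected_intron_retention"

    def test_prf_transcripts_are_not_flagged(self, small_ds, small_run):
        calls, _ = small_run
        truth = {r.transcript_id: r for r in small_ds.truth}
        for c in calls:
            if truth[c.transcript_id].is_prf:
                assert c.status != "rejected_intron_retention"

    def test_gt_ag_segment_length_multiple_of_3_never_qualifies(self):
        # 30-nt GT..AG insert, length % 3 == 0: cannot explain a frame change.
        # Flanks are GCT/GAT codons, which contain no other GT or AG dimers.
        intron = "GT" + "T" * 26 + "AG"
        seq = "GCT" * 20 + intron + "GAT" * 21
        t = NucleotideSequence("t", seq)
        up = _hit(0, 60, 0, 0, 20)
        down = _hit(91, 151, 1, 20, 40)
        assert exclude_intron_retention(t, _cand(up, down)) is False

    def test_matching_gt_ag_segment_flags_candidate(self):
        # 80-nt insert (80 % 3 == 2) between co-linear hit regions
        intron = "GT" + "T" * 76 + "AG"
        seq = "GCT" * 20 + intron + "GCA" * 20
        t = NucleotideSequence("t", seq)
        up = _hit(0, 60, 0, 0, 20)
        down = _hit(60 + 80 + 1 - 1, 60 + 80 + 60, (60 + 80) % 3, 20, 40)
        cand = _cand(up, down)
        assert cand.frame_delta == 2
        assert exclude_intron_retention(t, cand) is True

    def test_junction_file_short_circuits_sequence_scan(self):
        seq = "GCT" * 20 + "GCA" * 48  # sequence content is irrelevant here
        t = NucleotideSequence("t", seq)
        up = _hit(0, 60, 0, 0, 20)
        down = _hit(143, 203, 2, 20, 40)
        cand = _cand(up, down)
        assert cand.frame_delta == 2
        junctions = {"t": [(60, 140)]}  # 80 nt, % 3 == 2 == frame_delta
        assert exclude_intron_retention(t, cand, junctions=junctions) is True
        assert exclude_intron_retention(t, cand, junctions={"t": []}) is False


class TestValidateFsGene:
    def test_confirmed_fs_hit_covers_both_original_intervals(
        self, small_ds, small_run
    ):
        calls, _ = small_run
        for t, rec, call in _prf_cases(small_ds, calls):
            cand = call.candidate
            assert call.fs_hit.s_start <= min(cand.upstream.s_start,
                                              cand.downstream.s_start)
            assert call.fs_hit.s_end >= max(cand.upstream.s_end,
                                            cand.downstream.s_end)

    def test_subject_too_short_for_extension_is_rejected(self, small_ds):
        # fs-gene of a genuine call re-validated against a truncated subject
        from prfscan.prf_detect import run_prf_pipeline

        calls, _ = run_prf_pipeline(small_ds.transcripts, small_ds.proteins)
        confirmed = [c for c in calls if c.status == "confirmed"]
        call = confirmed[0]
        proteins = {p.id: p for p in small_ds.proteins}
        subject = proteins[call.subject_id]
        truncated = type(subject)(
            subject.id, subject.residues[: call.candidate.upstream.s_end + 2]
        )
        status, _hit = validate_fs_gene(
            call.fs_gene, truncated, call.candidate, min_extension=10
        )
        assert status == "rejected_no_extension"


class TestMultipleSites:
    def test_double_shift_transcript_yields_two_sites(self):
        """A gene needing two successive +1 shifts is fully recovered."""
        import random

        from prfscan.prf_detect import PipelineConfig, run_prf_pipeline
        from prfscan.seqcore import ProteinSequence

        rng_codons = {
            "A": "GCT", "K": "AAA", "N": "AAT", "L": "TTA", "I": "ATT",
            "S": "TCT", "E": "GAA", "D": "GAT", "F": "TTT", "G": "GGT",
            "V": "GTT", "T": "ACT", "M": "ATG", "W": "TGG", "Y": "TAT",
            "P": "CCT", "H": "CAT", "Q": "CAA", "R": "AGA", "C": "TGT",
        }
        rng = random.Random(77)
        alphabet = "".join(sorted(rng_codons))
        seg1 = "".join(rng.choice(alphabet) for _ in range(48))
        seg2 = "".join(rng.choice(alphabet) for _ in range(48))
        seg3 = "".join(rng.choice(alphabet) for _ in range(48))
        protein = seg1 + "K" + "K" + seg2 + "K" + "K" + seg3
        # two AAA-TAA junctions: P-site K, post-shift codon AAA (K)
        cds = "".join(rng_codons[a] for a in seg1)
        part2 = "".join(rng_codons[a] for a in seg2)
        part3 = "".join(rng_codons[a] for a in seg3)
        seq = ("TAA" + cds + "AAA" + "T" + "AAA" + part2
               + "AAA" + "T" + "AAA" + part3 + "TAA")
        t = NucleotideSequence("t2x", seq)
        p = ProteinSequence("p2x", protein)
        calls, summary = run_prf_pipeline([t], [p], config=PipelineConfig())
        (call,) = calls
        assert call.status == "confirmed"
        assert call.n_sites == 2
        positions = [call.site.stop_pos] + [s.stop_pos for s in call.extra_sites]
        assert t.residues[positions[0]:positions[0] + 3] == "TAA"
        assert t.residues[positions[1]:positions[1] + 3] == "TAA"
        assert positions[1] > positions[0]
        assert summary["confirmed_sites"] == 2


class TestConfirmedCallInvariants:
    def test_plus_one_arithmetic_for_every_confirmed_call(
        self, small_ds, small_run
    ):
        """Deleting one nucleotide at the site must reconcile the frames."""
        calls, _ = small_run
        for c in calls:
            if c.status != "confirmed":
                continue
            assert c.candidate.frame_delta == 1
            up, down = c.candidate.upstream, c.candidate.downstream
            assert (down.frame - up.frame) % 3 == 1
            assert c.site.stop_pos % 3 == up.frame % 3

    def test_every_confirmed_stop_is_taa_or_tag(self, small_ds, small_run):
        calls, _ = small_run
        tx = {t.id: t for t in small_ds.transcripts}
        for c in calls:
            if c.status == "confirmed":
                stop = tx[c.transcript_id].residues[
                    c.site.stop_pos : c.site.stop_pos + 3
                ]
                assert stop in ("TAA", "TAG")
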