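"""The +1 programmed ribosomal frameshift detection pipeline.

A transcript becomes a +1 PRF call when

1. its homology to one protein is split across two reading frames
   (frame-split candidate, from the homology module),
2. the split is not explained by a retained intron (GT..AG heuristic or a
   user-supplied junction table),
3. the initial reading frame terminates at a slippery stop: an in-frame
   UAA/UAG close to the junction, preceded by the P-site codon (classically
   AAA in *Euplotes*),
4. deleting the T of that stop codon fuses the two frames into one ORF (the
   "fs-gene"), and
5. re-aligning the fs-gene to the subject produces a single-frame hit that
   covers both original fragments and extends the protein C-terminally.

Only net +1 shifts are callable: a confirmed site must make the downstream
frame congruent to the upstream frame after removing one nucleotide, i.e.
frame_delta == 1.  Candidates with frame_delta == 2 are reported but rejected
(no -1 PRF gene is known in *Euplotes*).

Detection is fully deterministic: no randomness anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homology import (
    FrameSplitCandidate,
    ScoringScheme,
    TranslatedHit,
    align_six_frames,
    default_scheme,
    find_frame_split_candidates,
    rank_candidates,
    search_hits,
)
from .seqcore import (
    EUPLOTID_CODE,
    GeneticCode,
    NucleotideSequence,
    ProteinSequence,
    find_orfs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SlipperySite",
    "FsGene",
    "PrfCall",
    "PipelineConfig",
    "exclude_intron_retention",
    "scan_slippery_site",
    "site_at",
    "build_fs_gene",
    "validate_fs_gene",
    "run_prf_pipeline",
]

WINDOW_FLANK = 30  # nt either side of the 6-nt motif kept for logo analyses


def junction_bounds(cand: FrameSplitCandidate) -> tuple[int, int]:
    """Query-coordinate bounds bracketing the frame-change junction.

    Hit ends are fuzzy: in AT-rich, low-complexity coding sequence a
    frame-shifted reading still resembles the protein, so an HSP can overshoot
    the true junction by dozens of residues in the wrong frame.  The subject
    coordinates are more trustworthy: the junction lies where the two hits'
    subject coverage meets.  Project that meeting point into query space from
    both sides and combine with the raw hit ends.  The projections anchor on
    each hit's *far* end (upstream start, downstream end), which lie in the
    trustworthy core of the alignment, and walk the ungapped diagonal from
    there to the subject positions where the coverage of the two hits meets.
    """
    up, down = cand.upstream, cand.downstream
    k_lo = min(up.s_end, down.s_start)
    k_hi = max(up.s_end, down.s_start)
    proj_lo = up.q_start + 3 * max(0, k_lo - up.s_start)
    proj_hi = down.q_end - 3 * max(0, down.s_end - k_hi)
    lo = min(up.q_end, down.q_start, proj_lo)
    hi = max(down.q_start, proj_hi)
    return lo, hi


def diagonal_offset(cand: FrameSplitCandidate) -> int:
    """Nucleotide offset between the two hits' alignment diagonals.

    Computed from the far (junction-distal) anchor of each hit:
    approximately the retained-intron length for an intron-retention event,
    approximately 1 for a genuine +1 frameshift.
    """
    up, down = cand.upstream, cand.downstream
    return (down.q_end - 3 * down.s_end) - (up.q_start - 3 * up.s_start)


@dataclass(frozen=True)
class SlipperySite:
    """A 0-frame stop with its P-site codon and 3'-context.

    ``window`` is the 30 nt preceding the motif + the 6-nt motif (P-site codon
    plus stop) + 30 nt following it, N-padded at sequence edges (66 nt total).
    """

    transcript_id: str
    stop_pos: int
    p_codon: str
    stop_codon: str
    next_nt: str
    motif_class: str
    tetra: str
    window: str

    def __post_init__(self):
        if self.stop_codon not in ("TAA", "TAG"):
            raise ValueError(f"not a Euplotid stop codon: {self.stop_codon}")
        if not self.motif_class.endswith("-TAR"):
            raise ValueError("motif_class must end in -TAR")
        if len(self.window) != 2 * WINDOW_FLANK + 6:
            raise ValueError("window must span the motif plus 30 nt flanks")


@dataclass(frozen=True)
class FsGene:
    """The in-silico fusion gene: the transcript with the stop's T removed."""

    transcript_id: str
    deletion_pos: int
    fs_sequence: NucleotideSequence
    fs_protein: ProteinSequence


@dataclass
class PrfCall:
    """Outcome of the pipeline for one frame-split candidate."""

    transcript_id: str
    subject_id: str
    candidate: FrameSplitCandidate
    status: str
    site: SlipperySite | None = None
    fs_gene: FsGene | None = None
    fs_hit: TranslatedHit | None = None
    extra_sites: list = field(default_factory=list)
    fs_extension_aa: int = 0

    STATUSES = (
        "confirmed",
        "rejected_no_site",
        "rejected_intron_retention",
        "rejected_no_extension",
        "rejected_wrong_delta",
    )

    @property
    def is_novel_motif(self) -> bool:
        return self.site is not None and self.site.p_codon != "AAA"

    @property
    def n_sites(self) -> int:
        return (1 if self.status == "confirmed" else 0) + len(self.extra_sites)


@dataclass
class PipelineConfig:
    """All tunable parameters of the detection pipeline, with defaults."""

    evalue_cutoff: float = 1e-5
    min_score: int = 50
    max_q_gap: int = 200
    min_subject_advance: int = 5
    max_s_overlap: int | None = None
    min_intron: int = 25
    max_intron: int = 500
    upstream_slack: int = 30
    downstream_slack: int = 30
    min_extension: int = 10
    min_span: float = 0.8
    include_reverse: bool = True
    max_sites_per_transcript: int = 3
    seed_k: int = 4
    min_seed_kmers: int = 3


# ---------------------------------------------------------------------------
# Stage 1: intron-retention exclusion
# ---------------------------------------------------------------------------

def exclude_intron_retention(
    t: NucleotideSequence,
    cand: FrameSplitCandidate,
    min_intron: int = 25,
    max_intron: int = 500,
    junctions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    offset_tolerance: int = 15,
) -> bool:
    """True when the frame split is better explained by a retained intron.

    The heuristic looks for a GT..AG segment in the junction region whose
    excision would make the two hit regions co-linear in a single frame.
    Co-linearity is judged on the diagonal offset of the two hits
    (:func:`diagonal_offset`), which is approximately the intron length for a
    genuine retention event but approximately 1 for a genuine +1 frameshift
    (one extra nucleotide), and is insensitive to hit-end overshoot because it
    anchors on the junction-distal hit ends.  A qualifying segment must start
    with GT, end with AG,
    have length within the configured intron bounds, be congruent to the
    observed frame change mod 3, and match the predicted offset to within
    ``offset_tolerance`` nt (absorbing alignment-gap fuzz).  A user-supplied
    junction table (per transcript, 0-based half-open intron coordinates)
    short-circuits the sequence scan.
    """
    up, down = cand.upstream, cand.downstream
    if up.q_end > len(t.residues) or down.q_end > len(t.residues):
        raise ValueError("candidate coordinates outside transcript")
    jlo, jhi = junction_bounds(cand)
    lo = max(0, jlo - 30)
    hi = min(len(t.residues), jhi + 30)
    predicted = diagonal_offset(cand)

    def qualifies(length: int) -> bool:
        return (min_intron <= length <= max_intron
                and length % 3 == cand.frame_delta
                and abs(length - predicted) <= offset_tolerance)

    if junctions is not None:
        return any(
            a >= lo and b <= hi and qualifies(b - a)
            for a, b in junctions.get(t.id, ())
        )
    if predicted + offset_tolerance < min_intron:
        return False  # offset too small for any intron to explain
    region = t.residues[lo:hi]
    gt_positions = [i for i in range(len(region) - 1) if region[i : i + 2] == "GT"]
    ag_ends = [j for j in range(2, len(region) + 1) if region[j - 2 : j] == "AG"]
    for i in gt_positions:
        for j in ag_ends:
            if qualifies(j - i):
                return True
    return False


# ---------------------------------------------------------------------------
# Stage 2: slippery-stop scan
# ---------------------------------------------------------------------------

def scan_slippery_site(
    t: NucleotideSequence,
    cand: FrameSplitCandidate,
    code: GeneticCode = EUPLOTID_CODE,
    upstream_slack: int = 30,
    downstream_slack: int = 30,
    scan_from: int | None = None,
) -> SlipperySite | None:
    """First in-frame stop of the upstream frame near the junction, or None.

    Walks codon-by-codon in the upstream hit's frame across the junction
    region (:func:`junction_bounds` widened by the slacks, or from
    ``scan_from`` when resuming past an already-confirmed site).
    """
    up, down = cand.upstream, cand.downstream
    seq = t.residues
    jlo, jhi = junction_bounds(cand)
    start = max(0, jlo - upstream_slack) if scan_from is None else scan_from
    start += (up.frame - start) % 3  # snap onto the upstream reading frame
    limit = min(len(seq) - 2, jhi + downstream_slack)
    if start >= limit:
        return None
    stops = code.stop_codons
    for pos in range(start, limit, 3):
        codon = seq[pos : pos + 3]
        if codon in stops and "N" not in codon:
            return site_at(t, pos)
    return None


def site_at(t: NucleotideSequence, stop_pos: int) -> SlipperySite:
    """Build the SlipperySite record for a known stop position (the stop codon
    must start at ``stop_pos``); used when reloading calls from report files."""
    seq = t.residues
    stop = seq[stop_pos : stop_pos + 3]
    p_codon = seq[stop_pos - 3 : stop_pos] if stop_pos >= 3 else "N" * 3
    next_nt = seq[stop_pos + 3] if stop_pos + 3 < len(seq) else "N"
    motif_start = stop_pos - 3
    win_lo = motif_start - WINDOW_FLANK
    win_hi = stop_pos + 3 + WINDOW_FLANK
    window = (
        "N" * max(0, -win_lo)
        + seq[max(0, win_lo) : min(len(seq), win_hi)]
        + "N" * max(0, win_hi - len(seq))
    )
    return SlipperySite(
        transcript_id=t.id,
        stop_pos=stop_pos,
        p_codon=p_codon,
        stop_codon=stop,
        next_nt=next_nt,
        motif_class=f"{p_codon}-TAR",
        tetra=stop + next_nt,
        window=window,
    )


# ---------------------------------------------------------------------------
# Stage 3: fs-gene construction
# ---------------------------------------------------------------------------

def build_fs_gene(
    t: NucleotideSequence,
    site: SlipperySite,
    code: GeneticCode = EUPLOTID_CODE,
) -> FsGene:
    """Delete the T of the slippery stop and extract the fused ORF.

    The fs-protein is the ORF, in the reading frame of the upstream segment
    (``stop_pos mod 3``, unchanged by the deletion), that contains the
    junction.  That frame is dictated by the candidate's arithmetic, making
    the choice deterministic even when another frame happens to hold a longer
    chance ORF through the same region.
    """
    if site.transcript_id != t.id:
        raise ValueError("site does not belong to this transcript")
    if t.residues[site.stop_pos] != "T":
        raise ValueError("slippery stop must begin with T")
    fs_seq = NucleotideSequence(
        f"{t.id}|fs", t.residues[: site.stop_pos] + t.residues[site.stop_pos + 1 :],
        description=f"T deleted at {site.stop_pos + 1} (1-based)",
    )
    frame = site.stop_pos % 3
    junction_orfs = [
        o for o in find_orfs(fs_seq, code, min_aa=1, frames=(frame,))
        if o.start <= site.stop_pos < o.end
    ]
    if junction_orfs:
        orf = max(junction_orfs, key=lambda o: len(o.protein.residues))
        fs_protein = ProteinSequence(
            f"{t.id}|fsprot", orf.protein.residues, allow_internal_stops=True
        )
    else:
        fs_protein = ProteinSequence(f"{t.id}|fsprot", "X", allow_internal_stops=True)
    return FsGene(t.id, site.stop_pos, fs_seq, fs_protein)


# ---------------------------------------------------------------------------
# Stage 4: re-alignment validation
# ---------------------------------------------------------------------------

def validate_fs_gene(
    fs: FsGene,
    subject: ProteinSequence,
    cand: FrameSplitCandidate,
    code: GeneticCode = EUPLOTID_CODE,
    scheme: ScoringScheme | None = None,
    min_score: int = 50,
    min_extension: int = 10,
    min_span: float = 0.8,
) -> tuple[str, TranslatedHit | None]:
    """Re-align the fs-gene to the subject and test for C-terminal extension.

    Confirmed iff the best post-deletion hit (single frame by construction)
    covers at least ``min_span`` of the union of the two original hits'
    subject intervals and its subject end exceeds the upstream hit's subject
    end by at least ``min_extension`` amino acids.
    """
    if scheme is None:
        scheme = default_scheme()
    # fs-gene sequences are already in candidate orientation
    hits = align_six_frames(
        fs.fs_sequence, subject, code, scheme, min_score, include_reverse=False
    )
    if not hits:
        return "rejected_no_extension", None
    best = hits[0]
    union_lo = min(cand.upstream.s_start, cand.downstream.s_start)
    union_hi = max(cand.upstream.s_end, cand.downstream.s_end)
    union_len = union_hi - union_lo
    overlap = max(0, min(best.s_end, union_hi) - max(best.s_start, union_lo))
    if union_len <= 0 or overlap / union_len < min_span:
        return "rejected_no_extension", best
    if best.s_end - cand.upstream.s_end < min_extension:
        return "rejected_no_extension", best
    return "confirmed", best


# ---------------------------------------------------------------------------
# Stage 5: full pipeline
# ---------------------------------------------------------------------------

def run_prf_pipeline(
    transcripts: Sequence[NucleotideSequence],
    proteins: Sequence[ProteinSequence] | None = None,
    hits: Sequence[TranslatedHit] | None = None,
    config: PipelineConfig | None = None,
    code: GeneticCode = EUPLOTID_CODE,
    scheme: ScoringScheme | None = None,
    junctions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[list[PrfCall], dict]:
    """Run hits -> candidates -> intron exclusion -> site scan -> fs-gene ->
    validation, one PrfCall per query transcript's best-ranked candidate.

    Either ``proteins`` (internal search) or precomputed ``hits`` must be
    given.  Transcripts may yield more than one confirmed site: after a
    confirmation the scan resumes downstream on the fs-gene coordinates,
    allowing genes with two successive +1 shifts.  A failing transcript is
    logged and never aborts the run.
    """
    cfg = config or PipelineConfig()
    if scheme is None:
        scheme = default_scheme()
    if hits is None:
        if proteins is None:
            raise ValueError("need either proteins or precomputed hits")
        hits = search_hits(
            transcripts, proteins, code, scheme, cfg.min_score,
            cfg.include_reverse, cfg.seed_k, cfg.min_seed_kmers,
        )
    by_id = {t.id: t for t in transcripts}
    subjects = {p.id: p for p in proteins} if proteins is not None else {}
    candidates = find_frame_split_candidates(
        hits, cfg.evalue_cutoff, cfg.max_q_gap,
        cfg.min_subject_advance, cfg.max_s_overlap,
    )
    per_query: dict[str, list[FrameSplitCandidate]] = {}
    for c in candidates:
        per_query.setdefault(c.query_id, []).append(c)

    calls: list[PrfCall] = []
    for qid in sorted(per_query):
        # best subject by score; within it, the candidate whose upstream hit
        # starts earliest in the protein -- the *initial* reading frame's
        # junction, which is where a multi-shift gene must be entered
        ranked = rank_candidates(per_query[qid])
        same_subject = [c for c in ranked
                        if c.subject_id == ranked[0].subject_id]
        cand = min(
            same_subject,
            key=lambda c: (c.upstream.s_start, c.downstream.s_start,
                           -c.total_score),
        )
        try:
            calls.append(
                _process_candidate(by_id[qid], cand, subjects, cfg, code,
                                   scheme, junctions)
            )
        except Exception:  # contract: one bad transcript never kills the run
            logger.exception("transcript %s failed; skipping", qid)

    summary = _summarize(transcripts, hits, per_query, calls)
    return calls, summary


def _process_candidate(t, cand, subjects, cfg, code, scheme, junctions) -> PrfCall:
    if not cand.upstream.forward:
        # reverse-orientation candidates: all hit coordinates refer to the
        # reverse complement, so analyze that sequence (site positions in the
        # resulting call are reverse-complement coordinates).
        from .seqcore import reverse_complement
        t = reverse_complement(t)
    call = PrfCall(t.id, cand.subject_id, cand, status="rejected_no_site")
    if exclude_intron_retention(t, cand, cfg.min_intron, cfg.max_intron, junctions):
        call.status = "rejected_intron_retention"
        return call
    if cand.frame_delta != 1:
        call.status = "rejected_wrong_delta"
        return call
    site = scan_slippery_site(t, cand, code, cfg.upstream_slack, cfg.downstream_slack)
    if site is None:
        call.status = "rejected_no_site"
        return call
    call.site = site
    fs = build_fs_gene(t, site, code)
    call.fs_gene = fs
    subject = subjects.get(cand.subject_id)
    if subject is None:
        raise ValueError(f"subject {cand.subject_id!r} unavailable for validation")
    status, fs_hit = validate_fs_gene(
        fs, subject, cand, code, scheme, cfg.min_score,
        cfg.min_extension, cfg.min_span,
    )
    call.status = status
    call.fs_hit = fs_hit
    if fs_hit is not None:
        call.fs_extension_aa = max(0, fs_hit.s_end - cand.upstream.s_end)
    if status == "confirmed":
        _scan_additional_sites(t, call, subject, cfg, code, scheme)
    return call


def _scan_additional_sites(t, call, subject, cfg, code, scheme):
    """Resume detection on the fs-gene to allow >1 shift per transcript."""
    current = call.fs_gene.fs_sequence
    deleted = [call.site.stop_pos]  # positions deleted so far, fs coordinates
    for _ in range(cfg.max_sites_per_transcript - 1):
        hits = align_six_frames(current, subject, code, scheme, cfg.min_score,
                                include_reverse=False)
        cands = [
            c for c in find_frame_split_candidates(
                hits, cfg.evalue_cutoff, cfg.max_q_gap,
                cfg.min_subject_advance, cfg.max_s_overlap)
            if c.frame_delta == 1
        ]
        cands = [c for c in cands if c.upstream.q_end > deleted[-1]]
        if not cands:
            break
        cand = rank_candidates(cands)[0]
        site = scan_slippery_site(current, cand, code,
                                  cfg.upstream_slack, cfg.downstream_slack,
                                  scan_from=deleted[-1] + 3)
        if site is None:
            break
        fs = build_fs_gene(current, site, code)
        status, _ = validate_fs_gene(fs, subject, cand, code, scheme,
                                     cfg.min_score, cfg.min_extension, cfg.min_span)
        if status != "confirmed":
            break
        # map the fs-coordinate site back onto the original transcript
        orig_pos = site.stop_pos + sum(1 for d in deleted if d <= site.stop_pos)
        call.extra_sites.append(site_at(t, orig_pos))
        deleted.append(site.stop_pos)
        current = fs.fs_sequence


def _summarize(transcripts, hits, per_query, calls) -> dict:
    status_counts = {s: 0 for s in PrfCall.STATUSES}
    motif_hist: dict[str, int] = {}
    classical = novel = 0
    n_sites = 0
    for call in calls:
        status_counts[call.status] += 1
        if call.status == "confirmed":
            n_sites += call.n_sites
            for site in [call.site] + call.extra_sites:
                motif_hist[site.motif_class] = motif_hist.get(site.motif_class, 0) + 1
            if call.is_novel_motif:
                novel += 1
            else:
                classical += 1
    funnel = {
        "transcripts_in": len(transcripts),
        "transcripts_with_hits": len({h.query_id for h in hits}),
        "frame_split_transcripts": len(per_query),
        "surviving_intron_filter": len(per_query)
        - status_counts["rejected_intron_retention"],
        "site_found": status_counts["confirmed"]
        + status_counts["rejected_no_extension"],
        "confirmed": status_counts["confirmed"],
    }
    return {
        "funnel": funnel,
        "status_counts": status_counts,
        "motif_class_counts": dict(sorted(motif_hist.items())),
        "classical_calls": classical,
        "novel_calls": novel,
        "confirmed_sites": n_sites,
    }
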