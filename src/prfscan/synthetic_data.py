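"""Seeded generator of ground-truthed synthetic inputs.

The generator emulates the data structure of an AT-rich ciliate macronuclear
transcriptome in which a sizeable fraction of genes (~11% by default) require a
+1 programmed ribosomal frameshift at a slippery stop to encode their full
protein:

* a protein set standing in for the homology-search subjects,
* transcripts encoding those proteins, a configurable fraction carrying a
  planted +1 PRF whose slippery motif, stop codon and 3'-context follow
  configurable distributions (defaults: heavily AAA-TAR, UAA-skewed, A as the
  favoured 3' base),
* intron-retention decoys whose inserted GT..AG segment also splits homology
  across frames,
* non-homologous random decoys,
* telomere-capped nanochromosomes (~2 kb, C4A4/G4T4 caps) embedding the
  transcripts for assembly QC,
* per-transcript expression values (FPKM), lower on average for frameshifted
  genes.

The key structural guarantee, enforced by construction and re-checked after
every build: deleting the T of the planted slippery stop yields a sequence
whose junction ORF translates exactly to the source protein, and the planted
stop is the first in-frame stop downstream of the upstream homology segment.

All randomness flows from a single numpy Generator seeded from the config, in
a fixed draw order; outputs are byte-identical for a given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqcore import (
    EUPLOTID_CODE,
    NucleotideSequence,
    ProteinSequence,
    translate_str,
    write_fasta,
)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_proteins",
    "generate_transcripts",
    "generate_nanochromosomes",
    "generate_dataset",
    "write_dataset",
    "load_truth",
    "evaluate_recovery",
    "RecoveryMetrics",
]


def _default_motif_distribution() -> dict:
    # Classical AAA-TAR dominates; the four most frequent novel motifs carry
    # the remaining mass in their observed order.
    return {"AAA": 0.943, "TTT": 0.020, "AAG": 0.015, "AAT": 0.011, "ATT": 0.011}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 42
    n_transcripts: int = 500
    prf_fraction: float = 0.11
    intron_retention_fraction: float = 0.05
    decoy_fraction: float = 0.20
    motif_distribution: dict = field(default_factory=_default_motif_distribution)
    stop_distribution_slippery: dict = field(
        default_factory=lambda: {"TAA": 0.894, "TAG": 0.106}
    )
    stop_distribution_normal: dict = field(
        default_factory=lambda: {"TAA": 0.796, "TAG": 0.204}
    )
    next_nt_distribution_slippery: dict = field(
        default_factory=lambda: {"A": 0.55, "T": 0.20, "C": 0.15, "G": 0.10}
    )
    next_nt_distribution_normal: dict = field(
        default_factory=lambda: {"A": 0.40, "T": 0.38, "C": 0.12, "G": 0.10}
    )
    protein_len_range: tuple = (120, 260)
    gc_coding: float = 0.31
    gc_noncoding: float = 0.23
    intron_len_range: tuple = (26, 120)  # sampled lengths are forced to %3 == 2
    nanochromosome_median: int = 2000
    nanochromosome_sigma: float = 0.45
    cap_units_range: tuple = (2, 7)
    cap_dropout: float = 0.0
    fpkm_mean_prf: float = 10.59
    fpkm_mean_normal: float = 44.38
    fpkm_sigma: float = 1.0

    def __post_init__(self):
        for dist in (
            self.motif_distribution,
            self.stop_distribution_slippery,
            self.stop_distribution_normal,
            self.next_nt_distribution_slippery,
            self.next_nt_distribution_normal,
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"distribution does not sum to 1: {dist}")
        for frac in (self.prf_fraction, self.intron_retention_fraction,
                     self.decoy_fraction, self.cap_dropout):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if (self.prf_fraction + self.intron_retention_fraction
                + self.decoy_fraction) > 1.0:
            raise ValueError("class fractions exceed 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic transcript."""

    transcript_id: str
    is_prf: bool
    stop_pos: int | None
    motif_class: str | None
    stop_codon: str | None
    next_nt: str | None
    protein_id: str | None
    is_intron_retention_decoy: bool = False
    is_nonhomologous_decoy: bool = False

    def __post_init__(self):
        if self.is_prf and (self.stop_pos is None or self.motif_class is None
                            or self.protein_id is None):
            raise ValueError("PRF truth requires site position, motif and protein")
        if self.is_intron_retention_decoy and self.is_nonhomologous_decoy:
            raise ValueError("at most one decoy flag may be set")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    proteins: list
    transcripts: list
    truth: list
    contigs: list
    fpkm: dict  # transcript_id -> float


# ---------------------------------------------------------------------------
# Codon machinery
# ---------------------------------------------------------------------------

_SENSE_CODONS = [c for c, aa in EUPLOTID_CODE.codon_map.items() if aa != "*"]


def _base_probs(gc: float) -> dict:
    return {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}


def _codon_weights(gc: float) -> tuple[list, np.ndarray, dict]:
    """Sense codons with base-composition weights, plus per-aa codon tables."""
    bp = _base_probs(gc)
    weights = np.array(
        [bp[c[0]] * bp[c[1]] * bp[c[2]] for c in _SENSE_CODONS], dtype=float
    )
    weights /= weights.sum()
    by_aa: dict[str, tuple[list, np.ndarray]] = {}
    for aa in set(EUPLOTID_CODE.codon_map.values()) - {"*"}:
        codons = [c for c in _SENSE_CODONS if EUPLOTID_CODE.codon_map[c] == aa]
        w = np.array([bp[c[0]] * bp[c[1]] * bp[c[2]] for c in codons])
        by_aa[aa] = (codons, w / w.sum())
    return _SENSE_CODONS, weights, by_aa


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    bp = _base_probs(gc)
    bases = np.array(list("ACGT"))
    probs = np.array([bp[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=length, p=probs)) if length else ""


def _choose(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------

def generate_proteins(cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> list:
    """I.i.d. proteins drawn by sampling sense codons at the coding GC target.

    Sampling codons (rather than amino acids) automatically gives the AT-biased
    amino-acid composition that an AT-rich coding genome actually has, so the
    reverse-translated transcripts meet the same GC target.  Each protein
    starts with M.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    codons, weights, _ = _codon_weights(cfg.gc_coding)
    codon_arr = np.array(codons)
    lo, hi = cfg.protein_len_range
    if lo < 3 or hi < lo:
        raise ValueError("invalid protein_len_range")
    proteins = []
    for i in range(cfg.n_transcripts):
        L = int(rng.integers(lo, hi + 1))
        picks = rng.choice(codon_arr, size=L - 1, p=weights)
        aa = "M" + "".join(EUPLOTID_CODE.codon_map[c] for c in picks)
        proteins.append(ProteinSequence(f"prot{i:05d}", aa))
    return proteins


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def _motif_aa(motif: str) -> str:
    """Amino acid encoded by a P-site motif codon (must be a sense codon)."""
    aa = EUPLOTID_CODE.codon_map[motif]
    if aa == "*":
        raise ValueError(f"P-site motif {motif} is a stop codon")
    return aa


def _encode(rng, protein_residues: str, by_aa) -> list:
    return [
        _pick_codon(rng, by_aa, aa) for aa in protein_residues
    ]


def _pick_codon(rng, by_aa, aa: str) -> str:
    codons, w = by_aa[aa]
    return codons[rng.choice(len(codons), p=w)]


def _has_confounding_intron(seq: str, center: int, delta: int,
                            min_intron: int, max_intron: int,
                            halfwidth: int = 40) -> bool:
    lo = max(0, center - halfwidth)
    hi = min(len(seq), center + halfwidth)
    region = seq[lo:hi]
    for i in range(len(region) - 1):
        if region[i : i + 2] != "GT":
            continue
        for j in range(i + min_intron, min(len(region), i + max_intron) + 1):
            if region[j - 2 : j] == "AG" and (j - i) % 3 == delta:
                return True
    return False


def generate_transcripts(
    cfg: SyntheticConfig,
    proteins: Sequence[ProteinSequence],
    rng: np.random.Generator | None = None,
) -> tuple[list, list, list]:
    """Build transcripts with planted truth; returns (transcripts, truth,
    finalized proteins).

    Transcript i encodes protein i.  For a planted +1 PRF the +1 overlap
    arithmetic fixes the two junction residues of the protein: the P-site
    codon encodes the residue before the shift and the post-shift codon
    (stop[1:3] + next nucleotide) encodes the residue after it, so those two
    residues of the source protein are set accordingly -- exactly as in real
    *Euplotes* frameshift genes, where the junction carries Lys.  The returned
    protein list reflects these adjustments and is the set to search against.

    Guarantees, re-checked for every planted transcript: the planted stop is
    the first in-frame stop after the upstream segment, and deleting its T
    yields a junction ORF translating to the source protein exactly.
    """
    if not proteins:
        raise ValueError("protein set must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    _, _, by_aa = _codon_weights(cfg.gc_coding)
    final_proteins = list(proteins)
    transcripts: list[NucleotideSequence] = []
    truth: list[TruthRecord] = []

    p_prf = cfg.prf_fraction
    p_ret = cfg.intron_retention_fraction
    p_dec = cfg.decoy_fraction
    categories = ["prf", "retention", "decoy", "normal"]
    probs = np.array([p_prf, p_ret, p_dec, 1.0 - p_prf - p_ret - p_dec])

    for i in range(cfg.n_transcripts):
        tid = f"tx{i:05d}"
        category = categories[rng.choice(4, p=probs)]
        protein = final_proteins[i % len(final_proteins)]
        if category == "prf":
            t, rec, new_prot = _build_prf_transcript(cfg, rng, tid, protein, by_aa)
            final_proteins[i % len(final_proteins)] = new_prot
        elif category == "retention":
            t, rec = _build_retention_transcript(cfg, rng, tid, protein, by_aa)
        elif category == "decoy":
            t, rec = _build_nonhomologous_decoy(cfg, rng, tid)
        else:
            t, rec = _build_normal_transcript(cfg, rng, tid, protein, by_aa)
        transcripts.append(t)
        truth.append(rec)
    _self_check(transcripts, truth, final_proteins)
    return transcripts, truth, final_proteins


def _utr5(cfg, rng) -> str:
    """5' UTR ending with an in-frame stop just before the CDS start."""
    u = int(rng.integers(18, 60))
    return _random_dna(rng, u, cfg.gc_noncoding) + "TAA"


def _build_normal_transcript(cfg, rng, tid, protein, by_aa,
                             _return_parts: bool = False):
    utr5 = _utr5(cfg, rng)
    stop = _choose(rng, cfg.stop_distribution_normal)
    nxt = _choose(rng, cfg.next_nt_distribution_normal)
    utr3 = nxt + _random_dna(rng, int(rng.integers(20, 80)), cfg.gc_noncoding)
    codons = _encode(rng, protein.residues, by_aa)
    seq = utr5 + "".join(codons) + stop + utr3
    t = NucleotideSequence(tid, seq)
    rec = TruthRecord(tid, False, None, None, stop, nxt, protein.id)
    if _return_parts:
        return t, rec, utr5, codons, stop, utr3
    return t, rec


def _build_prf_transcript(cfg, rng, tid, protein, by_aa):
    """Plant a +1 PRF; may adjust the protein's two junction residues."""
    res = list(protein.residues)
    L = len(res)
    motif = _choose(rng, cfg.motif_distribution)
    stop = _choose(rng, cfg.stop_distribution_slippery)
    nxt = _choose(rng, cfg.next_nt_distribution_slippery)
    post_codon = stop[1] + stop[2] + nxt
    k = int(rng.integers(L // 3, 2 * L // 3))  # shift after k residues
    res[k - 1] = _motif_aa(motif)
    res[k] = EUPLOTID_CODE.codon_map[post_codon]
    new_prot = ProteinSequence(protein.id, "".join(res), protein.description)

    for _ in range(80):  # rejection-sample junction composition
        utr5 = _utr5(cfg, rng)
        up_codons = _encode(rng, new_prot.residues[: k - 1], by_aa) + [motif]
        tail_codons = _encode(rng, new_prot.residues[k + 1 :], by_aa)
        term_stop = _choose(rng, cfg.stop_distribution_normal)
        utr3 = _random_dna(rng, int(rng.integers(20, 80)), cfg.gc_noncoding)
        seq = (utr5 + "".join(up_codons) + "T" + post_codon
               + "".join(tail_codons) + term_stop + utr3)
        stop_pos = len(utr5) + 3 * k
        assert seq[stop_pos : stop_pos + 3] == stop
        # a chance GT..AG of length = 1 mod 3 near the junction would mimic a
        # retained intron and get the transcript excluded; resample if present
        if not _has_confounding_intron(seq, stop_pos, 1, 25, 500):
            break
    t = NucleotideSequence(tid, seq)
    rec = TruthRecord(tid, True, stop_pos, f"{motif}-TAR", stop, nxt, new_prot.id)
    return t, rec, new_prot


def _build_retention_transcript(cfg, rng, tid, protein, by_aa):
    """A normal gene with an unspliced GT..AG segment (length = 2 mod 3)."""
    utr5 = _utr5(cfg, rng)
    codons = _encode(rng, protein.residues, by_aa)
    stop = _choose(rng, cfg.stop_distribution_normal)
    nxt = _choose(rng, cfg.next_nt_distribution_normal)
    utr3 = nxt + _random_dna(rng, int(rng.integers(20, 80)), cfg.gc_noncoding)
    L = len(codons)
    j = int(rng.integers(L // 3, 2 * L // 3))
    lo, hi = cfg.intron_len_range
    ilen = int(rng.integers(lo, hi + 1))
    ilen += (2 - ilen % 3) % 3  # force length = 2 mod 3: cannot be a +1 shift
    intron = "GT" + _random_dna(rng, ilen - 4, cfg.gc_noncoding) + "AG"
    seq = (utr5 + "".join(codons[:j]) + intron + "".join(codons[j:])
           + stop + utr3)
    t = NucleotideSequence(tid, seq)
    rec = TruthRecord(tid, False, None, None, stop, nxt, protein.id,
                      is_intron_retention_decoy=True)
    return t, rec


def _build_nonhomologous_decoy(cfg, rng, tid):
    length = int(rng.integers(500, 1200))
    t = NucleotideSequence(tid, _random_dna(rng, length, cfg.gc_noncoding))
    rec = TruthRecord(tid, False, None, None, None, None, None,
                      is_nonhomologous_decoy=True)
    return t, rec


def _self_check(transcripts, truth, proteins) -> None:
    """Re-verify the generator's structural guarantee on every planted PRF."""
    prot_by_id = {p.id: p for p in proteins}
    tx_by_id = {t.id: t for t in transcripts}
    for rec in truth:
        if not rec.is_prf:
            continue
        t = tx_by_id[rec.transcript_id]
        pos = rec.stop_pos
        assert t.residues[pos : pos + 3] == rec.stop_codon
        fs = t.residues[:pos] + t.residues[pos + 1 :]
        aa = translate_str(fs, pos % 3, EUPLOTID_CODE)
        # junction ORF: between the stop before the CDS and the terminal stop
        prot = prot_by_id[rec.protein_id].residues
        segment = max(aa.split("*"), key=len)
        if segment != prot:
            raise AssertionError(
                f"{rec.transcript_id}: fs translation does not reproduce "
                f"{rec.protein_id}"
            )


# ---------------------------------------------------------------------------
# Nanochromosomes
# ---------------------------------------------------------------------------

def generate_nanochromosomes(
    cfg: SyntheticConfig,
    transcripts: Sequence[NucleotideSequence],
    rng: np.random.Generator | None = None,
) -> list:
    """Embed each transcript in an AT-rich telomere-capped nanochromosome.

    Contig length is lognormal with the configured median (~2 kb); caps are
    2-7 units of C4A4 (5') and G4T4 (3').  ``cap_dropout`` is the fraction of
    contigs losing one or both caps, for exercising the QC classifier.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    cap5_unit = "CCCCAAAA"
    cap3_unit = "GGGGTTTT"
    contigs = []
    for i, t in enumerate(transcripts):
        u5 = int(rng.integers(cfg.cap_units_range[0], cfg.cap_units_range[1] + 1))
        u3 = int(rng.integers(cfg.cap_units_range[0], cfg.cap_units_range[1] + 1))
        cap5, cap3 = cap5_unit * u5, cap3_unit * u3
        if cfg.cap_dropout and rng.random() < cfg.cap_dropout:
            which = rng.choice(3)
            if which == 0:
                cap5 = ""
            elif which == 1:
                cap3 = ""
            else:
                cap5 = cap3 = ""
        target = int(rng.lognormal(np.log(cfg.nanochromosome_median),
                                   cfg.nanochromosome_sigma))
        pad = max(40, target - len(t) - len(cap5) - len(cap3))
        left = int(rng.integers(20, max(21, pad - 19)))
        right = pad - left
        seq = (cap5 + _random_dna(rng, left, cfg.gc_noncoding) + t.residues
               + _random_dna(rng, right, cfg.gc_noncoding) + cap3)
        contigs.append(NucleotideSequence(f"contig{i:05d}", seq))
    return contigs


# ---------------------------------------------------------------------------
# Orchestration, truth I/O, recovery metrics
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset from one RNG stream in a fixed draw order:
    proteins, transcripts, nanochromosomes, then FPKM values."""
    rng = np.random.default_rng(cfg.seed)
    proteins = generate_proteins(cfg, rng)
    transcripts, truth, proteins = generate_transcripts(cfg, proteins, rng)
    contigs = generate_nanochromosomes(cfg, transcripts, rng)
    fpkm = {}
    for rec in truth:
        mean = cfg.fpkm_mean_prf if rec.is_prf else cfg.fpkm_mean_normal
        mu = np.log(mean) - cfg.fpkm_sigma ** 2 / 2
        fpkm[rec.transcript_id] = float(rng.lognormal(mu, cfg.fpkm_sigma))
    return SyntheticDataset(cfg, proteins, transcripts, truth, contigs, fpkm)


_TRUTH_COLS = [
    "transcript_id", "is_prf", "stop_pos", "motif_class", "stop_codon",
    "next_nt", "protein_id", "is_intron_retention_decoy",
    "is_nonhomologous_decoy",
]


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write transcripts/proteins/contigs FASTA, truth.tsv, expression.tsv and
    manifest.json (config echo + realized counts).  Fully deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.transcripts, outdir / "transcripts.fasta")
    write_fasta(ds.proteins, outdir / "proteins.fasta")
    write_fasta(ds.contigs, outdir / "contigs.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for rec in ds.truth:
            row = [
                rec.transcript_id, str(int(rec.is_prf)),
                "" if rec.stop_pos is None else str(rec.stop_pos),
                rec.motif_class or "", rec.stop_codon or "", rec.next_nt or "",
                rec.protein_id or "",
                str(int(rec.is_intron_retention_decoy)),
                str(int(rec.is_nonhomologous_decoy)),
            ]
            fh.write("\t".join(row) + "\n")
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("transcript_id\tfpkm\n")
        for rec in ds.truth:
            fh.write(f"{rec.transcript_id}\t{ds.fpkm[rec.transcript_id]:.4f}\n")
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "realized": {
            "n_prf": sum(r.is_prf for r in ds.truth),
            "n_intron_retention": sum(r.is_intron_retention_decoy
                                      for r in ds.truth),
            "n_nonhomologous": sum(r.is_nonhomologous_decoy for r in ds.truth),
            "n_transcripts": len(ds.transcripts),
            "n_proteins": len(ds.proteins),
            "n_contigs": len(ds.contigs),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLS:
            raise ValueError(f"unexpected truth columns: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    transcript_id=f[0],
                    is_prf=bool(int(f[1])),
                    stop_pos=int(f[2]) if f[2] else None,
                    motif_class=f[3] or None,
                    stop_codon=f[4] or None,
                    next_nt=f[5] or None,
                    protein_id=f[6] or None,
                    is_intron_retention_decoy=bool(int(f[7])),
                    is_nonhomologous_decoy=bool(int(f[8])),
                )
            )
    return records


@dataclass
class RecoveryMetrics:
    sensitivity: float
    false_discovery_proportion: float
    n_truth_prf: int
    n_confirmed: int
    true_positives: int
    false_positives: int
    false_negatives: int
    site_exact_fraction: float
    motif_confusion: dict  # (true motif, called motif) -> count


def evaluate_recovery(calls, truth, pos_tolerance: int = 0) -> RecoveryMetrics:
    """Score confirmed calls against planted truth.

    A confirmed call is a true positive iff its transcript is truth-PRF and
    the called stop position is within ``pos_tolerance`` nt of the planted
    one.  FDP over zero confirmed calls is reported as 0.
    """
    truth_by_id = {r.transcript_id: r for r in truth}
    confirmed = [c for c in calls if c.status == "confirmed"]
    tp = fp = 0
    exact = 0
    confusion: dict[tuple, int] = {}
    for call in confirmed:
        rec = truth_by_id.get(call.transcript_id)
        if rec is None:
            raise ValueError(f"unknown transcript id in calls: {call.transcript_id}")
        if rec.is_prf and abs(call.site.stop_pos - rec.stop_pos) <= pos_tolerance:
            tp += 1
            if call.site.stop_pos == rec.stop_pos:
                exact += 1
            key = (rec.motif_class, call.site.motif_class)
            confusion[key] = confusion.get(key, 0) + 1
        else:
            fp += 1
    n_truth = sum(r.is_prf for r in truth)
    return RecoveryMetrics(
        sensitivity=tp / n_truth if n_truth else 0.0,
        false_discovery_proportion=fp / len(confirmed) if confirmed else 0.0,
        n_truth_prf=n_truth,
        n_confirmed=len(confirmed),
        true_positives=tp,
        false_positives=fp,
        false_negatives=n_truth - tp,
        site_exact_fraction=exact / tp if tp else 0.0,
        motif_confusion=confusion,
    )
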