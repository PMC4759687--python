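"""Telomere-aware QC for nanochromosome assemblies.

*Euplotes* macronuclear DNA comes as gene-sized nanochromosomes (~2 kb) capped
at both ends with 5'-(C4A4)n-3' telomeric repeats (G4T4 on the 3' end of the
plus strand).  This module classifies contigs by telomere content
(0/1/2/multi-telomere), and computes the usual assembly summary metrics: N50,
GC content, length histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqcore import NucleotideSequence, reverse_complement

__all__ = [
    "TelomereAnnotation",
    "AssemblyStats",
    "detect_telomeres",
    "assembly_stats",
    "length_histogram",
]

TELOMERE_CLASSES = ("0-telomere", "1-telomere", "2-telomere", "multi-telomere")


@dataclass(frozen=True)
class TelomereAnnotation:
    contig_id: str
    has_5p: bool
    has_3p: bool
    internal_runs: int
    telomere_class: str

    def __post_init__(self):
        expected = _classify(self.has_5p, self.has_3p, self.internal_runs)
        if self.telomere_class != expected:
            raise ValueError(
                f"{self.contig_id}: class {self.telomere_class!r} inconsistent "
                f"with flags (expected {expected!r})"
            )


def _classify(has_5p: bool, has_3p: bool, internal_runs: int) -> str:
    if internal_runs >= 1:
        return "multi-telomere"
    if has_5p and has_3p:
        return "2-telomere"
    if has_5p or has_3p:
        return "1-telomere"
    return "0-telomere"


def _tandem_runs(seq: str, motif: str) -> list[tuple[int, int, float]]:
    """Maximal tandem runs of ``motif``: (start, end, units).

    Units count full copies plus any trailing partial copy (a proper prefix of
    the motif immediately following the last full copy).
    """
    m = len(motif)
    runs = []
    i = seq.find(motif)
    while i != -1:
        j = i
        while seq[j : j + m] == motif:
            j += m
        full = (j - i) // m
        partial = 0
        while partial < m - 1 and j + partial < len(seq) and \
                seq[j + partial] == motif[partial]:
            partial += 1
        runs.append((i, j + partial, full + partial / m))
        nxt = seq.find(motif, j)
        i = nxt
    return runs


def detect_telomeres(
    c: NucleotideSequence,
    motif: str = "CCCCAAAA",
    min_units: float = 1.5,
    end_window: int = 50,
) -> TelomereAnnotation:
    """Classify one contig by its telomeric repeat content.

    A 5' cap is a tandem run of >= ``min_units`` copies of ``motif`` (the last
    copy may be partial) beginning within ``end_window`` nt of the 5' end; the
    3' cap uses the reverse-complement motif (G4T4) ending within
    ``end_window`` of the 3' end.  Internal runs are tandem runs of >= 2 full
    copies of either motif lying wholly outside both end windows.
    """
    if not motif:
        raise ValueError("motif must be a non-empty DNA string")
    seq = c.residues
    L = len(seq)
    rc = reverse_complement(motif)
    if L < len(motif):
        warnings.warn(f"{c.id}: contig shorter than telomere motif")
        return TelomereAnnotation(c.id, False, False, 0, "0-telomere")

    runs_5 = _tandem_runs(seq, motif)
    has_5p = any(start <= end_window and units >= min_units
                 for start, _, units in runs_5)
    # 3' side: scan the reverse complement with the same rule so partial copies
    # on the inboard side of the cap are handled symmetrically.
    rc_seq = reverse_complement(seq)
    runs_3 = _tandem_runs(rc_seq, motif)
    has_3p = any(start <= end_window and units >= min_units
                 for start, _, units in runs_3)

    internal = 0
    for m in (motif, rc):
        for start, end, units in _tandem_runs(seq, m):
            full = int(units)
            if full >= 2 and start >= end_window and \
                    start + full * len(m) <= L - end_window:
                internal += 1
    return TelomereAnnotation(c.id, has_5p, has_3p, internal,
                              _classify(has_5p, has_3p, internal))


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int
    mean_len: float
    max_len: int
    gc_fraction: float
    class_counts: dict
    pct_2_telomere: float
    n_short: int


def assembly_stats(
    contigs: Sequence[NucleotideSequence],
    annotations: Sequence[TelomereAnnotation],
    short_threshold: int = 500,
) -> AssemblyStats:
    """Summary metrics over a contig set.

    N50 is the largest length L such that contigs of length >= L hold at least
    half of the total bases.  The GC denominator excludes N.
    """
    if not contigs:
        raise ValueError("empty contig set")
    ann_ids = {a.contig_id for a in annotations}
    if ann_ids != {c.id for c in contigs} or len(annotations) != len(contigs):
        raise ValueError("annotations must cover exactly the contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    gc = at = 0
    for c in contigs:
        gc += c.residues.count("G") + c.residues.count("C")
        at += c.residues.count("A") + c.residues.count("T")
    class_counts = {cls: 0 for cls in TELOMERE_CLASSES}
    for a in annotations:
        class_counts[a.telomere_class] += 1
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bp=total,
        n50=n50,
        mean_len=total / len(contigs),
        max_len=lengths[0],
        gc_fraction=gc / (gc + at) if gc + at else 0.0,
        class_counts=class_counts,
        pct_2_telomere=100.0 * class_counts["2-telomere"] / len(contigs),
        n_short=sum(1 for L in lengths if L <= short_threshold),
    )


def length_histogram(
    contigs: Iterable[NucleotideSequence],
    bin_width: int,
    normalize: bool = False,
) -> dict:
    """Counts (or frequencies) of contig lengths per ``bin_width`` bin.

    Keys are (lo, hi) half-open bin bounds; only occupied bins appear.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    hist: dict[tuple[int, int], float] = {}
    n = 0
    for c in contigs:
        lo = (len(c) // bin_width) * bin_width
        key = (lo, lo + bin_width)
        hist[key] = hist.get(key, 0) + 1
        n += 1
    if normalize and n:
        hist = {k: v / n for k, v in hist.items()}
    return dict(sorted(hist.items()))
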