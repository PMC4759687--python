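"""Stop-codon usage, slippery-site logo analytics and expression comparison.

The release factor recognises a tetranucleotide termination signal -- the stop
codon plus its nearest 3' neighbour -- so usage is tabulated both at the
trinucleotide (UAA vs UAG) and the tetranucleotide (stop + next base) level,
separately for "normal" stops (terminating stops of the longest ORFs of
non-frameshifted transcripts) and "slippery" stops (confirmed +1 PRF sites).
Association between class and codon is tested with a two-sided Fisher exact
test; positional conservation around the slippery motif is summarized as
per-position information content (2 - Shannon entropy, bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .seqcore import EUPLOTID_CODE, GeneticCode, NucleotideSequence, longest_orf

__all__ = [
    "StopUsageTable",
    "ContingencyTable2x2",
    "LogoMatrix",
    "normal_stop_positions",
    "count_stop_usage",
    "fisher_exact_two_sided",
    "stop_usage_contingency",
    "logo_from_windows",
    "consensus",
    "compare_expression",
]

_STOPS = ("TAA", "TAG")
_BASES = "ACGT"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class StopUsageTable:
    """Tri- and tetranucleotide stop usage for one class of stops."""

    class_label: str
    tri_counts: dict
    tetra_counts: dict
    n_excluded_no_context: int

    def __post_init__(self):
        if sum(self.tetra_counts.values()) + self.n_excluded_no_context != sum(
            self.tri_counts.values()
        ):
            raise ValueError("tetra counts + excluded must equal tri counts")

    @property
    def n(self) -> int:
        return sum(self.tri_counts.values())

    def tri_fraction(self, stop: str) -> float:
        return self.tri_counts.get(stop, 0) / self.n if self.n else 0.0

    def tetra_fraction(self, stop: str, nxt: str) -> float:
        total = sum(self.tetra_counts.values())
        return self.tetra_counts.get((stop, nxt), 0) / total if total else 0.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one positive margin required")


def normal_stop_positions(
    transcripts: Sequence[NucleotideSequence],
    code: GeneticCode = EUPLOTID_CODE,
    exclude_ids: Iterable[str] = (),
    min_aa: int = 30,
) -> list[tuple[str, int]]:
    """Terminating stop of the longest ORF of each non-excluded transcript.

    Returns (transcript_id, stop start position) pairs; transcripts whose
    longest ORF runs off the sequence end contribute nothing.
    """
    excluded = set(exclude_ids)
    out = []
    for t in transcripts:
        if t.id in excluded:
            continue
        orf = longest_orf(t, code, min_aa=min_aa)
        if orf is not None and orf.terminated:
            out.append((t.id, orf.end - 3))
    return out


def count_stop_usage(
    stop_positions: Sequence[tuple[str, int]],
    transcripts: Mapping[str, NucleotideSequence] | Sequence[NucleotideSequence],
    class_label: str,
) -> StopUsageTable:
    """Tabulate stop codons and their 3' neighbours.

    A stop occupying the terminal 3 nt of its transcript has no 3' context:
    it contributes to the trinucleotide counts and to
    ``n_excluded_no_context`` only.
    """
    if class_label not in ("normal", "slippery"):
        raise ValueError(f"unknown class label {class_label!r}")
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t for t in transcripts}
    tri: dict[str, int] = {}
    tetra: dict[tuple[str, str], int] = {}
    n_excluded = 0
    for tid, pos in stop_positions:
        seq = transcripts[tid].residues
        stop = seq[pos : pos + 3]
        if stop not in _STOPS:
            raise ValueError(f"{tid}:{pos}: not a stop codon ({stop})")
        tri[stop] = tri.get(stop, 0) + 1
        if pos + 3 < len(seq) and seq[pos + 3] in _BASES:
            key = (stop, seq[pos + 3])
            tetra[key] = tetra.get(key, 0) + 1
        else:
            n_excluded += 1
    return StopUsageTable(class_label, tri, tetra, n_excluded)


def stop_usage_contingency(
    normal: StopUsageTable, slippery: StopUsageTable
) -> ContingencyTable2x2:
    """2x2 table: rows = class (normal, slippery), cols = codon (TAA, TAG)."""
    return ContingencyTable2x2(
        normal.tri_counts.get("TAA", 0), normal.tri_counts.get("TAG", 0),
        slippery.tri_counts.get("TAA", 0), slippery.tri_counts.get("TAG", 0),
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p using the point-probability rule.

    p is the sum of hypergeometric probabilities of all tables sharing the
    observed margins whose point probability does not exceed that of the
    observed table (relative tolerance 1e-7 on the comparison).  Degenerate
    margins give p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    # hypergeometric log-pmf via log-gamma; vectorized over the support
    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logpmf = log_comb(r1, ks) + log_comb(r2, c1 - ks) - log_comb(n, c1)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - k_lo]
    # normalize by the summed pmf so the all-tables-qualify case is exactly 1
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum() / pmf.sum())
    return min(1.0, p)


@dataclass
class LogoMatrix:
    """Per-position base counts and information content around the motif.

    ``positions`` are offsets relative to the motif start (the first base of
    the P-site codon); ``info_bits`` is NaN at positions with no non-N
    observations.
    """

    positions: list
    counts: np.ndarray  # (L, 4) over A, C, G, T
    info_bits: np.ndarray

    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)


def logo_from_windows(windows: Sequence[str], motif_offset: int = 30) -> LogoMatrix:
    """Build the logo matrix from equal-length windows (N excluded per column).

    info_bits[i] = 2 - H_i, H_i the Shannon entropy (bits) of the observed
    A/C/G/T frequencies at position i.  No small-sample correction and no
    pseudocounts are applied.
    """
    if not windows:
        raise ValueError("no windows given")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must all have the same length")
    counts = np.zeros((length, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for w in windows:
        for i, ch in enumerate(w.upper()):
            if ch in base_idx:
                counts[i, base_idx[ch]] += 1
    totals = counts.sum(axis=1)
    info = np.full(length, np.nan)
    for i in range(length):
        if totals[i] == 0:
            continue
        f = counts[i] / totals[i]
        nz = f[f > 0]
        info[i] = 2.0 + float((nz * np.log2(nz)).sum())
    positions = [i - motif_offset for i in range(length)]
    return LogoMatrix(positions, counts, info)


def consensus(matrix: LogoMatrix, threshold: float = 0.25) -> str:
    """Minimal IUPAC code per position covering all bases at frequency
    >= ``threshold``; positions with no qualifying base (or no data) give N."""
    freqs = matrix.frequencies()
    out = []
    for row in freqs:
        if np.isnan(row).any():
            out.append("N")
            continue
        bases = frozenset(_BASES[i] for i in range(4) if row[i] >= threshold)
        out.append(_IUPAC.get(bases, "N") if bases else "N")
    return "".join(out)


def compare_expression(
    fpkm_prf: Sequence[float],
    fpkm_other: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided two-sample t-test on expression values (Welch by default).

    Returns (t statistic, p value, (mean_prf, mean_other)).  When both groups
    have zero variance and equal means the test is vacuous: t = 0, p = 1.
    """
    x = np.asarray(fpkm_prf, dtype=float)
    y = np.asarray(fpkm_other, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    means = (float(x.mean()), float(y.mean()))
    if x.var() == 0 and y.var() == 0:
        if means[0] == means[1]:
            return 0.0, 1.0, means
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), means
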