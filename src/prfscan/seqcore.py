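"""Sequence primitives: alphabets, genetic codes, translation, ORFs, FASTA I/O.

Everything downstream (homology search, frameshift detection, codon statistics)
is built on these types.  The module houses the Euplotid nuclear genetic code
(NCBI translation table 10), in which UGA is reassigned to cysteine and only
UAA/UAG terminate translation -- the property that makes the "slippery stop"
arrangement of *Euplotes* +1 frameshift genes possible in the first place.

Coordinate conventions: 0-based half-open internally; reading frames are
offsets {0, 1, 2} on the forward strand.  Report files use 1-based inclusive
coordinates (BLAST convention) and convert at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "NucleotideSequence",
    "ProteinSequence",
    "GeneticCode",
    "OpenReadingFrame",
    "STANDARD_CODE",
    "EUPLOTID_CODE",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate",
    "translate_str",
    "find_orfs",
    "longest_orf",
]

_DNA_RE = re.compile(r"^[ACGTN]+$")
# 20 standard amino acids + X (unknown) + * (stop)
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over {A,C,G,T,N}, uppercase-normalized (U mapped to T)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"{self.id}: empty sequence")
        if not _DNA_RE.match(norm):
            bad = sorted(set(norm) - set("ACGTN"))
            raise ValueError(f"{self.id}: illegal DNA residue(s) {bad}")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence.

    ``allow_internal_stops`` relaxes the terminal-only '*' rule; translations of
    full frames (no early termination) legitimately contain internal stops,
    whereas subject proteins loaded from FASTA must not.
    """

    id: str
    residues: str
    description: str = ""
    allow_internal_stops: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        norm = self.residues.upper()
        if not norm:
            raise ValueError(f"{self.id}: empty sequence")
        bad = sorted(set(norm) - _PROTEIN_CHARS)
        if bad:
            raise ValueError(f"{self.id}: illegal protein residue(s) {bad}")
        if not self.allow_internal_stops and "*" in norm[:-1]:
            raise ValueError(f"{self.id}: internal stop codon in protein sequence")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


# Codons enumerated in TCAG order (the NCBI convention for the AA strings below).
_BASES = "TCAG"
_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
_STANDARD_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


@dataclass(frozen=True)
class GeneticCode:
    """Total map from the 64 codons to amino acids, stops encoded as '*'."""

    name: str
    codon_map: dict

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError("codon_map must cover all 64 codons")

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_map.items() if aa == "*")

    def __getitem__(self, codon: str) -> str:
        return self.codon_map[codon]


def _standard_code() -> GeneticCode:
    return GeneticCode("standard", dict(zip(_CODONS, _STANDARD_AAS)))


def _euplotid_code() -> GeneticCode:
    # NCBI translation table 10 semantics: UGA -> Cys; only UAA/UAG terminate.
    cmap = dict(zip(_CODONS, _STANDARD_AAS))
    cmap["TGA"] = "C"
    return GeneticCode("euplotid", cmap)


STANDARD_CODE = _standard_code()
EUPLOTID_CODE = _euplotid_code()


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _iter_fasta(path: Path) -> Iterator[tuple[str, str, str, int]]:
    """Yield (id, description, residues, header_line_number) per record."""
    header = None
    desc = ""
    chunks: list[str] = []
    header_line = 0
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, desc, "".join(chunks), header_line
                token = line[1:].strip()
                if not token:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                parts = token.split(None, 1)
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.strip())
        if header is not None:
            yield header, desc, "".join(chunks), header_line


def read_fasta(path, alphabet: str = "dna") -> list:
    """Read a FASTA file into sequence records.

    Parameters
    ----------
    path : path-like
    alphabet : {"dna", "protein"}

    Ids must be unique; lowercase and U are normalized on input.  Errors are
    reported with the line number of the offending record header.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records = []
    seen: dict[str, int] = {}
    for rec_id, desc, residues, lineno in _iter_fasta(path):
        if rec_id in seen:
            raise FastaFormatError(
                f"{path}:{lineno}: duplicate id {rec_id!r} "
                f"(first seen at line {seen[rec_id]})"
            )
        seen[rec_id] = lineno
        try:
            if alphabet == "dna":
                records.append(NucleotideSequence(rec_id, residues, desc))
            else:
                records.append(ProteinSequence(rec_id, residues, desc))
        except ValueError as exc:
            raise FastaFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            res = rec.residues
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Basic operations
# ---------------------------------------------------------------------------

def reverse_complement(s):
    """Reverse complement; accepts a NucleotideSequence or a plain string."""
    if isinstance(s, NucleotideSequence):
        return NucleotideSequence(
            s.id, s.residues.translate(_COMPLEMENT)[::-1], s.description
        )
    return s.translate(_COMPLEMENT)[::-1]


def translate_str(
    seq: str, frame: int = 0, code: GeneticCode = EUPLOTID_CODE,
    to_first_stop: bool = False,
) -> str:
    """Translate a raw DNA string from ``frame``; codons containing N give X.

    Trailing 1-2 nt are ignored.  With ``to_first_stop`` the translation halts
    after the first stop, which is emitted as '*'.  Ambiguous codons (any N)
    never count as stops.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if frame >= len(seq):
        raise ValueError("frame beyond end of sequence")
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = code[codon]
        out.append(aa)
        if aa == "*" and to_first_stop:
            break
    if not out:
        raise ValueError("empty effective sequence after applying frame")
    return "".join(out)


def translate(
    s: NucleotideSequence, frame: int = 0, code: GeneticCode = EUPLOTID_CODE,
    to_first_stop: bool = False,
) -> ProteinSequence:
    aa = translate_str(s.residues, frame, code, to_first_stop)
    return ProteinSequence(
        f"{s.id}|frame{frame}", aa, allow_internal_stops=not to_first_stop
    )


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpenReadingFrame:
    """A maximal stop-to-stop (or sequence-edge) stretch in one forward frame.

    ``end`` includes the terminating stop codon when ``terminated`` is True, so
    (end - start) is always divisible by 3 and the protein excludes the stop.
    """

    seq_id: str
    frame: int
    start: int
    end: int
    protein: ProteinSequence
    terminated: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span not divisible by 3")


def find_orfs(
    s: NucleotideSequence,
    code: GeneticCode = EUPLOTID_CODE,
    min_aa: int = 1,
    frames: Sequence[int] = (0, 1, 2),
    require_atg: bool = False,
) -> list[OpenReadingFrame]:
    """Enumerate maximal open reading frames in the forward frames.

    ORFs run stop-to-stop; stretches abutting the sequence edges are reported
    as unterminated.  ``require_atg`` trims each ORF to its first in-frame ATG
    (dropping it when none exists).  Codons containing N translate to X and
    never terminate an ORF.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(s.residues)
    stops = code.stop_codons
    orfs: list[OpenReadingFrame] = []
    for frame in frames:
        start = frame
        pos = frame
        while pos + 3 <= n:
            codon = s.residues[pos : pos + 3]
            if codon in stops and "N" not in codon:
                _maybe_add(orfs, s, code, frame, start, pos + 3, True,
                           min_aa, require_atg)
                start = pos + 3
            pos += 3
        if pos > start:  # unterminated tail of full codons
            _maybe_add(orfs, s, code, frame, start, pos, False, min_aa, require_atg)
    return orfs


def _maybe_add(orfs, s, code, frame, start, end, terminated, min_aa, require_atg):
    if require_atg:
        cursor = start
        stop_len = 3 if terminated else 0
        while cursor < end - stop_len and s.residues[cursor : cursor + 3] != "ATG":
            cursor += 3
        if cursor >= end - stop_len:
            return
        start = cursor
    aa_span = (end - start) // 3 - (1 if terminated else 0)
    if aa_span < min_aa:
        return
    coding_end = end - 3 if terminated else end
    if coding_end <= start:
        return
    prot = translate_str(s.residues[start:coding_end], 0, code)
    orfs.append(
        OpenReadingFrame(
            s.id, frame, start, end,
            ProteinSequence(f"{s.id}|orf{frame}:{start}", prot,
                            allow_internal_stops=True),
            terminated,
        )
    )


def longest_orf(
    s: NucleotideSequence,
    code: GeneticCode = EUPLOTID_CODE,
    min_aa: int = 1,
    **kw,
) -> OpenReadingFrame | None:
    """Longest ORF; ties broken by smaller start, then smaller frame."""
    orfs = find_orfs(s, code, min_aa, **kw)
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-len(o.protein.residues), o.start, o.frame))
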