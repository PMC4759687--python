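"""Run orchestration and report writing.

Ties the stages together: synthetic data (or user FASTA) -> homology search ->
frameshift detection -> stop-codon statistics -> QC, and writes the TSV/JSON
reports.  Data files never contain timestamps, so reruns on identical inputs
are byte-identical and diffable; timestamps live only in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from . import assembly_qc, codon_stats, prf_detect, synthetic_data
from .homology import TranslatedHit
from .prf_detect import PipelineConfig, PrfCall
from .seqcore import EUPLOTID_CODE, NucleotideSequence, read_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "write_calls_tsv",
    "run_qc",
    "run_detection",
    "run_stats",
    "run_all",
]

_CALL_COLS = [
    "transcript_id", "subject_id", "status", "stop_pos_1based", "p_codon",
    "stop_codon", "tetra", "motif_class", "is_novel_motif", "fs_extension_aa",
    "upstream_evalue", "downstream_evalue", "frame_delta", "n_sites",
]


def write_calls_tsv(calls: Sequence[PrfCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLS) + "\n")
        for c in sorted(calls, key=lambda c: c.transcript_id):
            site = c.site
            row = [
                c.transcript_id, c.subject_id, c.status,
                str(site.stop_pos + 1) if site else "",
                site.p_codon if site else "",
                site.stop_codon if site else "",
                site.tetra if site else "",
                site.motif_class if site else "",
                str(int(c.is_novel_motif)),
                str(c.fs_extension_aa),
                f"{c.candidate.upstream.evalue:.3g}",
                f"{c.candidate.downstream.evalue:.3g}",
                str(c.candidate.frame_delta),
                str(c.n_sites),
            ]
            fh.write("\t".join(row) + "\n")


def run_qc(contigs: Sequence[NucleotideSequence], outdir,
           short_threshold: int = 500) -> assembly_qc.AssemblyStats:
    """Telomere classification + assembly metrics; writes per-contig TSV and a
    JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = [assembly_qc.detect_telomeres(c) for c in contigs]
    stats = assembly_qc.assembly_stats(contigs, annotations, short_threshold)
    with open(outdir / "qc_contigs.tsv", "w") as fh:
        fh.write("contig_id\tlength\tgc\ttelomere_class\n")
        for c, a in zip(contigs, annotations):
            gc = c.residues.count("G") + c.residues.count("C")
            acgt = sum(c.residues.count(b) for b in "ACGT")
            fh.write(f"{c.id}\t{len(c)}\t{gc / acgt if acgt else 0:.4f}"
                     f"\t{a.telomere_class}\n")
    summary = {
        "Contigs (n)": stats.n_contigs,
        "N50 (bp)": stats.n50,
        "Mean contig length (bp)": round(stats.mean_len, 1),
        "Max contig length (bp)": stats.max_len,
        "GC content (fraction)": round(stats.gc_fraction, 4),
        "Number of 2-telomere contigs (n)": stats.class_counts["2-telomere"],
        "Number of 1-telomere contigs (n)": stats.class_counts["1-telomere"],
        "Number of 0-telomere contigs (n)": stats.class_counts["0-telomere"],
        "Number of multi-telomere contigs": stats.class_counts["multi-telomere"],
        "2-telomere contig percentage (%)": round(stats.pct_2_telomere, 1),
        "Number of shorter nanochromosomes (length<=500 bp)": stats.n_short,
    }
    with open(outdir / "qc_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stats


def run_detection(
    transcripts, proteins=None, hits: Sequence[TranslatedHit] | None = None,
    config: PipelineConfig | None = None, outdir=None,
    junctions: Mapping | None = None,
):
    """Run the detection pipeline and write calls.tsv + run_summary.json."""
    calls, summary = prf_detect.run_prf_pipeline(
        transcripts, proteins, hits, config, junctions=junctions
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_calls_tsv(calls, outdir / "calls.tsv")
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return calls, summary


def run_stats(
    transcripts: Sequence[NucleotideSequence],
    calls: Sequence[PrfCall],
    outdir=None,
    fpkm: Mapping[str, float] | None = None,
) -> dict:
    """Stop-codon usage, Fisher test, logo consensus and the FPKM comparison."""
    confirmed = [c for c in calls if c.status == "confirmed"]
    prf_ids = {c.transcript_id for c in confirmed}
    tx_map = {t.id: t for t in transcripts}

    slippery_positions = []
    windows = []
    for c in confirmed:
        for site in [c.site] + c.extra_sites:
            slippery_positions.append((c.transcript_id, site.stop_pos))
            windows.append(site.window)
    normal_positions = codon_stats.normal_stop_positions(
        transcripts, EUPLOTID_CODE, exclude_ids=prf_ids
    )
    normal = codon_stats.count_stop_usage(normal_positions, tx_map, "normal")
    slippery = codon_stats.count_stop_usage(slippery_positions, tx_map, "slippery")
    fisher_p = None
    if normal.n and slippery.n:
        fisher_p = codon_stats.fisher_exact_two_sided(
            codon_stats.stop_usage_contingency(normal, slippery)
        )

    out: dict = {
        "normal": _usage_dict(normal),
        "slippery": _usage_dict(slippery),
        "fisher_p_taa_vs_tag": fisher_p,
    }
    logo = None
    if windows:
        logo = codon_stats.logo_from_windows(windows)
        out["consensus"] = codon_stats.consensus(logo)
    if fpkm is not None and confirmed:
        prf_vals = [fpkm[i] for i in sorted(prf_ids) if i in fpkm]
        other_vals = [fpkm[i] for i in sorted(fpkm) if i not in prf_ids]
        if len(prf_vals) >= 2 and len(other_vals) >= 2:
            t_stat, p, means = codon_stats.compare_expression(prf_vals, other_vals)
            out["expression"] = {
                "t_statistic": t_stat, "p_value": p,
                "mean_fpkm_prf": means[0], "mean_fpkm_other": means[1],
            }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_usage_tsv(normal, slippery, outdir / "stop_usage.tsv")
        if logo is not None:
            _write_logo_tsv(logo, outdir / "logo_matrix.tsv")
        with open(outdir / "stats.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out


def _usage_dict(table: codon_stats.StopUsageTable) -> dict:
    return {
        "n": table.n,
        "tri_counts": dict(sorted(table.tri_counts.items())),
        "tetra_counts": {f"{s}-{n}": c for (s, n), c in
                         sorted(table.tetra_counts.items())},
        "n_excluded_no_context": table.n_excluded_no_context,
    }


def _write_usage_tsv(normal, slippery, path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tstop\tnext_nt\tcount\tfrequency\n")
        for table in (normal, slippery):
            for stop in ("TAA", "TAG"):
                fh.write(f"{table.class_label}\t{stop}\t.\t"
                         f"{table.tri_counts.get(stop, 0)}\t"
                         f"{table.tri_fraction(stop):.4f}\n")
            for (stop, nxt), count in sorted(table.tetra_counts.items()):
                fh.write(f"{table.class_label}\t{stop}\t{nxt}\t{count}\t"
                         f"{table.tetra_fraction(stop, nxt):.4f}\n")


def _write_logo_tsv(logo, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tinfo_bits\n")
        for pos, row, bits in zip(logo.positions, logo.counts, logo.info_bits):
            bits_s = "" if bits != bits else f"{bits:.4f}"  # NaN -> empty
            fh.write(f"{pos}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t{bits_s}\n")


def run_all(data_dir, outdir, config: PipelineConfig | None = None) -> dict:
    """Full pipeline over a dataset directory (as written by the synthetic
    generator, or user-provided files with the same names).

    Expects transcripts.fasta and proteins.fasta; contigs.fasta,
    expression.tsv and truth.tsv are optional.  Returns the combined summary
    (also written as run_summary.json).
    """
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = read_fasta(data_dir / "transcripts.fasta", "dna")
    if not transcripts:
        raise ValueError("no transcripts in input")
    proteins = read_fasta(data_dir / "proteins.fasta", "protein")
    logger.info("loaded %d transcripts, %d proteins", len(transcripts),
                len(proteins))

    calls, summary = run_detection(transcripts, proteins, None, config, outdir)
    fpkm = None
    expr_path = data_dir / "expression.tsv"
    if expr_path.exists():
        fpkm = {}
        with open(expr_path) as fh:
            fh.readline()
            for line in fh:
                tid, val = line.split("\t")
                fpkm[tid] = float(val)
    stats = run_stats(transcripts, calls, outdir, fpkm)
    summary = {"detection": summary, "stats": stats}

    contig_path = data_dir / "contigs.fasta"
    if contig_path.exists():
        qc = run_qc(read_fasta(contig_path, "dna"), outdir)
        summary["qc"] = {"n50": qc.n50, "pct_2_telomere": qc.pct_2_telomere}

    truth_path = data_dir / "truth.tsv"
    if truth_path.exists():
        truth = synthetic_data.load_truth(truth_path)
        metrics = synthetic_data.evaluate_recovery(calls, truth)
        summary["recovery"] = {
            k: v for k, v in dataclasses.asdict(metrics).items()
            if k != "motif_confusion"
        }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
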