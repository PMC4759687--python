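#!/usr/bin/env python
"""Stop-codon usage and slippery-site statistics from the detection output.

Consumes calls.tsv from the detection step (plus the transcript FASTA and the
expression table) and computes: tri- and tetranucleotide stop usage for the
slippery vs normal classes, the Fisher exact test on UAA/UAG usage, the
positional information content of the +-30 nt windows around the slippery
motifs with their IUPAC consensus, and the FPKM comparison between
frameshifted and normal genes (Welch t-test).
"""

import argparse
import json
from pathlib import Path

from prfscan.codon_stats import (
    compare_expression,
    consensus,
    count_stop_usage,
    fisher_exact_two_sided,
    logo_from_windows,
    normal_stop_positions,
    stop_usage_contingency,
)
from prfscan.prf_detect import site_at
from prfscan.seqcore import read_fasta


def load_confirmed_sites(calls_tsv, tx_map):
    """(transcript_id, stop position) pairs for confirmed calls, re-deriving
    each site record from the transcript sequence."""
    sites = []
    with open(calls_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {k: i for i, k in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[idx["status"]] != "confirmed":
                continue
            tid = f[idx["transcript_id"]]
            pos = int(f[idx["stop_pos_1based"]]) - 1
            sites.append(site_at(tx_map[tid], pos))
    return sites


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path,
                    default=Path("results/synthetic"))
    ap.add_argument("--calls", type=Path,
                    default=Path("results/detection/calls.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    transcripts = read_fasta(args.data_dir / "transcripts.fasta", "dna")
    tx_map = {t.id: t for t in transcripts}
    sites = load_confirmed_sites(args.calls, tx_map)
    prf_ids = {s.transcript_id for s in sites}

    slippery = count_stop_usage(
        [(s.transcript_id, s.stop_pos) for s in sites], tx_map, "slippery"
    )
    normal = count_stop_usage(
        normal_stop_positions(transcripts, exclude_ids=prf_ids),
        tx_map, "normal",
    )
    fisher_p = fisher_exact_two_sided(stop_usage_contingency(normal, slippery))

    logo = logo_from_windows([s.window for s in sites])
    cons = consensus(logo)

    out = {
        "n_slippery_stops": slippery.n,
        "n_normal_stops": normal.n,
        "slippery_UAA_pct": round(100 * slippery.tri_fraction("TAA"), 1),
        "normal_UAA_pct": round(100 * normal.tri_fraction("TAA"), 1),
        "slippery_UAA-A_pct": round(
            100 * slippery.tetra_fraction("TAA", "A"), 1),
        "normal_UAA-A_pct": round(100 * normal.tetra_fraction("TAA", "A"), 1),
        "fisher_p_UAA_usage": fisher_p,
        "consensus_around_motif": cons,
        "consensus_motif_positions": cons[30:36],
    }

    expr_path = args.data_dir / "expression.tsv"
    if expr_path.exists():
        fpkm = {}
        with open(expr_path) as fh:
            fh.readline()
            for line in fh:
                tid, val = line.split("\t")
                fpkm[tid] = float(val)
        prf_vals = [fpkm[i] for i in sorted(prf_ids) if i in fpkm]
        other_vals = [v for k, v in sorted(fpkm.items()) if k not in prf_ids]
        t_stat, p, (m_prf, m_other) = compare_expression(prf_vals, other_vals)
        out["mean_FPKM_prf"] = round(m_prf, 2)
        out["mean_FPKM_normal"] = round(m_other, 2)
        out["fpkm_t_test_p"] = p

    with open(args.outdir / "stats.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(json.dumps(out, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
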