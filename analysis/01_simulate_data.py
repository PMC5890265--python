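"""Build the synthetic study data set.

Generates the demo genome (200 kb, 20 genes, four planted retroelement
families including a DNMT-bearing LINE and DIRS), the per-site truth
methylome (mCG 0.7, mCH 0.01 with a 5x 3' bias on elements), and 30x
pre-aligned bisulfite reads with a 0.5% non-conversion error and an
unmethylated spike-in contig. Outputs land in results/simulated/.
"""

import argparse
import os

from temeth import simulate
from temeth.experiments import demo_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/simulated")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    cfg = demo_config(args.seed)
    sim = simulate.simulate_genome(cfg)
    truth = simulate.simulate_truth_methylome(sim.sample_genome, sim.features,
                                              cfg)
    reads = simulate.simulate_bisulfite_reads(sim.sample_genome, truth, cfg)

    simulate.write_fasta(sim.genome, f"{args.out}/genome.fa")
    simulate.write_gff3(sim.features, f"{args.out}/features.gff3")
    simulate.write_bed(sim.features, f"{args.out}/features.bed")
    simulate.write_expression_tsv(sim.features, f"{args.out}/expression.tsv")
    simulate.write_truth_tsv(truth, f"{args.out}/truth_methylome.tsv")
    simulate.write_sam(reads, sim.sample_genome, f"{args.out}/reads.sam")

    n_te = (sim.features["kind"] == "TE").sum()
    print(f"genome: {sum(len(s) for s in sim.genome.values()):,} bp over "
          f"{len(sim.genome)} contigs; {cfg.n_genes} genes, {n_te} TE copies "
          f"({len(cfg.te_families)} families); {len(reads):,} reads "
          f"-> {args.out}/")


if __name__ == "__main__":
    main()
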