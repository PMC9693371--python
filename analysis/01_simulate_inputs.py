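"""Generate the synthetic study inputs: a 200-gene genome with planted MYB
repeats and promoter elements, tissue count matrices with a planted
flavonoid-correlated module, and a qPCR Ct table from planted fold changes.

Writes scratch/simulated/ (genome.fasta, annotation.gff3, proteome.fasta,
cds.fasta, truth.json, counts.tsv, lengths.tsv, library_sizes.tsv, ct.tsv);
the downstream numbered scripts read from there and write their summary
tables under results/.
"""

import json
import os

from familyscan.synthetic_data import (generate_expression, generate_genome,
                                       generate_qpcr)

SEED = 7
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "simulated")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    genome = generate_genome(n_chrom=6, n_genes=200,
                             repeat_spec={"1R": 21, "R2R3": 60, "3R": 4},
                             seed=SEED)
    paths = genome.write(OUT)
    spec = genome.truth["subfamily_counts"]
    print(f"genome: 6 chromosomes, 200 genes "
          f"({spec['1R']} 1R + {spec['R2R3']} R2R3 + {spec['3R']} 3R planted, "
          f"{genome.truth['n_decoys']} decoys) -> {paths['genome']}")

    expr = generate_expression(n_genes=121, seed=SEED)
    with open(os.path.join(OUT, "expression_truth.json"), "w") as fh:
        json.dump(expr["truth"], fh, indent=1, sort_keys=True)
    expr["counts"].to_csv(os.path.join(OUT, "counts.tsv"), sep="\t")
    expr["lengths"].to_frame().to_csv(os.path.join(OUT, "lengths.tsv"), sep="\t")
    expr["library_sizes"].to_frame().to_csv(
        os.path.join(OUT, "library_sizes.tsv"), sep="\t")
    print(f"expression: 121 family genes + {len(expr['truth']['pathway'])} pathway "
          f"genes x 7 tissues, {len(expr['truth']['zero_genes'])} planted silent, "
          f"{len(expr['truth']['partners'])} correlated partners")

    folds = {"MYB17": {"R": 0.25, "LE": 3.0, "BA": 2.0},
             "MYB18": {"R": 0.5, "LE": 1.5, "BA": 4.0},
             "MYB20": {"R": 0.2, "LE": 6.0, "BA": 0.8},
             "MYB52": {"R": 0.3, "LE": 0.6, "BA": 3.0}}
    ct = generate_qpcr(list(folds), ["STT", "R", "LE", "BA"], folds,
                       noise_sd=0.05, seed=SEED)
    ct.to_csv(os.path.join(OUT, "ct.tsv"), sep="\t", index=False)
    print(f"qPCR: {len(folds)} genes x 4 samples x 3 replicates, stem calibrator")


if __name__ == "__main__":
    main()
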