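"""Tissue expression: FPKM, log2 heatmap matrix, not-expressed flags,
tissue-of-maximum calls, and Pearson correlation (with stars) of the family
genes against the flavonoid-pathway structural genes.

Writes results/expression_log2fpkm.tsv and results/correlations.tsv.
"""

import json
import os

import pandas as pd

from familyscan.expression import (PATHWAY_GENES, correlate_with_pathway,
                                   fpkm, heatmap_matrix, tissue_max_calls)

HERE = os.path.dirname(__file__)
SIM = os.path.join(HERE, "..", "scratch", "simulated")
OUT = os.path.join(HERE, "..", "results")


def main() -> None:
    counts = pd.read_csv(os.path.join(SIM, "counts.tsv"), sep="\t", index_col=0)
    lengths = pd.read_csv(os.path.join(SIM, "lengths.tsv"), sep="\t",
                          index_col=0).iloc[:, 0]
    libs = pd.read_csv(os.path.join(SIM, "library_sizes.tsv"), sep="\t",
                       index_col=0).iloc[:, 0]
    mat = fpkm(counts, lengths, libs)
    log_mat, not_expr = heatmap_matrix(mat)
    log_mat.round(4).to_csv(os.path.join(OUT, "expression_log2fpkm.tsv"), sep="\t")
    print(f"{int(not_expr.sum())} genes not expressed in any tissue: "
          f"{', '.join(not_expr[not_expr].index)}")

    myb_rows = [g for g in log_mat.index if g not in PATHWAY_GENES]
    calls = tissue_max_calls(mat.loc[myb_rows].drop(index=not_expr[not_expr].index))
    print("tissue of maximal expression:",
          dict(calls.value_counts().sort_index()))

    cors = correlate_with_pathway(log_mat.loc[myb_rows],
                                  log_mat.loc[list(PATHWAY_GENES)])
    df = pd.DataFrame([{"myb": c.myb_id, "pathway_gene": c.pathway_gene,
                        "r": round(c.r, 3), "p": c.p, "stars": c.stars}
                       for c in cors])
    df.to_csv(os.path.join(OUT, "correlations.tsv"), sep="\t", index=False)
    sig = df[df["stars"] != ""]
    print(f"{len(sig)}/{len(df)} correlations significant at p<0.05; "
          f"{(df['stars'] == '***').sum()} at p<0.001")

    truth = json.load(open(os.path.join(SIM, "expression_truth.json")))
    planted = {(m, pg) for m, pg, _ in truth["partners"]}
    hit = sum(1 for _, row in sig.iterrows()
              if (row["myb"], row["pathway_gene"]) in planted)
    print(f"planted correlated module: {hit}/{len(planted)} partner pairs "
          f"significant at p<0.05")


if __name__ == "__main__":
    main()
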