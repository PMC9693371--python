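"""Domain-anchored phylogeny with bootstrap, subgroup assignment against the
packaged anchor panel, repeat logos and conserved-tryptophan report, and the
bHLH-interaction motif scan.

Writes results/tree.nwk, results/subgroups.tsv, results/logo.tsv.
"""

import os
from importlib import resources

import pandas as pd

from familyscan.domain_scan import classify_proteome, load_packaged_pssm
from familyscan.io_formats import read_fasta
from familyscan.motif_logo import (column_information, conserved_positions,
                                   scan_bhlh_motif)
from familyscan.phylogeny import (DomainAlignment, assign_subgroups,
                                  bootstrap_support, build_domain_alignment)

HERE = os.path.dirname(__file__)
SIM = os.path.join(HERE, "..", "scratch", "simulated")
OUT = os.path.join(HERE, "..", "results")
DATA = resources.files("familyscan") / "data"


def main() -> None:
    proteins = read_fasta(os.path.join(SIM, "proteome.fasta"))
    pssm = load_packaged_pssm()
    classified = classify_proteome(proteins, pssm)
    hits_by = {c.protein_id: c.hits for c in classified if c.hits}
    seqs = {p.id: p.residues for p in proteins}
    aln = build_domain_alignment(hits_by, seqs, pssm)

    # splice the packaged anchors (two-repeat domain sequences) into the
    # alignment so queries can inherit their subgroup labels
    with resources.as_file(DATA / "subgroup_anchors.synthetic.fasta") as p:
        anchors = read_fasta(p)
    labels = pd.read_csv(str(DATA / "subgroup_anchors.synthetic.tsv"), sep="\t")
    anchor_labels = dict(zip(labels["id"], labels["subgroup"]))
    rows, ids = list(aln.rows), list(aln.ids)
    for rec in anchors:
        row = rec.residues[: aln.n_columns]
        rows.append(row + "-" * (aln.n_columns - len(row)))
        ids.append(rec.id)
    aln = DomainAlignment(ids=ids, rows=rows)

    tree = bootstrap_support(aln, n_reps=100, seed=7)
    with open(os.path.join(OUT, "tree.nwk"), "w") as fh:
        fh.write(tree.newick() + "\n")
    assignments = assign_subgroups(tree, anchor_labels)
    sg = pd.DataFrame([{"protein_id": a.protein_id, "subgroup": a.subgroup,
                        "anchor": a.anchor_id} for a in assignments])
    sg.to_csv(os.path.join(OUT, "subgroups.tsv"), sep="\t", index=False)
    print(f"tree: {len(aln.ids)} leaves ({len(anchors)} anchors); query "
          f"subgroup assignments: {dict(sg['subgroup'].value_counts())}")

    cols = column_information(aln)
    pd.DataFrame([{"position": c.position, "ic_bits": round(c.ic_bits, 4),
                   "top_residue": c.top_residue,
                   "top_fraction": round(c.top_fraction, 3)}
                  for c in cols if not c.all_gap]).to_csv(
        os.path.join(OUT, "logo.tsv"), sep="\t", index=False)
    rep = conserved_positions(aln, min_fraction=0.85, repeat_name="R2R3")
    ws = [p for p, res, _ in rep.conserved_positions if res == "W"]
    in_repeat = sorted({(p - 1) % pssm.width + 1 for p in ws})
    print(f"conserved tryptophans (>=85% of rows) at alignment positions {ws} "
          f"= repeat positions {in_repeat}")

    n_motif = sum(bool(scan_bhlh_motif(p.residues, protein_id=p.id))
                  for p in proteins)
    print(f"bHLH-interaction motif present in {n_motif}/{len(proteins)} proteins")


if __name__ == "__main__":
    main()
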