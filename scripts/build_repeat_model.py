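"""Regenerate the packaged repeat model data files.

Writes, deterministically:
  src/familyscan/data/myb_repeat_alignment.synthetic.fasta
  src/familyscan/data/myb_repeat_pssm.json
  src/familyscan/data/subgroup_anchors.synthetic.fasta
  src/familyscan/data/subgroup_anchors.synthetic.tsv

The alignment is a constructed (synthetic) stand-in for a curated MYB
helix-turn-helix repeat alignment: 30 ungapped 52-column rows around a
fixed consensus with conserved tryptophans at repeat positions 2, 22 and
42 (the spacing characteristic of plant R2 repeats). The PSSM is built
from it with +0.5 pseudocounts over a uniform background and calibrated on
shuffled decoys (threshold quantile 1 - 1e-5, Gumbel fit for E-values).
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from familyscan.domain_scan import build_pssm, calibrate_pssm  # noqa: E402
from familyscan.io_formats import SequenceRecord, write_fasta  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "src" / "familyscan" / "data"

CONSENSUS = (
    "EWTEEEDKLLREAVEKYGPHNWRAIASHLPGRTDNEIKNYWNTRLKRKLER"
)
# column 2, 22, 42 (1-based) are the conserved tryptophans
assert len(CONSENSUS) == 51
CONSENSUS = CONSENSUS[:41] + "W" + CONSENSUS[41:]  # pad to width 52 keeping W-42
assert len(CONSENSUS) == 52
assert CONSENSUS[1] == "W" and CONSENSUS[21] == "W" and CONSENSUS[41] == "W"

# chemically plausible alternatives per consensus letter
ALTERNATIVES = {
    "A": "STG", "C": "SA", "D": "EN", "E": "DQ", "F": "YLW", "G": "AS",
    "H": "NQY", "I": "LVM", "K": "RQ", "L": "IMV", "M": "LI", "N": "DSH",
    "P": "AS", "Q": "EKN", "R": "KQ", "S": "TAN", "T": "SA", "V": "ILA",
    "W": "F", "Y": "FH",
}


def main() -> None:
    rng = np.random.default_rng(20260901)
    rows = []
    for i in range(30):
        seq = []
        for j, aa in enumerate(CONSENSUS):
            conserved_w = j in (1, 21, 41)
            keep_p = 0.97 if conserved_w else 0.70
            if rng.random() < keep_p:
                seq.append(aa)
            else:
                seq.append(ALTERNATIVES[aa][int(rng.integers(0, len(ALTERNATIVES[aa])))])
        rows.append(SequenceRecord(f"rep{i + 1:02d}", "".join(seq)))
    aln_path = DATA / "myb_repeat_alignment.synthetic.fasta"
    write_fasta(rows, aln_path)

    pssm = build_pssm(rows)
    pssm = calibrate_pssm(pssm, seed=20260901, n_decoys=600, decoy_len=500)
    payload = {
        "width": pssm.width,
        "log_odds": np.round(pssm.log_odds, 6).tolist(),
        "probs": np.round(pssm.probs, 6).tolist(),
        "background": pssm.background.tolist(),
        "bit_threshold": round(pssm.bit_threshold, 6),
        "gumbel": [round(x, 6) for x in pssm.gumbel],
        "alphabet": "ACDEFGHIKLMNPQRSTVWY",
        "source": "built from myb_repeat_alignment.synthetic.fasta (synthetic stand-in)",
    }
    (DATA / "myb_repeat_pssm.json").write_text(json.dumps(payload) + "\n")
    print(f"width={pssm.width} threshold={pssm.bit_threshold:.2f} gumbel={pssm.gumbel}")

    # anchor panel: labelled reference proteins for subgroup assignment
    from familyscan.synthetic_data import generate_reference_panel

    labels = [f"C{i}" for i in (1, 2, 5, 7, 17, 20, 22, 27)]
    panel = generate_reference_panel(labels, per_label=2, n_queries_per_label=0,
                                     seed=20260901)
    write_fasta(panel["anchors"], DATA / "subgroup_anchors.synthetic.fasta")
    with open(DATA / "subgroup_anchors.synthetic.tsv", "w") as fh:
        fh.write("id\tsubgroup\n")
        for sid, lab in panel["anchor_labels"].items():
            fh.write(f"{sid}\t{lab}\n")
    print(f"wrote {len(panel['anchors'])} anchors for {len(labels)} subgroups")


if __name__ == "__main__":
    main()
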