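"""Sequence-logo information content, conserved residues, bHLH motif scan.

Information content per column is log2(20) minus the Shannon entropy of the
observed residue frequencies (gaps ignored), i.e. the bit height a logo
would draw, with no small-sample correction. The conserved-residue report
lists positions whose modal residue reaches a fraction threshold, with the
substitution sets at near-conserved positions — the view used to read off
the canonical tryptophan ladder of MYB repeats. The bHLH-interaction motif
scanner matches the [L-x5-L-x6-L-x3-R] spacing pattern (and a stricter
canonical variant) in R3 repeat sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .phylogeny import DomainAlignment, GAP

__all__ = [
    "LogoColumn",
    "ConservedResidueReport",
    "BhlhMotifHit",
    "BHLH_PATTERNS",
    "column_information",
    "conserved_positions",
    "scan_bhlh_motif",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class LogoColumn:
    position: int  # 1-based
    counts: dict[str, int]
    ic_bits: float
    top_residue: str
    top_fraction: float
    all_gap: bool = False


def column_information(alignment: DomainAlignment) -> list[LogoColumn]:
    """Per-column information content in bits.

    ic = log2(20) - H(column), H the Shannon entropy of residue frequencies
    with gaps dropped. An all-gap column is flagged and carries ic = nan.
    """
    out = []
    for j in range(alignment.n_columns):
        residues = [r[j] for r in alignment.rows if r[j] != GAP]
        if not residues:
            out.append(LogoColumn(j + 1, {}, float("nan"), GAP, 0.0, all_gap=True))
            continue
        counts: dict[str, int] = {}
        for aa in residues:
            counts[aa] = counts.get(aa, 0) + 1
        total = len(residues)
        freqs = np.array([c / total for c in counts.values()])
        entropy = float(-(freqs * np.log2(freqs)).sum())
        top = max(sorted(counts), key=lambda a: counts[a])
        out.append(
            LogoColumn(
                position=j + 1,
                counts=counts,
                ic_bits=MAX_BITS - entropy,
                top_residue=top,
                top_fraction=counts[top] / total,
            )
        )
    return out


@dataclass
class ConservedResidueReport:
    repeat_name: str
    conserved_positions: list[tuple[int, str, float]]
    substitutions: list[tuple[int, list[str]]] = field(default_factory=list)


def conserved_positions(alignment: DomainAlignment, min_fraction: float,
                        repeat_name: str = "R",
                        near_fraction: float = 0.5) -> ConservedResidueReport:
    """Positions whose modal residue fraction reaches ``min_fraction``.

    Positions below the threshold but with a modal fraction of at least
    ``near_fraction`` are reported as near-conserved, listing the observed
    substituting residues (e.g. the F/I/L/Y replacements of the first R3
    tryptophan).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    cols = column_information(alignment)
    conserved, subs = [], []
    for col in cols:
        if col.all_gap:
            continue
        if col.top_fraction >= min_fraction:
            conserved.append((col.position, col.top_residue, col.top_fraction))
        elif col.top_fraction >= near_fraction:
            others = sorted(a for a in col.counts if a != col.top_residue)
            subs.append((col.position, others))
    return ConservedResidueReport(repeat_name=repeat_name,
                                  conserved_positions=conserved,
                                  substitutions=subs)


@dataclass(frozen=True)
class BhlhMotifHit:
    protein_id: str
    start: int  # 1-based
    end: int
    matched_text: str


# Literal reading of the L-x-x/x-x-x-L-x6-L-x3-R spacing (the two leading
# spacers concatenate to 5), and the stricter canonical variant.
BHLH_PATTERNS = {
    "lx5lx6lx3r": r"L.{5}L.{6}L.{3}R",
    "canonical": r"[DE]L.{2}[RK].{2}L.{6}L.{3}R",
}


def scan_bhlh_motif(r3_sequence: str, pattern_id: str = "lx5lx6lx3r",
                    protein_id: str = "") -> list[BhlhMotifHit]:
    """All non-overlapping matches of the chosen bHLH-interaction pattern."""
    if pattern_id not in BHLH_PATTERNS:
        raise ValueError(f"unknown motif pattern {pattern_id!r}")
    pat = re.compile(BHLH_PATTERNS[pattern_id])
    hits = []
    pos = 0
    while True:
        m = pat.search(r3_sequence, pos)
        if m is None:
            break
        hits.append(BhlhMotifHit(protein_id=protein_id, start=m.start() + 1,
                                 end=m.end(), matched_text=m.group()))
        pos = m.end()
    return hits
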