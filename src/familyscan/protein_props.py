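"""Physicochemical protein properties: length, MW, pI, instability, GRAVY.

MW (average residue masses), the Guruprasad dipeptide instability index and
the Kyte-Doolittle GRAVY score use the standard ProtParam tables shipped
with Biopython. The isoelectric point is solved in-package by bisection on
the Henderson-Hasselbalch net-charge curve with the EMBOSS pKa set, which
makes the solver contract explicit: the returned pH has |net charge| < 1e-6.
ExPASy-style tools use the Bjellqvist pKa values instead, so small numeric
differences from those reports are expected.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io_formats import SequenceRecord

__all__ = [
    "PhysicoProperties",
    "molecular_weight",
    "gravy",
    "isoelectric_point",
    "net_charge",
    "instability_index",
    "compute_properties",
    "EMBOSS_PKA",
]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

# EMBOSS iep defaults: side chains + termini
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhysicoProperties:
    protein_id: str
    length: int
    mw: float
    pi: float
    instability: float
    gravy: float

    @property
    def stable(self) -> bool:
        return self.instability < 40.0


def _check(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _STANDARD
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average (not monoisotopic) molecular weight in Da, including one water."""
    return float(ProteinAnalysis(_check(seq)).molecular_weight())


def gravy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy."""
    return float(ProteinAnalysis(_check(seq)).gravy())


def instability_index(seq: str) -> float:
    """Guruprasad instability index, (10/L) * sum of dipeptide weights."""
    _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    return float(ProteinAnalysis(seq).instability_index())


def net_charge(seq: str, ph: float) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch, EMBOSS pKa set)."""
    _check(seq)
    pos = 10 ** (EMBOSS_PKA["Nterm"] - ph) / (1 + 10 ** (EMBOSS_PKA["Nterm"] - ph))
    neg = 10 ** (ph - EMBOSS_PKA["Cterm"]) / (1 + 10 ** (ph - EMBOSS_PKA["Cterm"]))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            pka = EMBOSS_PKA[aa]
            pos += n * 10 ** (pka - ph) / (1 + 10 ** (pka - ph))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            pka = EMBOSS_PKA[aa]
            neg += n * 10 ** (ph - pka) / (1 + 10 ** (ph - pka))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-6) -> float:
    """pH at which the net charge vanishes, by bisection in (0, 14).

    The charge curve is strictly decreasing in pH, so the root is unique;
    bisection runs until |charge| < tol.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def compute_properties(protein: SequenceRecord) -> PhysicoProperties:
    seq = protein.residues
    return PhysicoProperties(
        protein_id=protein.id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability=instability_index(seq),
        gravy=gravy(seq),
    )
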