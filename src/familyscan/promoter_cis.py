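"""Promoter extraction and cis-acting element census.

Promoters are the 2000 bp immediately upstream of the CDS start (−2000..−1,
strand-aware, truncated at chromosome edges). Elements are IUPAC nucleotide
patterns organized into functional categories and three groups: plant
development (PDE), stress response (SE, which houses the light-responsive
categories), and hormone response (HE). Counting is forward-strand,
overlap-inclusive, and identical to a brute-force IUPAC matcher.

The packaged element table is a compact literature-derived stand-in for a
full promoter-element database; it is versioned and user-replaceable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io_formats import GeneModel, SequenceRecord, reverse_complement

__all__ = [
    "CisElement",
    "PromoterScanResult",
    "IUPAC",
    "load_element_table",
    "packaged_element_table",
    "extract_promoter",
    "scan_elements",
    "summarize_census",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

GROUPS = ("PDE", "SE", "HE")


@dataclass(frozen=True)
class CisElement:
    name: str
    pattern: str  # IUPAC nucleotide string
    category: str
    group: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"element {self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"element {self.name}: invalid IUPAC codes {sorted(bad)}")
        if self.group not in GROUPS:
            raise ValueError(f"element {self.name}: group must be one of {GROUPS}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC[c] for c in self.pattern.upper()))


@dataclass
class PromoterScanResult:
    gene_id: str
    element_counts: dict[str, int]
    category_counts: dict[str, int] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)


def load_element_table(path) -> list[CisElement]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "pattern", "category", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"element table needs columns {sorted(required)}")
    return [CisElement(r["name"], r["pattern"], r["category"], r["group"])
            for _, r in df.iterrows()]


def packaged_element_table() -> list[CisElement]:
    ref = resources.files("familyscan") / "data" / "cis_elements.tsv"
    with resources.as_file(ref) as p:
        return load_element_table(p)


def extract_promoter(gene: GeneModel, chromosome_seq: str,
                     length: int = 2000) -> SequenceRecord:
    """The ``length`` bases upstream of the CDS start, on the coding strand.

    Plus strand: bases ending 1 bp before the first CDS base. Minus strand:
    reverse complement of the bases starting 1 bp after the last CDS base.
    Truncates (with a warning) at chromosome edges.
    """
    if not gene.cds:
        raise ValueError(f"gene {gene.id} has no CDS; promoter is CDS-anchored")
    if gene.strand == "+":
        cds_start = gene.cds[0][0]  # 1-based
        lo = max(1, cds_start - length)
        seq = chromosome_seq[lo - 1 : cds_start - 1]
    else:
        cds_end = gene.cds[-1][1]
        hi = min(len(chromosome_seq), cds_end + length)
        seq = reverse_complement(chromosome_seq[cds_end : hi])
    if len(seq) < length:
        warnings.warn(
            f"promoter of {gene.id} truncated to {len(seq)} bp at chromosome edge"
        )
    if not seq:
        raise ValueError(f"gene {gene.id}: CDS starts at the chromosome edge")
    return SequenceRecord(id=f"{gene.id}_promoter", residues=seq)


def count_pattern(seq: str, element: CisElement, both_strands: bool = False) -> int:
    """Overlap-inclusive occurrence count of one IUPAC pattern."""
    pat = element.regex()
    n = 0
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            break
        n += 1
        pos = m.start() + 1
    if both_strands:
        n += count_pattern(reverse_complement(seq), element, both_strands=False)
    return n


def scan_elements(promoter: SequenceRecord, table: list[CisElement],
                  both_strands: bool = False) -> PromoterScanResult:
    """Census one promoter against the element table (forward strand by default)."""
    element_counts = {el.name: count_pattern(promoter.residues, el, both_strands)
                      for el in table}
    category_counts: dict[str, int] = {}
    group_counts: dict[str, int] = {g: 0 for g in GROUPS}
    for el in table:
        c = element_counts[el.name]
        category_counts[el.category] = category_counts.get(el.category, 0) + c
        group_counts[el.group] += c
    gene_id = promoter.id.removesuffix("_promoter")
    return PromoterScanResult(gene_id=gene_id, element_counts=element_counts,
                              category_counts=category_counts,
                              group_counts=group_counts)


def summarize_census(results: list[PromoterScanResult],
                     table: list[CisElement]) -> pd.DataFrame:
    """Per-element totals and number of genes involved, plus group rows.

    'genes_involved' counts genes with at least one occurrence, the quantity
    behind statements like "appeared 327 times and involved 100 genes".
    """
    if not results:
        raise ValueError("no scan results to summarize")
    rows = []
    for el in table:
        counts = [r.element_counts.get(el.name, 0) for r in results]
        rows.append({
            "element": el.name, "category": el.category, "group": el.group,
            "total_occurrences": int(sum(counts)),
            "genes_involved": int(sum(1 for c in counts if c > 0)),
        })
    df = pd.DataFrame(rows)
    group_rows = (
        df.groupby("group", sort=False)["total_occurrences"].sum().rename("total_occurrences")
    )
    df.attrs["group_totals"] = group_rows.to_dict()
    return df
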