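"""Duplicate-pair detection, tandem/segmental classification, and NG86 Ka/Ks.

Candidate paralog pairs come from global protein alignment (BLOSUM62,
affine gaps) filtered on length coverage and percent identity. Codon
alignments are built by back-translating the protein alignment onto the
coding sequences. Ka and Ks follow Nei & Gojobori (1986): per-position
synonymous site fractions averaged over the two sequences, observed
differences partitioned by equal-weight averaging over all minimal
substitution pathways, and a Jukes-Cantor correction
d = -(3/4) ln(1 - 4p/3). omega = Ka/Ks is flagged undefined when Ks = 0 or
a proportion is at or past the correction's domain (p >= 3/4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import log

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import GenomeAnnotation, SequenceRecord

__all__ = [
    "PairCriteria",
    "DuplicatePair",
    "CodonAlignment",
    "align_pair",
    "find_pairs",
    "classify_mode",
    "backtranslate",
    "ng86_kaks",
    "analyze_pairs",
]

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class PairCriteria:
    """Thresholds for duplicate confirmation and paralog definition.

    ``min_coverage``/``min_identity`` implement the duplication rule
    (shorter sequence > 70% of the longer; aligned similarity > 70%);
    ``paralog_min_len``/``paralog_min_homology`` implement the looser
    paralog-pair rule (> 300 bp, homology >= 50%) used for Ka/Ks.
    """

    min_coverage: float = 0.7
    min_identity: float = 70.0
    paralog_min_len: int = 300
    paralog_min_homology: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1) or not (0 < self.min_identity <= 100):
            raise ValueError("criteria out of range")


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    mode: str = ""
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    flags: str = ""


@dataclass
class CodonAlignment:
    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")
        for row in (self.codons_a, self.codons_b):
            for c in row:
                if len(c) != 3:
                    raise ValueError(f"non-triplet cell {c!r}")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def align_pair(a: SequenceRecord, b: SequenceRecord) -> tuple[str, str, float, float]:
    """Globally align two proteins; return aligned rows, coverage, identity.

    Coverage is shorter/longer raw length. Identity is percent matches over
    aligned columns, counting internal gap columns as mismatches but
    excluding terminal overhangs.
    """
    aln = _aligner().align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim terminal overhangs (columns where either row is in a leading or
    # trailing gap run)
    def core(row: str) -> tuple[int, int]:
        start = len(row) - len(row.lstrip("-"))
        end = len(row.rstrip("-"))
        return start, end

    sa, ea = core(row_a)
    sb, eb = core(row_b)
    s, e = max(sa, sb), min(ea, eb)
    matches = sum(1 for x, y in zip(row_a[s:e], row_b[s:e]) if x == y and x != "-")
    ncols = e - s
    identity = 100.0 * matches / ncols if ncols else 0.0
    coverage = min(len(a), len(b)) / max(len(a), len(b))
    return row_a, row_b, coverage, identity


def find_pairs(proteins: list[SequenceRecord],
               criteria: PairCriteria = PairCriteria(),
               rule: str = "duplication") -> list[DuplicatePair]:
    """All unordered pairs passing the chosen filter.

    ``rule='duplication'`` applies the coverage/identity thresholds;
    ``rule='paralog'`` applies the CDS-length (3 x protein aa > 300 bp) and
    homology thresholds used for the Ka/Ks pair set. The two filters are
    deliberately separate.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    out = []
    for a, b in itertools.combinations(proteins, 2):
        _, _, cov, ident = align_pair(a, b)
        if rule == "duplication":
            keep = cov > criteria.min_coverage and ident > criteria.min_identity
        elif rule == "paralog":
            keep = (3 * min(len(a), len(b)) > criteria.paralog_min_len
                    and ident >= criteria.paralog_min_homology)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if keep:
            out.append(DuplicatePair(gene_a=a.id, gene_b=b.id,
                                     coverage=cov, identity=ident))
    return out


def classify_mode(pair: DuplicatePair, annotation: GenomeAnnotation,
                  max_intervening: int = 1, max_span_bp: int = 100_000) -> str:
    """Tandem if same-chromosome and close (few intervening genes or a short
    span); segmental otherwise."""
    genes = annotation.genes_by_id()
    try:
        ga, gb = genes[pair.gene_a], genes[pair.gene_b]
    except KeyError as exc:
        raise ValueError(f"gene {exc.args[0]} not in annotation") from None
    if ga.chromosome != gb.chromosome:
        return "segmental"
    lo, hi = sorted([ga, gb], key=lambda g: g.start)
    intervening = sum(
        1 for g in annotation.genes
        if g.chromosome == ga.chromosome and lo.end < g.start and g.end < hi.start
    )
    span = hi.end - lo.start + 1
    if intervening <= max_intervening or span <= max_span_bp:
        return "tandem"
    return "segmental"


def backtranslate(aligned_a: str, aligned_b: str,
                  cds_a: str, cds_b: str,
                  id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Map a protein alignment back onto its coding sequences.

    Each residue column becomes its codon; gaps become '---'. The CDS may
    carry one trailing stop codon. Translation mismatches error with the
    offending position.
    """
    def row_to_codons(aligned: str, cds: str, name: str) -> list[str]:
        n_res = len(aligned.replace("-", ""))
        if len(cds) == 3 * n_res + 3 and cds[-3:] in _STOPS:
            cds = cds[:-3]
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"{name}: CDS length {len(cds)} does not match {n_res} residues"
            )
        codons = []
        k = 0
        for i, aa in enumerate(aligned):
            if aa == "-":
                codons.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = _translate_codon(codon)
            if trans != aa:
                raise ValueError(
                    f"{name}: codon {codon} at alignment column {i + 1} "
                    f"translates to {trans}, protein has {aa}"
                )
            codons.append(codon)
            k += 1
        return codons

    return CodonAlignment(id_a=id_a, id_b=id_b,
                          codons_a=row_to_codons(aligned_a, cds_a, id_a),
                          codons_b=row_to_codons(aligned_b, cds_b, id_b))


# ---------------------------------------------------------------------------
# NG86


def _syn_fraction_sites(codon: str) -> tuple[float, float]:
    """(S, N) site counts for one codon: each position contributes the
    fraction of its three possible changes that are synonymous."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} in alignment")
    s = 0.0
    aa = _translate_codon(codon)
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _translate_codon(mut) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over all minimal pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total, nd_total = 0.0, 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd, nd = 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a1 = _translate_codon(cur)
            a2 = _translate_codon(nxt)
            if a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise OverflowError("proportion at or past the Jukes-Cantor domain")
    return -0.75 * log(1 - 4 * p / 3)


def ng86_kaks(aln: CodonAlignment) -> tuple[float | None, float | None, float | None]:
    """(Ka, Ks, omega); omega is None when Ks = 0 or a rate is saturated."""
    est = ng86(aln)
    return est["ka"], est["ks"], est["omega"]


def ng86(aln: CodonAlignment) -> dict:
    """NG86 estimates for one codon alignment.

    Returns a dict with S, N (site counts), Sd, Nd (differences), pS, pN,
    ka, ks, omega and a 'flag' string ('' when omega is defined, otherwise
    'ks_zero' or 'saturated').
    """
    pairs = [(a, b) for a, b in zip(aln.codons_a, aln.codons_b)
             if a != "---" and b != "---"]
    if not pairs:
        raise ValueError("all codon columns are gapped")
    S = N = Sd = Nd = 0.0
    for a, b in pairs:
        sa, na = _syn_fraction_sites(a)
        sb, nb = _syn_fraction_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_differences(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    flag = ""
    ka = ks = None
    try:
        ka = _jc_correct(pN)
    except OverflowError:
        flag = "saturated"
    try:
        ks = _jc_correct(pS)
    except OverflowError:
        flag = "saturated"
    omega = None
    if flag == "":
        if ks == 0:
            flag = "ks_zero"
        else:
            omega = ka / ks
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "ka": ka, "ks": ks, "omega": omega, "flag": flag}


def analyze_pairs(proteins: list[SequenceRecord], cds: dict[str, str],
                  annotation: GenomeAnnotation | None = None,
                  criteria: PairCriteria = PairCriteria(),
                  rule: str = "duplication") -> list[DuplicatePair]:
    """Find pairs, classify mode, and attach NG86 Ka/Ks estimates."""
    by_id = {p.id: p for p in proteins}
    pairs = find_pairs(proteins, criteria, rule=rule)
    for pair in pairs:
        a, b = by_id[pair.gene_a], by_id[pair.gene_b]
        row_a, row_b, _, _ = align_pair(a, b)
        codon_aln = backtranslate(row_a, row_b, cds[a.id], cds[b.id],
                                  id_a=a.id, id_b=b.id)
        est = ng86(codon_aln)
        pair.ka, pair.ks, pair.omega = est["ka"], est["ks"], est["omega"]
        pair.flags = est["flag"]
        if annotation is not None:
            pair.mode = classify_mode(pair, annotation)
    return pairs
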