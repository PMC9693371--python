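"""Synthetic study inputs with planted, machine-checkable ground truth.

Every generator is a pure function of (parameters, seed) and emits exactly
the formats the pipeline consumes. The planted truth is definitional: the
genome generator verifies at generation time that each planted repeat is
detectable by the packaged repeat model and that decoys are not, and the
promoter generator verifies planted element counts with an independent
naive matcher, so the truth tables are sufficient oracles for every stage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_scan import (AA_ALPHABET, RepeatPSSM, ScanConfig,
                          load_packaged_pssm, scan_repeats)
from .io_formats import (GeneModel, GenomeAnnotation, SequenceRecord,
                         reverse_complement, write_fasta, write_gff3)
from .promoter_cis import CisElement, packaged_element_table

__all__ = [
    "SyntheticGenome",
    "generate_genome",
    "evolve_pair",
    "generate_expression",
    "generate_qpcr",
    "generate_reference_panel",
    "reverse_translate",
    "sample_repeat",
]

_BASES = "ACGT"

# codon usage: uniform over synonymous codons, stops excluded
_CODONS_FOR_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

for _codon, _aa in _tbl.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
_STOPS = list(_tbl.stop_codons)

_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with uniformly chosen synonymous codons plus a stop."""
    codons = [rng.choice(_CODONS_FOR_AA[aa]) for aa in protein]
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def sample_repeat(pssm: RepeatPSSM, rng: np.random.Generator,
                  mutation_rate: float = 0.05) -> str:
    """One repeat drawn column-wise from the PSSM emission probabilities,
    then hit with uniform substitutions at ``mutation_rate``."""
    if pssm.probs is None:
        raise ValueError("PSSM carries no emission probabilities")
    letters = np.array(list(AA_ALPHABET))
    cols = [rng.choice(letters, p=pssm.probs[:, j] / pssm.probs[:, j].sum())
            for j in range(pssm.width)]
    seq = list("".join(cols))
    for i in range(len(seq)):
        if rng.random() < mutation_rate:
            seq[i] = rng.choice(letters)
    return "".join(seq)


# ---------------------------------------------------------------------------
# promoter planting


def _lookahead(pattern: str):
    import re

    from .promoter_cis import IUPAC

    return re.compile("(?=" + "".join(IUPAC[c] for c in pattern.upper()) + ")")


def _overlap_count(seq: str, pattern: str) -> int:
    """Overlap-inclusive IUPAC occurrence count (zero-width lookahead)."""
    return len(_lookahead(pattern).findall(seq))


def _scrub(seq: list[str], table: list[CisElement], rng: np.random.Generator,
           max_rounds: int = 50) -> None:
    """Replace accidental element occurrences with fresh random bases."""
    for _ in range(max_rounds):
        dirty = False
        for el in table:
            pat = el.pattern.upper()
            w = len(pat)
            s = "".join(seq)
            for m in _lookahead(pat).finditer(s):
                i = m.start()
                for k in range(w):
                    seq[i + k] = rng.choice(list(_BASES))
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub promoter background of element matches")


def _plant_promoter(table: list[CisElement], plant_counts: dict[str, int],
                    rng: np.random.Generator, length: int = 2000,
                    max_tries: int = 30) -> tuple[str, dict[str, int]]:
    """A promoter whose element census is known exactly.

    The background is scrubbed of accidental matches, requested occurrences
    are inserted at non-overlapping positions, and the final counts of every
    table element are verified with the naive matcher; those verified counts
    are the truth (insertion of one element can legitimately create an
    occurrence of a nested pattern, e.g. an ACGT-core element inside a
    G-box, and the truth records what is actually present).
    """
    by_name = {el.name: el for el in table}
    for _ in range(max_tries):
        seq = list(_rand_nt(rng, length))
        _scrub(seq, table, rng)
        slots: list[tuple[int, int]] = []
        ok = True
        for name, count in plant_counts.items():
            pat = by_name[name].pattern.upper()
            w = len(pat)
            for _k in range(count):
                placed = False
                for _try in range(200):
                    pos = int(rng.integers(0, length - w))
                    if all(pos + w <= s or pos >= e for s, e in slots):
                        realization = "".join(
                            rng.choice(list(_IUPAC_CHOICES[c])) for c in pat
                        )
                        seq[pos : pos + w] = list(realization)
                        slots.append((pos, pos + w))
                        placed = True
                        break
                if not placed:
                    ok = False
            if not ok:
                break
        if not ok:
            continue
        s = "".join(seq)
        verified = {el.name: _overlap_count(s, el.pattern.upper()) for el in table}
        if all(verified[n] >= c for n, c in plant_counts.items()):
            return s, verified
    raise RuntimeError("failed to plant promoter elements")


# ---------------------------------------------------------------------------
# genome


@dataclass
class SyntheticGenome:
    """In-memory bundle of all genome-stage inputs plus the planted truth."""

    chromosomes: dict[str, str]
    annotation: GenomeAnnotation
    proteins: list[SequenceRecord]
    cds: dict[str, str]
    truth: dict

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fasta"),
            "gff3": os.path.join(outdir, "annotation.gff3"),
            "proteome": os.path.join(outdir, "proteome.fasta"),
            "cds": os.path.join(outdir, "cds.fasta"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        write_fasta([SequenceRecord(n, s) for n, s in sorted(self.chromosomes.items())],
                    paths["genome"])
        write_gff3(self.annotation, paths["gff3"])
        write_fasta(self.proteins, paths["proteome"])
        write_fasta([SequenceRecord(i, s) for i, s in self.cds.items()], paths["cds"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


_SUBFAMILY_REPEATS = {"1R": 1, "R2R3": 2, "3R": 3, "4R": 4}


def _make_myb_protein(n_repeats: int, pssm: RepeatPSSM, rng: np.random.Generator,
                      mutation_rate: float, config: ScanConfig,
                      max_tries: int = 50) -> tuple[str, list[tuple[int, int]]]:
    """A protein with exactly ``n_repeats`` detectable planted repeats.

    Detectability (and absence of spurious extra hits) is verified with the
    scanner itself; failing drafts are resampled.
    """
    for _ in range(max_tries):
        n_flank = int(rng.integers(20, 60))
        parts = [_rand_aa(rng, n_flank)]
        positions = []
        cursor = n_flank
        for k in range(n_repeats):
            rep = sample_repeat(pssm, rng, mutation_rate)
            positions.append((cursor + 1, cursor + pssm.width))
            parts.append(rep)
            cursor += pssm.width
            if k < n_repeats - 1:
                linker = int(rng.integers(3, 12))
                parts.append(_rand_aa(rng, linker))
                cursor += linker
        parts.append(_rand_aa(rng, int(rng.integers(40, 120))))
        protein = "".join(parts)
        hits = scan_repeats(SequenceRecord("draft", protein), pssm, config)
        found = [(h.start, h.end) for h in hits]
        full = [h for h in hits if h.matched_columns / pssm.width > config.min_aln_rate]
        if found == positions and len(full) == n_repeats:
            return protein, positions
    raise RuntimeError("could not generate a verifiable planted protein")


def _make_decoy_protein(pssm: RepeatPSSM, rng: np.random.Generator,
                        config: ScanConfig, max_tries: int = 50) -> str:
    for _ in range(max_tries):
        protein = _rand_aa(rng, int(rng.integers(150, 450)))
        if not scan_repeats(SequenceRecord("draft", protein), pssm, config):
            return protein
    raise RuntimeError("could not generate a clean decoy protein")


def generate_genome(n_chrom: int = 3, n_genes: int = 40,
                    repeat_spec: dict[str, int] | None = None,
                    seed: int = 0, mutation_rate: float = 0.05,
                    pssm: RepeatPSSM | None = None,
                    config: ScanConfig = ScanConfig(),
                    element_table: list[CisElement] | None = None,
                    plant_elements: bool = True,
                    promoter_len: int = 2000) -> SyntheticGenome:
    """Multi-chromosome genome whose genes carry planted MYB repeats.

    ``repeat_spec`` maps subfamily to gene count (default
    {"1R": 5, "R2R3": 10, "3R": 2}); remaining genes are repeat-free decoys.
    Genes get 1-8 exons, random strand, and (optionally) promoters with
    planted cis-elements. Deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    pssm = pssm or load_packaged_pssm()
    repeat_spec = dict(repeat_spec or {"1R": 5, "R2R3": 10, "3R": 2})
    n_myb = sum(repeat_spec.values())
    if n_myb > n_genes:
        raise ValueError("repeat_spec asks for more MYB genes than n_genes")
    table = element_table if element_table is not None else packaged_element_table()

    # gene roster, shuffled so subfamilies interleave along chromosomes
    roster: list[str] = []
    for subfam, count in sorted(repeat_spec.items()):
        roster += [subfam] * count
    roster += ["decoy"] * (n_genes - n_myb)
    rng.shuffle(roster)

    chrom_names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chrom_parts: dict[str, list[str]] = {c: [_rand_nt(rng, 500)] for c in chrom_names}
    chrom_pos: dict[str, int] = {c: 500 for c in chrom_names}
    genes: list[GeneModel] = []
    proteins: list[SequenceRecord] = []
    cds_map: dict[str, str] = {}
    truth_genes: dict[str, dict] = {}

    for gi, subfam in enumerate(roster):
        gene_id = f"g{gi + 1:04d}"
        tid = gene_id + ".1"
        chrom = chrom_names[gi % n_chrom]
        if subfam == "decoy":
            protein = _make_decoy_protein(pssm, rng, config)
            repeat_pos: list[tuple[int, int]] = []
        else:
            protein, repeat_pos = _make_myb_protein(
                _SUBFAMILY_REPEATS[subfam], pssm, rng, mutation_rate, config)
        cds = reverse_translate(protein, rng)

        if plant_elements:
            wanted = {"G-box": int(rng.poisson(2.0)), "ABRE": int(rng.poisson(1.0))}
            extra = table[int(rng.integers(0, len(table)))]
            wanted[extra.name] = wanted.get(extra.name, 0) + int(rng.poisson(1.0))
            promoter, element_counts = _plant_promoter(table, wanted, rng, promoter_len)
        else:
            promoter = _rand_nt(rng, promoter_len)
            element_counts = {}

        # exon structure over the CDS (coding coordinates)
        n_exons = int(rng.integers(1, 9))
        n_exons = min(n_exons, max(1, len(cds) // 60))
        cut_points = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1,
                                       replace=False)) if n_exons > 1 else []
        bounds = [0] + [int(c) for c in cut_points] + [len(cds)]
        coding_pieces = [(bounds[k], bounds[k + 1]) for k in range(n_exons)]
        introns = [("GT" + _rand_nt(rng, int(rng.integers(60, 240))) + "AG")
                   for _ in range(n_exons - 1)]

        # assemble the transcribed region in coding orientation
        region_parts = []
        piece_offsets = []  # coding-orientation offsets of each exon in region
        off = 0
        for k, (a, b) in enumerate(coding_pieces):
            region_parts.append(cds[a:b])
            piece_offsets.append((off, off + (b - a)))
            off += b - a
            if k < n_exons - 1:
                region_parts.append(introns[k])
                off += len(introns[k])
        region = "".join(region_parts)

        strand = "+" if rng.random() < 0.5 else "-"
        block = promoter + region if strand == "+" else reverse_complement(promoter + region)
        start_of_block = chrom_pos[chrom] + 1  # 1-based genomic start
        chrom_parts[chrom].append(block)
        chrom_pos[chrom] += len(block)
        spacer = _rand_nt(rng, int(rng.integers(300, 800)))
        chrom_parts[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)

        if strand == "+":
            region_g0 = start_of_block + promoter_len  # genomic pos of region[0]
            intervals = [(region_g0 + a, region_g0 + b - 1) for a, b in piece_offsets]
        else:
            # block reversed: region occupies the block's 5' end on the minus strand
            block_end = start_of_block + len(block) - 1
            intervals = [
                (block_end - promoter_len - (b - 1), block_end - promoter_len - a)
                for a, b in piece_offsets
            ]
            intervals.sort()
        gene_start = min(s for s, _ in intervals)
        gene_end = max(e for _, e in intervals)
        genes.append(GeneModel(id=tid, chromosome=chrom, start=gene_start,
                               end=gene_end, strand=strand, exons=list(intervals),
                               cds=list(intervals), gene_id=gene_id))
        proteins.append(SequenceRecord(tid, protein))
        cds_map[tid] = cds
        truth_genes[tid] = {
            "subfamily": subfam if subfam != "decoy" else "other",
            "is_myb": subfam != "decoy",
            "n_repeats": len(repeat_pos),
            "repeat_positions": repeat_pos,
            "chromosome": chrom,
            "strand": strand,
            "element_counts": element_counts,
            "n_exons": n_exons,
        }

    chromosomes = {c: "".join(parts) for c, parts in chrom_parts.items()}
    annotation = GenomeAnnotation(
        chromosomes=sorted((c, len(s)) for c, s in chromosomes.items()),
        genes=sorted(genes, key=lambda g: (g.chromosome, g.start, g.id)),
    )
    order = annotation.chromosome_order
    naming = sorted(truth_genes,
                    key=lambda t: (order[truth_genes[t]["chromosome"]],
                                   annotation.gene(t).start, t))
    truth = {
        "seed": seed,
        "mutation_rate": mutation_rate,
        "genes": truth_genes,
        "naming_order": naming,
        "subfamily_counts": {k: int(v) for k, v in repeat_spec.items()},
        "n_decoys": n_genes - n_myb,
    }
    return SyntheticGenome(chromosomes=chromosomes, annotation=annotation,
                           proteins=proteins, cds=cds_map, truth=truth)


# ---------------------------------------------------------------------------
# codon-pair evolution


def evolve_pair(cds: str, divergence: float, omega: float,
                seed: int = 0) -> tuple[str, str, dict]:
    """Evolve two descendants of one CDS under acceptance-thinned mutation.

    ``divergence`` is the expected number of proposed substitutions per
    codon across the pair (half per lineage). Proposals are uniform over
    sites and alternative bases; synonymous proposals fix, nonsynonymous
    fix with probability ``omega``, stop-creating proposals are rejected.
    The truth dict records realized synonymous/nonsynonymous fixations.
    """
    if not (0 < omega <= 2):
        raise ValueError("omega must be in (0, 2]")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if len(cds) % 3:
        raise ValueError("CDS length must be a codon multiple")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    body = codons[:-1] if codons[-1] in _STOPS else codons
    for c in body:
        if c in _STOPS:
            raise ValueError("internal stop codon")
        if set(c) - set(_BASES):
            raise ValueError(f"invalid codon {c}")
    rng = np.random.default_rng(seed)
    n_codons = len(body)

    def one_lineage(start: list[str]) -> tuple[list[str], int, int]:
        seq = list(start)
        n_prop = rng.poisson(divergence / 2 * n_codons)
        syn = nonsyn = 0
        for _ in range(n_prop):
            ci = int(rng.integers(0, n_codons))
            pos = int(rng.integers(0, 3))
            old = seq[ci]
            alt = [b for b in _BASES if b != old[pos]]
            new = old[:pos] + alt[int(rng.integers(0, 3))] + old[pos + 1 :]
            if new in _STOPS:
                continue
            if _tbl.forward_table[new] == _tbl.forward_table[old]:
                seq[ci] = new
                syn += 1
            elif rng.random() < omega:
                seq[ci] = new
                nonsyn += 1
        return seq, syn, nonsyn

    a, syn_a, non_a = one_lineage(body)
    b, syn_b, non_b = one_lineage(body)
    tail = codons[-1] if codons[-1] in _STOPS else ""
    truth = {
        "omega": omega,
        "divergence": divergence,
        "syn_fixed": syn_a + syn_b,
        "nonsyn_fixed": non_a + non_b,
        "seed": seed,
    }
    return "".join(a) + tail, "".join(b) + tail, truth


# ---------------------------------------------------------------------------
# expression & qPCR


def generate_expression(n_genes: int = 121, tissues: tuple[str, ...] | None = None,
                        module_spec: dict | None = None, seed: int = 0,
                        dispersion: float = 0.05,
                        n_zero: int = 4) -> dict:
    """Negative-binomial tissue counts with a planted correlated module.

    ``module_spec``: {"pathway": [names...], "partners":
    [(myb_index, pathway_name, target_r), ...]}. Pathway genes and their
    partners share a latent tissue profile scaled so the expected Pearson
    correlation of their log-expression equals the target. Returns a dict
    with counts (genes x tissues DataFrame, pathway genes included as extra
    rows), gene lengths, library sizes and the truth.
    """
    from .expression import PATHWAY_GENES, TISSUES

    tissues = tuple(tissues or TISSUES)
    if module_spec is None:
        # default planted module: 16 family genes tied to pathway genes at
        # r = 0.95 (or as many as fit in a small roster)
        lo = min(10, max(n_zero, n_genes - 1))
        hi = min(lo + 16, n_genes)
        module_spec = {
            "pathway": list(PATHWAY_GENES),
            "partners": [(i, PATHWAY_GENES[i % len(PATHWAY_GENES)], 0.95)
                         for i in range(lo, hi)],
        }
    if any(r > 1 for _, _, r in module_spec["partners"]):
        raise ValueError("target correlation cannot exceed 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"MYB{i + 1}" for i in range(n_genes)]
    pathway = list(module_spec["pathway"])
    latent = {pg: rng.normal(0, 1, size=len(tissues)) for pg in pathway}

    log_means = {}
    for pg in pathway:
        log_means[pg] = 5.0 + 2.5 * latent[pg]
    partner_map = {gene_ids[i]: (pg, r) for i, pg, r in module_spec["partners"]}
    zero_genes = set(gene_ids[:n_zero])
    for g in gene_ids:
        if g in zero_genes:
            continue
        if g in partner_map:
            pg, r = partner_map[g]
            eps = rng.normal(0, 1, size=len(tissues))
            profile = r * latent[pg] + np.sqrt(1 - r**2) * eps
            log_means[g] = 5.0 + 2.5 * profile
        else:
            log_means[g] = rng.uniform(2, 8) + rng.normal(0, 1.5, size=len(tissues))

    lengths = pd.Series(rng.integers(600, 3000, size=n_genes + len(pathway)).astype(float),
                        index=gene_ids + pathway, name="length")
    lib_sizes = pd.Series(rng.integers(15_000_000, 25_000_000, size=len(tissues)).astype(float),
                          index=list(tissues), name="library_size")

    counts = pd.DataFrame(0, index=gene_ids + pathway, columns=list(tissues), dtype=int)
    for g in counts.index:
        if g in zero_genes:
            continue
        fpkm_mean = 2.0 ** log_means[g]
        mean_counts = fpkm_mean * lib_sizes.values * lengths[g] / 1e9
        r_nb = 1.0 / dispersion
        p_nb = r_nb / (r_nb + mean_counts)
        counts.loc[g] = rng.negative_binomial(r_nb, p_nb)

    truth = {
        "zero_genes": sorted(zero_genes),
        "partners": [(gene_ids[i], pg, r) for i, pg, r in module_spec["partners"]],
        "pathway": pathway,
        "seed": seed,
    }
    return {"counts": counts, "lengths": lengths, "library_sizes": lib_sizes,
            "truth": truth}


def generate_qpcr(genes: list[str], samples: list[str],
                  fold_spec: dict[str, dict[str, float]], noise_sd: float = 0.05,
                  seed: int = 0, calibrator: str = "STT",
                  reference_gene: str = "Actin", n_replicates: int = 3) -> pd.DataFrame:
    """Ct table generated from planted fold changes.

    Ct_target = Ct_ref + dCt_calibrator - log2(fold) + N(0, noise_sd), with
    ``n_replicates`` per sample x gene. fold values are relative to the
    calibrator sample (whose fold is forced to 1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for g in genes:
        if any(f <= 0 for f in fold_spec.get(g, {}).values()):
            raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    base_ref = 20.0
    dct_cal = {g: float(rng.uniform(2, 6)) for g in genes}
    for s in samples:
        for rep in range(1, n_replicates + 1):
            rows.append({"sample": s, "gene": reference_gene, "replicate": rep,
                         "ct": base_ref + rng.normal(0, noise_sd)})
    for g in genes:
        for s in samples:
            fold = 1.0 if s == calibrator else fold_spec.get(g, {}).get(s, 1.0)
            for rep in range(1, n_replicates + 1):
                ct = (base_ref + dct_cal[g] - np.log2(fold)
                      + rng.normal(0, noise_sd))
                rows.append({"sample": s, "gene": g, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference anchors for subgroup assignment


def generate_reference_panel(labels: list[str], per_label: int = 2,
                             n_queries_per_label: int = 2, seed: int = 0,
                             pssm: RepeatPSSM | None = None,
                             n_label_mutations: int = 8) -> dict:
    """Anchor and query proteins with known subgroup memberships.

    Each subgroup gets its own two-repeat consensus (the global repeat
    consensus with label-specific substitutions); anchors and queries are
    light perturbations of it, so queries sit nearest their own subgroup's
    anchors in the domain tree.
    """
    rng = np.random.default_rng(seed)
    pssm = pssm or load_packaged_pssm()
    letters = np.array(list(AA_ALPHABET))
    consensus = "".join(letters[np.argmax(pssm.probs[:, j])] for j in range(pssm.width))

    def perturb(seq: str, n_mut: int) -> str:
        s = list(seq)
        pos = rng.choice(len(s), size=n_mut, replace=False)
        for p in pos:
            s[p] = rng.choice(letters)
        return "".join(s)

    anchors, queries = [], []
    anchor_labels: dict[str, str] = {}
    query_labels: dict[str, str] = {}
    for label in labels:
        sub_consensus = perturb(consensus + consensus, n_label_mutations)
        for k in range(per_label):
            sid = f"{label}_anchor{k + 1}"
            anchors.append(SequenceRecord(sid, perturb(sub_consensus, 2)))
            anchor_labels[sid] = label
        for k in range(n_queries_per_label):
            qid = f"{label}_query{k + 1}"
            queries.append(SequenceRecord(qid, perturb(sub_consensus, 2)))
            query_labels[qid] = label
    return {"anchors": anchors, "anchor_labels": anchor_labels,
            "queries": queries, "query_labels": query_labels, "seed": seed}
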