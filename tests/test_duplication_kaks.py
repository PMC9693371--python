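import itertools

import numpy as np
import pytest

from familyscan.duplication_kaks import (CodonAlignment, PairCriteria,
                                         align_pair, backtranslate,
                                         classify_mode, find_pairs, ng86,
                                         ng86_kaks)
from familyscan.io_formats import GeneModel, GenomeAnnotation, SequenceRecord
from familyscan.synthetic_data import evolve_pair, reverse_translate


class TestFindPairs:
    def test_identical_sequences_form_a_pair(self):
        seqs = [SequenceRecord("a", "MKWVLLIV" * 10),
                SequenceRecord("b", "MKWVLLIV" * 10)]
        pairs = find_pairs(seqs)
        assert len(pairs) == 1
        assert pairs[0].coverage == 1.0 and pairs[0].identity == 100.0

    def test_length_60_vs_100_rejected_by_coverage(self):
        base = "MKWVLLIVAG" * 10
        seqs = [SequenceRecord("a", base[:60]), SequenceRecord("b", base)]
        # identity of the overlap is perfect, but 0.6 coverage < 0.7
        assert find_pairs(seqs) == []

    def test_toy_set_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, size=120))
        mut = list(base)
        for i in rng.choice(len(mut), size=12, replace=False):
            mut[i] = rng.choice(aas)
        seqs = [
            SequenceRecord("s1", base),
            SequenceRecord("s2", "".join(mut)),        # close to s1
            SequenceRecord("s3", base[:70]),           # fails coverage
            SequenceRecord("s4", "".join(rng.choice(aas, size=120))),  # unrelated
            SequenceRecord("s5", base),                # identical to s1
        ]
        crit = PairCriteria()
        got = {(p.gene_a, p.gene_b) for p in find_pairs(seqs, crit)}
        expected = set()
        for a, b in itertools.combinations(seqs, 2):
            _, _, cov, ident = align_pair(a, b)
            if cov > crit.min_coverage and ident > crit.min_identity:
                expected.add((a.id, b.id))
        assert got == expected
        assert ("s1", "s5") in got and ("s1", "s3") not in got

    def test_fewer_than_two_proteins_errors(self):
        with pytest.raises(ValueError):
            find_pairs([SequenceRecord("a", "MK")])


def _ann(genes):
    return GenomeAnnotation(chromosomes=[("chr1", 10_000_000), ("chr2", 10_000_000)],
                            genes=genes)


def _gene(gid, chrom, start, end):
    return GeneModel(id=gid, chromosome=chrom, start=start, end=end, strand="+",
                     exons=[(start, end)], cds=[(start, end)])


class TestClassifyMode:
    def test_adjacent_genes_are_tandem(self):
        ann = _ann([_gene("a", "chr1", 1000, 2000), _gene("b", "chr1", 3000, 4000)])
        pair = find_pairs([SequenceRecord("a", "MKWV" * 30),
                           SequenceRecord("b", "MKWV" * 30)])[0]
        assert classify_mode(pair, ann) == "tandem"

    def test_different_chromosomes_are_segmental(self):
        ann = _ann([_gene("a", "chr1", 1000, 2000), _gene("b", "chr2", 1000, 2000)])
        pair = find_pairs([SequenceRecord("a", "MKWV" * 30),
                           SequenceRecord("b", "MKWV" * 30)])[0]
        assert classify_mode(pair, ann) == "segmental"

    def test_distant_same_chromosome_with_many_intervening_is_segmental(self):
        genes = [_gene("a", "chr1", 1000, 2000)]
        genes += [_gene(f"x{i}", "chr1", 10_000 + 5000 * i, 12_000 + 5000 * i)
                  for i in range(50)]
        genes.append(_gene("b", "chr1", 5_001_000, 5_002_000))
        ann = _ann(genes)
        pair = find_pairs([SequenceRecord("a", "MKWV" * 30),
                           SequenceRecord("b", "MKWV" * 30)])[0]
        # 50 intervening genes and a 5 Mb span: both tandem conditions fail
        assert classify_mode(pair, ann) == "segmental"

    def test_missing_gene_errors(self):
        ann = _ann([_gene("a", "chr1", 1000, 2000)])
        pair = find_pairs([SequenceRecord("a", "MKWV" * 30),
                           SequenceRecord("zz", "MKWV" * 30)])[0]
        with pytest.raises(ValueError):
            classify_mode(pair, ann)


class TestBacktranslate:
    def test_direct_mapping(self):
        aln = backtranslate("MK", "MK", "ATGAAA", "ATGAAG")
        assert aln.codons_a == ["ATG", "AAA"] and aln.codons_b == ["ATG", "AAG"]

    def test_gap_becomes_triplet_gap(self):
        aln = backtranslate("M-K", "MQK", "ATGAAA", "ATGCAAAAA")
        assert aln.codons_a == ["ATG", "---", "AAA"]
        assert aln.codons_b == ["ATG", "CAA", "AAA"]

    def test_trailing_stop_codon_tolerated(self):
        aln = backtranslate("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert aln.codons_a == ["ATG", "AAA"]

    def test_translation_mismatch_errors_with_position(self):
        with pytest.raises(ValueError, match="column 2"):
            backtranslate("MK", "MK", "ATGCCC", "ATGAAA")

    def test_round_trip_on_simulated_pair(self):
        rng = np.random.default_rng(5)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        cds = reverse_translate(protein, rng)
        a, b, _ = evolve_pair(cds, divergence=0.2, omega=0.5, seed=1)
        from familyscan.io_formats import translate_cds
        aln = backtranslate(translate_cds(a), translate_cds(b), a, b)
        assert translate_cds("".join(aln.codons_a)) == translate_cds(a)



def _codon_aln(a, b):
    from familyscan.io_formats import translate_cds
    return backtranslate(translate_cds(a), translate_cds(b), a, b)

def brute_force_ng86(codons_a, codons_b):
    """Independent NG86 oracle: literal site and pathway enumeration."""
    from Bio.Data.CodonTable import standard_dna_table
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)

    def tr(c):
        return "*" if c in stops else table[c]

    def sites(codon):
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b != codon[pos]:
                    m = codon[:pos] + b + codon[pos + 1:]
                    if tr(m) == tr(codon):
                        s += 1 / 3
        return s

    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca == "---" or cb == "---":
            continue
        S += (sites(ca) + sites(cb)) / 2
        N += 3 - (sites(ca) + sites(cb)) / 2
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if diff:
            paths = list(itertools.permutations(diff))
            sd = nd = 0.0
            for path in paths:
                cur = ca
                for pos in path:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if tr(nxt) == tr(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
            Sd += sd / len(paths)
            Nd += nd / len(paths)
    from math import log
    pS, pN = Sd / S, Nd / N
    ks = -0.75 * log(1 - 4 * pS / 3) if pS < 0.75 else None
    ka = -0.75 * log(1 - 4 * pN / 3) if pN < 0.75 else None
    return S, N, Sd, Nd, ka, ks


class TestNG86:
    def test_identical_pair_has_zero_rates_and_undefined_omega(self):
        aln = CodonAlignment("a", "b", ["ATG", "AAA"], ["ATG", "AAA"])
        ka, ks, omega = ng86_kaks(aln)
        assert ka == 0.0 and ks == 0.0 and omega is None

    def test_single_synonymous_difference(self):
        aln = CodonAlignment("a", "b", ["TTT", "GGG", "AAA"], ["TTC", "GGG", "AAA"])
        est = ng86(aln)
        assert est["Nd"] == 0.0 and est["Sd"] == 1.0
        assert est["ka"] == 0.0 and est["ks"] > 0

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(7)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        cds = reverse_translate(protein, rng)
        a, b, _ = evolve_pair(cds, 0.3, 0.5, seed=2)
        aln = _codon_aln(a, b)
        est = ng86(aln)
        assert est["S"] + est["N"] == pytest.approx(3 * 60, abs=1e-9)

    def test_symmetric_in_the_two_sequences(self):
        aln = CodonAlignment("a", "b", ["TTA", "CGA", "ATG"], ["CTG", "AGA", "ATA"])
        fwd = ng86(aln)
        rev = ng86(CodonAlignment("b", "a", aln.codons_b, aln.codons_a))
        assert fwd["ka"] == pytest.approx(rev["ka"], abs=1e-12)
        assert fwd["ks"] == pytest.approx(rev["ks"], abs=1e-12)

    def test_matches_brute_force_oracle_on_simulated_pair(self):
        rng = np.random.default_rng(8)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        cds = reverse_translate(protein, rng)
        a, b, _ = evolve_pair(cds, 0.4, 0.3, seed=3)
        aln = _codon_aln(a, b)
        est = ng86(aln)
        S, N, Sd, Nd, ka, ks = brute_force_ng86(aln.codons_a, aln.codons_b)
        assert est["S"] == pytest.approx(S, abs=1e-9)
        assert est["Sd"] == pytest.approx(Sd, abs=1e-9)
        assert est["ka"] == pytest.approx(ka, abs=1e-12)
        assert est["ks"] == pytest.approx(ks, abs=1e-12)

    def test_matches_biopython_ng86_cross_check(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(9)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=90))
        cds = reverse_translate(protein, rng)[:-3]  # drop stop
        a, b, _ = evolve_pair(cds, 0.3, 0.4, seed=4)
        est = ng86(CodonAlignment("a", "b",
                                  [a[i:i + 3] for i in range(0, len(a), 3)],
                                  [b[i:i + 3] for i in range(0, len(b), 3)]))
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert est["ka"] == pytest.approx(dn, abs=1e-3)
        assert est["ks"] == pytest.approx(ds, abs=1e-3)

    def test_synonymous_only_evolution_gives_exactly_zero_ka(self):
        rng = np.random.default_rng(10)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        cds = reverse_translate(protein, rng)
        a, b, truth = evolve_pair(cds, 0.5, omega=1e-12, seed=5)
        assert truth["nonsyn_fixed"] == 0
        aln = _codon_aln(a, b)
        ka, ks, _ = ng86_kaks(aln)
        assert ka == 0.0 and ks > 0

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            ng86(CodonAlignment("a", "b", ["TAA", "AAA"], ["TAA", "AAA"]))

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment("a", "b", ["---"], ["---"]))

    def test_omega_recovery_small_simulation(self):
        rng = np.random.default_rng(11)
        errs = []
        for rep in range(8):
            protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
            cds = reverse_translate(protein, rng)
            a, b, _ = evolve_pair(cds, 1.0, omega=0.5, seed=100 + rep)
            aln = _codon_aln(a, b)
            _, _, omega = ng86_kaks(aln)
            errs.append(abs(omega - 0.5))
        assert np.mean(errs) <= 0.1
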