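"""End-to-end orchestration: scan -> properties/phylogeny/logos -> promoter
census -> duplication + Ka/Ks -> expression, with deterministic outputs.

Every stage writes a TSV (tree as Newick) into the output directory; each
table carries the configuration hash so runs are traceable. Stages run in
dependency order and a stage failure leaves earlier outputs intact.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import domain_scan, duplication_kaks, expression, io_formats, motif_logo
from . import phylogeny as phylo
from . import promoter_cis, protein_props

__all__ = ["PipelineConfig", "run_pipeline", "summarize_family", "round_half_up_pct"]


@dataclass
class PipelineConfig:
    proteome: str
    gff3: str
    genome: str = ""
    cds: str = ""
    counts: str = ""
    gene_lengths: str = ""
    library_sizes: str = ""
    ct_table: str = ""
    element_table: str = ""  # empty -> packaged table
    anchor_labels: str = ""  # TSV id<TAB>subgroup; empty -> skip subgroups
    name_prefix: str = "MYB"
    evalue_max: float = 1e-10
    min_aln_len: int = 100
    min_aln_rate: float = 0.5
    min_coverage: float = 0.7
    min_identity: float = 70.0
    bootstrap_reps: int = 100
    seed: int = 7
    outdir: str = "familyscan_out"

    def scan_config(self) -> domain_scan.ScanConfig:
        return domain_scan.ScanConfig(evalue_max=self.evalue_max,
                                      min_aln_len=self.min_aln_len,
                                      min_aln_rate=self.min_aln_rate)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate(self) -> None:
        required = {"proteome": self.proteome, "gff3": self.gff3}
        optional = {k: getattr(self, k) for k in
                    ("genome", "cds", "counts", "gene_lengths", "library_sizes",
                     "ct_table", "element_table", "anchor_labels")}
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")


def round_half_up_pct(members: int, total: int, ndigits: int = 2) -> float:
    """Percentage with round-half-up at ``ndigits`` decimals (printed style)."""
    pct = Decimal(100) * Decimal(members) / Decimal(total)
    q = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_family(classifications: list[domain_scan.MybClassification],
                     subgroups: dict[str, str] | None = None) -> dict:
    """Subfamily counts plus per-subgroup counts and percentages."""
    if not classifications:
        raise ValueError("no classifications")
    total = len(classifications)
    subfam: dict[str, int] = {}
    for c in classifications:
        subfam[c.subfamily] = subfam.get(c.subfamily, 0) + 1
    out = {"total": total, "subfamily_counts": subfam}
    if subgroups:
        sg_counts: dict[str, int] = {}
        for label in subgroups.values():
            sg_counts[label] = sg_counts.get(label, 0) + 1
        out["subgroup_counts"] = sg_counts
        out["subgroup_percent"] = {
            label: round_half_up_pct(n, total) for label, n in sorted(sg_counts.items())
        }
    return out


def _write_tsv(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages; returns a report dict of output paths
    and headline numbers."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    h = config.config_hash()
    report: dict = {"config_hash": h, "outputs": {}}
    with open(os.path.join(config.outdir, "config.resolved.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)

    proteins = io_formats.read_fasta(config.proteome)
    annotation = io_formats.read_gff3(config.gff3)
    scan_cfg = config.scan_config()
    pssm = domain_scan.load_packaged_pssm()

    # stage 1: scan + classify + name
    classified = domain_scan.classify_proteome(proteins, pssm, scan_cfg)
    members = [c for c in classified if c.subfamily in {"1R", "R2R3", "3R", "4R", "other"}
               and c.n_repeats >= 1]
    members = domain_scan.assign_names(members, annotation, config.name_prefix)
    fam_df = pd.DataFrame(
        [{"protein_id": c.protein_id, "assigned_name": c.assigned_name,
          "subfamily": c.subfamily, "n_repeats": c.n_repeats,
          "n_partial": c.n_partial} for c in members]
    )
    path = os.path.join(config.outdir, "family.tsv")
    _write_tsv(fam_df, path, h)
    report["outputs"]["family"] = path
    report["n_members"] = len(members)

    # stage 2: physicochemical properties
    by_id = {p.id: p for p in proteins}
    props = [protein_props.compute_properties(by_id[c.protein_id]) for c in members]
    props_df = pd.DataFrame(
        [{"protein_id": p.protein_id, "assigned_name": n.assigned_name,
          "length": p.length, "mw_kda": round(p.mw / 1000, 2), "pi": round(p.pi, 2),
          "instability": round(p.instability, 2), "stable": p.stable,
          "gravy": round(p.gravy, 3)} for p, n in zip(props, members)]
    )
    path = os.path.join(config.outdir, "properties.tsv")
    _write_tsv(props_df, path, h)
    report["outputs"]["properties"] = path

    # stage 3: domain alignment, tree, logos, subgroups
    hits_by = {c.protein_id: c.hits for c in members if c.hits}
    seqs = {p.id: p.residues for p in proteins}
    subgroup_map: dict[str, str] = {}
    if len(hits_by) >= 2:
        aln = phylo.build_domain_alignment(hits_by, seqs, pssm)
        anchor_labels: dict[str, str] = {}
        if config.anchor_labels:
            lab = pd.read_csv(config.anchor_labels, sep="\t")
            anchor_labels = dict(zip(lab["id"], lab["subgroup"]))
            anchor_fa = config.anchor_labels.replace(".tsv", ".fasta")
            if os.path.exists(anchor_fa):
                for rec in io_formats.read_fasta(anchor_fa):
                    if rec.id in anchor_labels:
                        aln = phylo.DomainAlignment(
                            ids=aln.ids + [rec.id],
                            rows=aln.rows + [_fit_row(rec.residues, aln.n_columns)],
                        )
        tree = phylo.bootstrap_support(aln, config.bootstrap_reps, config.seed)
        path = os.path.join(config.outdir, "tree.nwk")
        with open(path, "w") as fh:
            fh.write(tree.newick() + "\n")
        report["outputs"]["tree"] = path
        if anchor_labels:
            assignments = phylo.assign_subgroups(tree, anchor_labels)
            subgroup_map = {a.protein_id: a.subgroup for a in assignments}
            sg_df = pd.DataFrame([{"protein_id": a.protein_id, "subgroup": a.subgroup,
                                   "anchor_id": a.anchor_id} for a in assignments])
            path = os.path.join(config.outdir, "subgroups.tsv")
            _write_tsv(sg_df, path, h)
            report["outputs"]["subgroups"] = path

        logo_cols = motif_logo.column_information(aln)
        logo_df = pd.DataFrame([{"position": c.position, "ic_bits": c.ic_bits,
                                 "top_residue": c.top_residue,
                                 "top_fraction": c.top_fraction}
                                for c in logo_cols if not c.all_gap])
        path = os.path.join(config.outdir, "logo.tsv")
        _write_tsv(logo_df, path, h)
        report["outputs"]["logo"] = path

    # stage 4: promoter census
    if config.genome:
        genome = {r.id: r.residues for r in io_formats.read_fasta(config.genome)}
        table = (promoter_cis.load_element_table(config.element_table)
                 if config.element_table else promoter_cis.packaged_element_table())
        gene_models = annotation.genes_by_id()
        results = []
        for c in members:
            gene = gene_models[c.protein_id]
            prom = promoter_cis.extract_promoter(gene, genome[gene.chromosome])
            results.append(promoter_cis.scan_elements(prom, table))
        census = promoter_cis.summarize_census(results, table)
        path = os.path.join(config.outdir, "cis_census.tsv")
        _write_tsv(census, path, h)
        report["outputs"]["cis_census"] = path
        report["group_totals"] = census.attrs["group_totals"]

    # stage 5: duplication + Ka/Ks
    if config.cds:
        cds_map = {r.id: r.residues for r in io_formats.read_fasta(config.cds)}
        member_prots = [by_id[c.protein_id] for c in members]
        criteria = duplication_kaks.PairCriteria(min_coverage=config.min_coverage,
                                                 min_identity=config.min_identity)
        pairs = duplication_kaks.analyze_pairs(member_prots, cds_map, annotation,
                                               criteria)
        dup_df = pd.DataFrame(
            [{"gene_a": p.gene_a, "gene_b": p.gene_b,
              "coverage": round(p.coverage, 3), "identity": round(p.identity, 2),
              "mode": p.mode, "ka": p.ka, "ks": p.ks, "omega": p.omega,
              "flags": p.flags} for p in pairs]
        )
        path = os.path.join(config.outdir, "duplications.tsv")
        _write_tsv(dup_df, path, h)
        report["outputs"]["duplications"] = path
        report["n_pairs"] = len(pairs)

    # stage 6: expression
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        lengths = pd.read_csv(config.gene_lengths, sep="\t", index_col=0).iloc[:, 0]
        libs = pd.read_csv(config.library_sizes, sep="\t", index_col=0).iloc[:, 0]
        fpkm_mat = expression.fpkm(counts, lengths, libs)
        log_mat, not_expr = expression.heatmap_matrix(fpkm_mat)
        expr_df = log_mat.round(4)
        expr_df.insert(0, "gene", expr_df.index)
        path = os.path.join(config.outdir, "expression_log2fpkm.tsv")
        _write_tsv(expr_df, path, h)
        report["outputs"]["expression"] = path
        report["n_not_expressed"] = int(not_expr.sum())

    if config.ct_table:
        ct = pd.read_csv(config.ct_table, sep="\t")
        qpcr = expression.ddct(ct, reference_gene="Actin", calibrator_sample="STT")
        q_df = pd.DataFrame([{"gene": q.gene, "sample": q.sample,
                              "rq": q.relative_expression, "sem": q.sem}
                             for q in qpcr])
        path = os.path.join(config.outdir, "qpcr_rq.tsv")
        _write_tsv(q_df, path, h)
        report["outputs"]["qpcr"] = path

    report["summary"] = summarize_family(members, subgroup_map or None)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def _fit_row(seq: str, n_columns: int) -> str:
    """Pad or trim an anchor domain sequence to the alignment width."""
    if len(seq) >= n_columns:
        return seq[:n_columns]
    return seq + phylo.GAP * (n_columns - len(seq))
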