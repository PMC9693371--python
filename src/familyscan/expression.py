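"""Tissue expression: FPKM, heatmap transform, tissue calls, correlation,
one-way ANOVA and 2^-ddCt qPCR quantification.

Correlation against flavonoid-pathway structural genes is the sample
Pearson r on log2(FPKM+1) over tissues, with a two-sided p-value from the
exact t transform t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom and
the usual significance stars (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TISSUES",
    "PATHWAY_GENES",
    "CorrelationResult",
    "QpcrResult",
    "fpkm",
    "heatmap_matrix",
    "tissue_max_calls",
    "pearson_with_p",
    "stars_for_p",
    "correlate_with_pathway",
    "anova_oneway",
    "ddct",
]

TISSUES = ("BA", "FL", "LE", "Pl", "R", "SE", "STT")
PATHWAY_GENES = ("PAL", "C4H", "4CL", "CHS", "CHI", "F3H", "F3'H", "F3'5'H",
                 "DFR", "LDOX")


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """FPKM_gt = 1e9 * C_gt / (N_t * L_g).

    ``counts`` is genes x tissues; lengths in bp indexed by gene; library
    sizes (total mapped reads) indexed by tissue.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    L = gene_lengths.reindex(counts.index)
    N = library_sizes.reindex(counts.columns)
    if (L <= 0).any() or L.isna().any():
        raise ValueError("gene lengths must be positive and complete")
    if (N <= 0).any() or N.isna().any():
        raise ValueError("library sizes must be positive and complete")
    return 1e9 * counts.div(N, axis=1).div(L, axis=0)


def heatmap_matrix(fpkm_mat: pd.DataFrame, transform: str = "log2p1"
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """log2(FPKM+1) matrix plus a per-gene 'not expressed' flag (all-zero row)."""
    if transform != "log2p1":
        raise ValueError(f"unknown transform {transform!r}")
    not_expressed = (fpkm_mat == 0).all(axis=1)
    return np.log2(fpkm_mat + 1.0), not_expressed


def tissue_max_calls(fpkm_mat: pd.DataFrame) -> pd.Series:
    """Tissue of maximal expression per gene; ties are 'ambiguous'."""
    if fpkm_mat.shape[1] < 1:
        raise ValueError("need at least one tissue")
    vals = fpkm_mat.values
    argmax = fpkm_mat.idxmax(axis=1)
    is_tie = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    out = argmax.where(~is_tie, other="ambiguous")
    return out


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_p(x, y) -> tuple[float, float, str]:
    """Sample Pearson r with a two-sided t-test p-value and stars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal vectors of length >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p, stars_for_p(p)


@dataclass(frozen=True)
class CorrelationResult:
    myb_id: str
    pathway_gene: str
    r: float
    p: float
    stars: str


def correlate_with_pathway(myb_log: pd.DataFrame, pathway_log: pd.DataFrame
                           ) -> list[CorrelationResult]:
    """Pearson r/p/stars of every family gene against every pathway gene.

    Both inputs are log2(FPKM+1) matrices over the same tissue columns.
    Genes with zero variance across tissues are skipped.
    """
    out = []
    for myb in myb_log.index:
        x = myb_log.loc[myb].values
        if np.isclose(np.std(x), 0):
            continue
        for pg in pathway_log.index:
            y = pathway_log.loc[pg].values
            if np.isclose(np.std(y), 0):
                continue
            r, p, s = pearson_with_p(x, y)
            out.append(CorrelationResult(myb, pg, r, p, s))
    return out


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with (k-1, N-k) degrees of freedom."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if all(np.allclose(g, g[0]) for g in groups):
        raise ValueError("every group is constant; F is undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    sample: str
    ct_target: float
    ct_reference: float
    relative_expression: float
    sem: float = 0.0


def ddct(ct_table: pd.DataFrame, reference_gene: str,
         calibrator_sample: str) -> list[QpcrResult]:
    """2^-ddCt relative quantification.

    ``ct_table`` has columns sample, gene, replicate, ct. Replicate Cts are
    averaged per sample x gene before dCt; the calibrator sample's RQ is
    exactly 1. The SEM column is the standard error of per-replicate RQs
    (replicate dCt against the calibrator's mean dCt).
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = ct_table["sample"].unique()
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    for s in samples:
        if (s, reference_gene) not in mean_ct.index:
            raise ValueError(f"reference gene {reference_gene} missing in sample {s}")
    out = []
    for g in genes:
        dct = {}
        for s in samples:
            if (s, g) not in mean_ct.index:
                continue
            dct[s] = mean_ct[(s, g)] - mean_ct[(s, reference_gene)]
        if calibrator_sample not in dct:
            raise ValueError(f"calibrator {calibrator_sample} missing for {g}")
        for s, d in dct.items():
            rq = 1.0 if s == calibrator_sample else float(2.0 ** -(d - dct[calibrator_sample]))
            reps = ct_table[(ct_table["sample"] == s) & (ct_table["gene"] == g)]
            ref = ct_table[(ct_table["sample"] == s) & (ct_table["gene"] == reference_gene)]
            rep_dct = reps["ct"].values - ref["ct"].mean()
            rep_rq = 2.0 ** -(rep_dct - dct[calibrator_sample])
            sem = float(rep_rq.std(ddof=1) / np.sqrt(len(rep_rq))) if len(rep_rq) > 1 else 0.0
            out.append(QpcrResult(gene=g, sample=s,
                                  ct_target=float(mean_ct[(s, g)]),
                                  ct_reference=float(mean_ct[(s, reference_gene)]),
                                  relative_expression=rq, sem=sem))
    return out
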