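"""RPKM / chi-square differential-expression caller.

Procedure: per-gene RPKM in each of two samples (replicates pooled by
summation), log2 fold-change of the RPKM ratio, a Pearson chi-square test on
the 2x2 table (gene reads vs all other reads, sample 1 vs sample 2),
Benjamini-Hochberg adjustment across genes, and a conjunction threshold:
p < 0.01, |log2 fold-change| > 1, and BH q < 0.05.

The 2x2 test treats each sample's pooled library as one observation; it has
no replicate structure, so a per-replicate concordance diagnostic is
provided separately.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_FC_THRESHOLD = 1.0  # in log2 units
DEFAULT_FDR_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5  # added to both RPKMs when either is zero


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    rpkm1: float
    rpkm2: float
    log2_fc: float
    p_value: float
    q_value: float
    is_deg: bool


def rpkm(count, gene_length_bp, total_mapped):
    """Reads per kilobase of gene per million mapped reads.

    ``count / ((gene_length_bp / 1000) * (total_mapped / 1e6))``; invariant
    under scaling count and total by the same factor.
    """
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(gene_length_bp <= 0):
        raise ValueError("gene length must be positive")
    if np.any(total_mapped <= 0):
        raise ValueError("total mapped reads must be positive")
    out = np.asarray(count, dtype=float) / (
        (gene_length_bp / 1000.0) * (total_mapped / 1e6)
    )
    return float(out) if out.ndim == 0 else out


def chisq_2x2(a, b, c, d, continuity: bool = False) -> float:
    """Upper-tail p of the Pearson chi-square test on [[a, b], [c, d]].

    ``a`` = gene reads in sample 1, ``b`` = remaining sample-1 reads; c, d
    likewise for sample 2.  Closed form: chi2 = N(ad - bc)^2 /
    ((a+b)(c+d)(a+c)(b+d)), 1 df, no continuity correction by default.
    A zero margin makes the test undefined; p = 1 with a warning.
    """
    stat = _chisq_stat(
        np.array(a, float), np.array(b, float), np.array(c, float), np.array(d, float),
        continuity,
    )
    if np.isnan(stat):
        warnings.warn("zero margin in 2x2 table; p set to 1", stacklevel=2)
        return 1.0
    return float(chi2.sf(stat, df=1))


def _chisq_stat(a, b, c, d, continuity: bool = False):
    """Vectorised Pearson statistic; NaN where any margin is zero."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    diff = np.abs(a * d - b * c)
    if continuity:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * diff**2 / np.where(denom > 0, denom, 1.0), np.nan)
    return stat


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pool(df: pd.DataFrame, cols) -> pd.Series:
    return df[list(cols)].sum(axis=1)


def call_degs(
    counts: pd.DataFrame,
    sample1_cols,
    sample2_cols,
    length_col: str = "length_bp",
    totals: tuple[float, float] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    continuity: bool = False,
) -> pd.DataFrame:
    """Per-gene DEG calls for two samples with replicate columns.

    ``counts`` is indexed by gene id with a gene-length column and one
    column per sample-replicate.  Replicates are summed into one pooled
    count per sample before testing.  ``totals`` (total mapped reads per
    pooled sample) default to the pooled column sums.  Missing counts are
    treated as zero.

    Returns a DataFrame sorted by gene id with columns rpkm1, rpkm2,
    log2_fc, p_value, q_value, is_deg.
    """
    df = counts.copy()
    df[list(sample1_cols) + list(sample2_cols)] = (
        df[list(sample1_cols) + list(sample2_cols)].fillna(0)
    )
    c1 = _pool(df, sample1_cols).to_numpy(float)
    c2 = _pool(df, sample2_cols).to_numpy(float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("negative counts")
    t1, t2 = (float(c1.sum()), float(c2.sum())) if totals is None else map(float, totals)
    lengths = df[length_col].to_numpy(float)

    r1 = rpkm(c1, lengths, t1)
    r2 = rpkm(c2, lengths, t2)
    zero = (r1 == 0) | (r2 == 0)
    r1_fc = np.where(zero, r1 + PSEUDOCOUNT, r1)
    r2_fc = np.where(zero, r2 + PSEUDOCOUNT, r2)
    log2_fc = np.log2(r1_fc / r2_fc)

    stat = _chisq_stat(c1, t1 - c1, c2, t2 - c2, continuity)
    n_bad = int(np.isnan(stat).sum())
    if n_bad:
        warnings.warn(f"{n_bad} genes with a zero margin; p set to 1", stacklevel=2)
    p = np.where(np.isnan(stat), 1.0, chi2.sf(np.nan_to_num(stat), df=1))
    q = bh_fdr(p)
    is_deg = (p < p_threshold) & (np.abs(log2_fc) > fc_threshold) & (q < fdr_threshold)

    out = pd.DataFrame(
        {
            "rpkm1": r1,
            "rpkm2": r2,
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
            "is_deg": is_deg,
        },
        index=df.index,
    )
    out.index.name = counts.index.name or "gene_id"
    return out.sort_index()


def replicate_concordance(
    counts: pd.DataFrame,
    sample1_cols,
    sample2_cols,
    length_col: str = "length_bp",
) -> pd.DataFrame:
    """Diagnostic: Pearson correlation of log RPKM between replicate pairs.

    One row per sample with the replicate count and the correlation of
    log10(RPKM + 0.5) across genes (NaN for single-replicate samples).
    """
    rows = []
    for name, cols in (("sample1", list(sample1_cols)), ("sample2", list(sample2_cols))):
        if len(cols) < 2:
            rows.append({"sample": name, "n_replicates": len(cols), "log_rpkm_r": np.nan})
            continue
        lengths = counts[length_col].to_numpy(float)
        reps = []
        for col in cols[:2]:
            c = counts[col].fillna(0).to_numpy(float)
            reps.append(np.log10(rpkm(c, lengths, c.sum()) + 0.5))
        r = float(np.corrcoef(reps[0], reps[1])[0, 1])
        rows.append({"sample": name, "n_replicates": len(cols), "log_rpkm_r": r})
    return pd.DataFrame(rows)
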