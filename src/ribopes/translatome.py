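"""Translational efficiency and differential-translation calling.

TE for a transcript is the ratio of ribosome-footprint density over its
coding region to total-mRNA density over the whole transcript:
``TE = RPKM(CDS, RPF) / RPKM(exons, RNA)``.  Replicate libraries are pooled
by summing counts; a symmetric pseudocount protects low-count transcripts
from infinite fold changes.  Up-translated transcripts satisfy, with strict
inequalities, ``log2(TE_ko/TE_wt) > 1``, ``|log2(RNA_ko/RNA_wt)| < 1`` and a
Benjamini-Hochberg FDR on the footprint-count change below 0.2; the
down-translated rule is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .params import ThresholdSet

CLASSES = ("up_translated", "down_translated", "unchanged",
           "excluded_transcriptional", "low_coverage")


def _pool(quants: Sequence[pd.DataFrame], count_col: str, length_col: str) -> pd.DataFrame:
    """Sum replicate counts and library totals per transcript (outer join, 0-filled counts)."""
    if not quants:
        raise ValueError("no replicate tables supplied")
    pieces = []
    for df in quants:
        lib = int(df["library_total"].iloc[0]) if len(df) else 0
        pieces.append((df.set_index("transcript_id")[[count_col, length_col]], lib))
    idx = pieces[0][0].index
    for df, _ in pieces[1:]:
        idx = idx.union(df.index)
    count = pd.Series(0.0, index=idx)
    length = pd.Series(np.nan, index=idx)
    present_everywhere = pd.Series(True, index=idx)
    for df, _ in pieces:
        count = count.add(df[count_col].reindex(idx, fill_value=0), fill_value=0)
        incoming = df[length_col].reindex(idx)
        take = length.isna() & incoming.notna()
        length[take] = incoming[take]
        present_everywhere &= idx.isin(df.index)
    total = sum(lib for _, lib in pieces)
    out = pd.DataFrame({"count": count, "length": length, "present": present_everywhere})
    out.attrs["library_total"] = total
    return out


def compute_te(
    rpf_quants: dict[str, Sequence[pd.DataFrame]],
    rna_quants: dict[str, Sequence[pd.DataFrame]],
    conditions: tuple[str, str] = ("wt", "ko"),
    thresholds: ThresholdSet | None = None,
) -> pd.DataFrame:
    """Build the TE table from per-condition, per-replicate region quantifications.

    ``rpf_quants``/``rna_quants`` map condition label to the list of replicate
    DataFrames produced by :func:`ribopes.ribo.quantify_regions` (rpf_psite
    and rna_fragment modes respectively).  Returns one row per transcript
    with pooled counts, RPKMs, TEs, log2 fold changes, Fisher p / BH FDR on
    the footprint change, and translation_class unset ("unchanged" pending
    :func:`classify_translation`).
    """
    thresholds = thresholds or ThresholdSet()
    ref, alt = conditions
    pooled = {}
    totals = {}
    for cond in conditions:
        rpf = _pool(rpf_quants[cond], "cds_count", "cds_length")
        rna = _pool(rna_quants[cond], "exon_count", "exon_length")
        pooled[cond] = (rpf, rna)
        totals[cond] = (rpf.attrs["library_total"], rna.attrs["library_total"])

    idx = pooled[ref][0].index.union(pooled[alt][0].index)
    df = pd.DataFrame(index=idx)
    complete = pd.Series(True, index=idx)
    df["cds_length"] = pd.Series(np.nan, index=idx)
    df["exon_length"] = pd.Series(np.nan, index=idx)
    for cond in conditions:
        rpf, rna = pooled[cond]
        df[f"rpf_cds_count_{cond}"] = rpf["count"].reindex(idx, fill_value=0)
        df[f"rna_exon_count_{cond}"] = rna["count"].reindex(idx, fill_value=0)
        for col, src in (("cds_length", rpf), ("exon_length", rna)):
            incoming = src["length"].reindex(idx)
            take = df[col].isna() & incoming.notna()
            df.loc[take, col] = incoming[take]
        complete &= idx.isin(rpf.index) & rpf["present"].reindex(idx, fill_value=False)
        complete &= idx.isin(rna.index) & rna["present"].reindex(idx, fill_value=False)

    counts = df[[f"rpf_cds_count_{ref}", f"rpf_cds_count_{alt}",
                 f"rna_exon_count_{ref}", f"rna_exon_count_{alt}"]].to_numpy(float)
    needs_pc = (counts < thresholds.min_counts).any(axis=1)
    adj = counts + np.where(needs_pc[:, None], thresholds.pseudocount, 0.0)

    all_zero = counts.sum(axis=1) == 0
    low_coverage = (~complete.to_numpy()) | all_zero

    def _rpkm(col_counts, length, lib_total):
        return col_counts / ((length / 1e3) * (lib_total / 1e6))

    rpf_rpkm = {}
    rna_rpkm = {}
    for j, cond in enumerate(conditions):
        rpf_tot, rna_tot = totals[cond]
        rpf_rpkm[cond] = _rpkm(adj[:, j], df["cds_length"].to_numpy(float), rpf_tot)
        rna_rpkm[cond] = _rpkm(adj[:, 2 + j], df["exon_length"].to_numpy(float), rna_tot)
        df[f"rpf_cds_rpkm_{cond}"] = rpf_rpkm[cond]
        df[f"rna_exon_rpkm_{cond}"] = rna_rpkm[cond]
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"te_{cond}"] = rpf_rpkm[cond] / rna_rpkm[cond]

    with np.errstate(divide="ignore", invalid="ignore"):
        df["log2fc_te"] = np.log2(df[f"te_{alt}"] / df[f"te_{ref}"])
        df["log2fc_mrna"] = np.log2(df[f"rna_exon_rpkm_{alt}"] / df[f"rna_exon_rpkm_{ref}"])

    # Fisher exact on pooled footprint counts vs library totals
    pvals = np.ones(len(df))
    rpf_tot_ref, rpf_tot_alt = totals[ref][0], totals[alt][0]
    cnt_ref = df[f"rpf_cds_count_{ref}"].to_numpy()
    cnt_alt = df[f"rpf_cds_count_{alt}"].to_numpy()
    for i in range(len(df)):
        if low_coverage[i]:
            continue
        pvals[i] = rpf_significance(cnt_alt[i], cnt_ref[i], rpf_tot_alt, rpf_tot_ref)
    df["rpf_p"] = pvals
    df["rpf_fdr"] = bh_adjust(pvals)
    df["pseudocount_applied"] = needs_pc
    df["low_coverage"] = low_coverage
    df["translation_class"] = "unchanged"
    df.index.name = "transcript_id"
    return df.reset_index()


def rpf_significance(count_ko: float, count_wt: float,
                     total_ko: int, total_wt: int) -> float:
    """Two-sided Fisher exact p for a footprint-count change between libraries."""
    a, b = int(round(count_ko)), int(round(count_wt))
    if total_ko < a or total_wt < b:
        raise ValueError("library totals smaller than counts")
    if total_ko <= 0 or total_wt <= 0:
        raise ValueError("zero library total")
    table = [[a, total_ko - a], [b, total_wt - b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_translation(te_table: pd.DataFrame,
                         thresholds: ThresholdSet | None = None) -> pd.DataFrame:
    """Assign translation classes; a pure function of the thresholds (idempotent)."""
    t = thresholds or ThresholdSet()
    df = te_table.copy()
    lfc_te = df["log2fc_te"].to_numpy(float)
    lfc_rna = df["log2fc_mrna"].to_numpy(float)
    fdr = df["rpf_fdr"].to_numpy(float)
    low = df["low_coverage"].to_numpy(bool) if "low_coverage" in df else np.zeros(len(df), bool)

    cls = np.full(len(df), "unchanged", dtype=object)
    transcriptional = np.abs(lfc_rna) >= t.max_abs_log2fc_mrna
    up = (lfc_te > t.min_log2fc_te) & ~transcriptional & (fdr < t.max_fdr)
    down = (lfc_te < -t.min_log2fc_te) & ~transcriptional & (fdr < t.max_fdr)
    cls[transcriptional] = "excluded_transcriptional"
    cls[up] = "up_translated"
    cls[down] = "down_translated"
    cls[low | ~np.isfinite(lfc_te)] = "low_coverage"
    df["translation_class"] = cls
    return df


def replicate_correlation(counts_a, counts_b) -> float:
    """Pearson r between two replicate count vectors on the log2(count+1) scale."""
    a = np.log2(np.asarray(counts_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(counts_b, dtype=float) + 1.0)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length, n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


@dataclass(frozen=True)
class TeShiftResult:
    statistic: float
    pvalue: float
    median_log2_shift: float
    n: int


def cumulative_te_shift(te_ref, te_alt) -> TeShiftResult:
    """Two-sided Wilcoxon signed-rank test on paired log2 TE values."""
    ref = np.asarray(te_ref, dtype=float)
    alt = np.asarray(te_alt, dtype=float)
    if ref.shape != alt.shape:
        raise ValueError("paired TE vectors must have equal length")
    ok = np.isfinite(ref) & np.isfinite(alt) & (ref > 0) & (alt > 0)
    diffs = np.log2(alt[ok]) - np.log2(ref[ok])
    median = float(np.median(diffs)) if diffs.size else np.nan
    if diffs.size == 0 or np.all(diffs == 0):
        return TeShiftResult(statistic=0.0, pvalue=1.0,
                             median_log2_shift=median if diffs.size else np.nan,
                             n=int(diffs.size))
    stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    return TeShiftResult(statistic=float(stat), pvalue=float(p),
                         median_log2_shift=median, n=int(diffs.size))
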