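"""Expression-based filters for Y-candidate transcripts.

Two layers, applied after the k-mer sieve:

* a male-bias differential test (log2 fold change plus a rank-sum test
  with Benjamini-Hochberg FDR), and
* the strict TPM filter — mean male TPM above a floor and exactly zero
  TPM in every female sample, the expected signature of a gene absent
  from XX genomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionTable, FilterConfig, Sex


def strict_tpm_filter(expr: ExpressionTable, cfg: FilterConfig | None = None) -> list[str]:
    """Transcripts with mean male TPM > cfg.min_male_mean_tpm and every
    female TPM <= cfg.max_female_tpm (strict zero at the default 0)."""
    cfg = cfg or FilterConfig()
    male_cols = expr.columns_for(Sex.male)
    female_cols = expr.columns_for(Sex.female)
    if not male_cols or not female_cols:
        raise ValueError("need at least one sample of each sex")
    male_mean = expr.tpm[:, male_cols].mean(axis=1)
    female_max = expr.tpm[:, female_cols].max(axis=1)
    keep = (male_mean > cfg.min_male_mean_tpm) & (female_max <= cfg.max_female_tpm)
    return [t for t, ok in zip(expr.transcript_ids, keep) if ok]


def male_bias_test(expr: ExpressionTable, cfg: FilterConfig | None = None,
                   test: str = "ranksum") -> pd.DataFrame:
    """Per-transcript male-bias statistics.

    log2FC = log2((mean_male + pseudocount) / (mean_female + pseudocount)).
    p comes from a two-sided Wilcoxon rank-sum (Mann-Whitney U) test on
    per-sample TPM — distribution-free, suited to the small sample counts
    typical here; ``test='ttest'`` swaps in Welch's t. With fewer than two
    samples in either sex, p and FDR are NaN and the pass flag uses log2FC
    alone. FDR is Benjamini-Hochberg over all tested transcripts.

    Returns a DataFrame with columns transcript, log2fc, p, fdr, passed.
    """
    cfg = cfg or FilterConfig()
    male_cols = expr.columns_for(Sex.male)
    female_cols = expr.columns_for(Sex.female)
    if not male_cols or not female_cols:
        raise ValueError("need at least one sample of each sex")
    m = expr.tpm[:, male_cols]
    f = expr.tpm[:, female_cols]
    log2fc = np.log2((m.mean(axis=1) + cfg.pseudocount)
                     / (f.mean(axis=1) + cfg.pseudocount))

    can_test = len(male_cols) >= 2 and len(female_cols) >= 2
    pvals = np.full(len(expr.transcript_ids), np.nan)
    if can_test:
        for i in range(len(pvals)):
            if np.all(m[i] == m[i][0]) and np.all(f[i] == f[i][0]) and m[i][0] == f[i][0]:
                pvals[i] = 1.0  # identical constant groups: no evidence
                continue
            if test == "ttest":
                pvals[i] = stats.ttest_ind(m[i], f[i], equal_var=False).pvalue
            else:
                pvals[i] = stats.mannwhitneyu(m[i], f[i], alternative="two-sided").pvalue
        fdr = np.full_like(pvals, np.nan)
        ok = ~np.isnan(pvals)
        if ok.any():
            fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        passed = (log2fc >= cfg.min_log2fc) & ok & (fdr <= cfg.max_fdr)
    else:
        fdr = pvals.copy()
        passed = log2fc >= cfg.min_log2fc

    return pd.DataFrame({
        "transcript": expr.transcript_ids,
        "log2fc": log2fc,
        "p": pvals,
        "fdr": fdr,
        "passed": passed,
    })
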