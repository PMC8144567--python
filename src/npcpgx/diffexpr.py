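"""Count normalization, two stand-in differential tests, BH adjustment, and
the two-method overlap filter that defines signature gene lists.

The discriminating step of the emulated workflow is not any single DE
engine but the conjunction: a gene counts as a signature gene only when it
clears |log2FC| > 1, p < 0.05 and BH-adjusted p < 0.05 in BOTH of two
independent tests.  Here method A is a moderated location test (pooled
per-gene variance shrunk toward the gene-wise median) and method B a
Wilcoxon rank-sum test; both share the same log2FC estimate so the overlap
acts purely on the p-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_THRESHOLDS = {"min_abs_log2fc": 1.0, "max_p": 0.05, "max_padj": 0.05}

#: prior degrees of freedom for variance shrinkage in the moderated test
MODERATION_DF = 4.0


def normalize_counts(counts: pd.DataFrame):
    """Median-of-ratios size factors and a log2-normalized matrix.

    For genes with nonzero counts in every sample, each sample's size factor
    is the median of count / geometric-mean-across-samples; when no such
    gene exists, falls back to total-count scaling (factors normalized to
    geometric mean 1) with a warning.  Returns ``(size_factors,
    log2(count/sf + 1))``.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = counts.values.astype(float)
    allpos = np.all(x > 0, axis=1)
    if allpos.any():
        logx = np.log(x[allpos])
        log_gm = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_gm, axis=0))
    else:
        warnings.warn(
            "no gene with nonzero counts in all samples; "
            "falling back to total-count size factors"
        )
        totals = x.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    norm = np.log2(x / sf[None, :] + 1.0)
    return size_factors, pd.DataFrame(norm, index=counts.index, columns=counts.columns)


def drop_all_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero reads in every sample."""
    return counts.loc[counts.sum(axis=1) > 0]


def _validate_groups(normalized, groups):
    groups = pd.Series(groups, index=normalized.columns)
    levels = sorted(pd.unique(groups))  # fixed orientation: label swap flips fc
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels")
    a, b = levels
    if (groups == a).sum() < 2 or (groups == b).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return groups, a, b


def de_test(normalized: pd.DataFrame, groups, method: str = "A") -> pd.DataFrame:
    """Per-gene differential test on the log2-normalized matrix.

    log2fc is the mean difference between group levels in sorted label order
    (alphabetically first minus second), so relabeling samples flips its
    sign; the estimate is shared between methods.  Method 'A': moderated t, pooled variance shrunk
    toward the gene-wise median with 4 prior df.  Method 'B': two-sided
    Wilcoxon rank-sum.  Returns a frame with gene, log2fc, p, padj, method.
    """
    groups, a, b = _validate_groups(normalized, groups)
    xa = normalized.loc[:, (groups == a).values].values
    xb = normalized.loc[:, (groups == b).values].values
    na, nb = xa.shape[1], xb.shape[1]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)

    if method == "A":
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        df_g = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / df_g
        s2_prior = np.median(s2)
        s2_mod = (MODERATION_DF * s2_prior + df_g * s2) / (MODERATION_DF + df_g)
        se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df=df_g + MODERATION_DF)
    elif method == "B":
        res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue)
    else:
        raise ValueError("method must be 'A' or 'B'")

    return pd.DataFrame(
        {
            "gene": normalized.index,
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "method": method,
        }
    ).set_index("gene")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_filter(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Signature genes: pass |log2fc|, p and padj cutoffs in BOTH methods.

    Direction ('up_in_A_level' by the sign of log2fc, i.e. up in the first
    group level) comes from method A's estimate; output is sorted by
    |log2fc| descending.
    """
    if not res_a.index.equals(res_b.index):
        if set(res_a.index) != set(res_b.index):
            raise ValueError("gene universes differ between methods")
        res_b = res_b.reindex(res_a.index)

    def passes(res):
        return (
            (res["log2fc"].abs() > min_abs_log2fc)
            & (res["p"] < max_p)
            & (res["padj"] < max_padj)
        )

    keep = passes(res_a) & passes(res_b)
    out = pd.DataFrame(
        {
            "log2fc": res_a["log2fc"][keep],
            "p_a": res_a["p"][keep],
            "padj_a": res_a["padj"][keep],
            "p_b": res_b["p"][keep],
            "padj_b": res_b["padj"][keep],
        }
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up_in_first", "up_in_second")
    return out.reindex(out["log2fc"].abs().sort_values(ascending=False).index)


def assemble_pathway_signature(
    sig_genes, pathway_sets: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Intersect a signature gene list with pathway sets; add the union.

    Returns per-pathway intersections plus a 'combined' entry (union over
    pathways).  Warns when every intersection is empty.
    """
    if not pathway_sets:
        raise ValueError("pathway sets must be nonempty")
    genes = set(sig_genes.index if isinstance(sig_genes, pd.DataFrame) else sig_genes)
    out = {
        name: sorted(genes & set(members)) for name, members in pathway_sets.items()
    }
    combined = sorted(set().union(*[set(v) for v in out.values()]))
    if not combined:
        warnings.warn("signature genes intersect no pathway set; empty signature")
    out["combined"] = combined
    return out
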