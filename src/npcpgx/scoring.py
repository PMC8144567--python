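"""ssGSEA scoring, IC50-quantile response labeling, and ROC/AUC evaluation.

Per sample, genes are ranked by expression; the single-sample enrichment
score is the integral (sum over rank positions) of the difference between a
rank-weighted in-set ECDF (step weights |rank|^alpha, alpha = 0.25) and the
uniform out-of-set ECDF.  Because only ranks enter, the score is invariant
to any strictly increasing transform of the expression values.  Samples are
labeled sensitive/resistant from the bottom/top 10% of IC50s, and
classification accuracy is the midrank (Mann-Whitney) AUC: the probability
that a random sensitive sample outscores a random resistant one, ties
counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_ALPHA = 0.25
DEFAULT_QUANTILE = 0.10


class _RankedExpression:
    """Per-sample descending rank order and rank weights, precomputed once."""

    def __init__(self, expression: pd.DataFrame, alpha: float = DEFAULT_ALPHA):
        x = expression.values.astype(float)
        self.genes = pd.Index(expression.index)
        self.samples = expression.columns
        self.alpha = alpha
        # midranks ascending (1..N), weight = rank^alpha on descending walk
        ranks = np.apply_along_axis(rankdata, 0, x)
        self.order = np.argsort(-x, axis=0, kind="stable")
        self.weights = np.take_along_axis(
            np.abs(ranks) ** alpha, self.order, axis=0
        )

    def scores(self, member_mask: np.ndarray) -> np.ndarray:
        in_sorted = member_mask[self.order]
        w_in = self.weights * in_sorted
        denom_in = w_in.sum(axis=0)
        n_out = (~member_mask).sum()
        p_in = np.cumsum(w_in, axis=0) / denom_in
        p_out = np.cumsum(~in_sorted, axis=0) / n_out
        return (p_in - p_out).sum(axis=0)


def ssgsea_score(
    expression: pd.DataFrame,
    geneset,
    alpha: float = DEFAULT_ALPHA,
    rescale: bool = False,
) -> pd.Series:
    """Single-sample GSEA score of one gene set for every sample (column).

    Requires at least 2 set genes and 2 non-set genes after intersecting the
    set with the matrix rows.  With ``rescale=True`` scores are min-max
    rescaled to [0, 1] across samples (a presentation convenience; AUC and
    correlations are unaffected by the raw/rescaled choice for fixed
    orientation).
    """
    ranked = _RankedExpression(expression, alpha=alpha)
    mask = ranked.genes.isin(set(geneset)).astype(bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need >= 2 genes inside and outside the set")
    scores = ranked.scores(mask)
    s = pd.Series(scores, index=expression.columns, name="ssgsea")
    if rescale:
        rng = s.max() - s.min()
        s = (s - s.min()) / rng if rng > 0 else s * 0.0
    return s


def score_genesets(
    expression: pd.DataFrame, genesets: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score several gene sets, sharing the per-sample ranking work."""
    ranked = _RankedExpression(expression, alpha=alpha)
    out = {}
    for name, members in genesets.items():
        mask = ranked.genes.isin(set(members)).astype(bool)
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"gene set {name!r} too small after intersection")
        out[name] = ranked.scores(mask)
    return pd.DataFrame(out, index=expression.columns)


def label_by_ic50(ic50: pd.Series, q: float = DEFAULT_QUANTILE) -> pd.Series:
    """Sensitive / resistant / unlabeled by bottom and top IC50 quantiles.

    The ``floor(q*n)`` samples with the lowest IC50 are sensitive, the
    ``floor(q*n)`` highest are resistant, the rest unlabeled.  Boundary ties
    are broken by stable input order so the labeling is deterministic.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    ic50 = pd.Series(ic50)
    n = len(ic50)
    if ic50.nunique() == 1:
        raise ValueError("all IC50 values identical; no ordering to label by")
    if n < 10:
        warnings.warn(f"labeling only {n} samples; quantile classes will be tiny")
    k = int(np.floor(q * n))
    order = np.argsort(ic50.values, kind="stable")
    labels = pd.Series("unlabeled", index=ic50.index, name="label")
    labels.iloc[order[:k]] = "sensitive"
    if k > 0:
        labels.iloc[order[-k:]] = "resistant"
    return labels


@dataclass(frozen=True)
class ROCResult:
    auc: float
    points: np.ndarray  # (fpr, tpr) pairs, (0,0) .. (1,1)
    positive_label: str


def roc_auc(
    scores: pd.Series, labels: pd.Series, positive: str = "sensitive",
    negative: str = "resistant",
) -> ROCResult:
    """Midrank AUC and ROC points; positive class defaults to 'sensitive'.

    Unlabeled samples are excluded.  AUC = (R1 - n1(n1+1)/2) / (n1*n0) with
    midranks, i.e. the tie-corrected probability that a positive outranks a
    negative.
    """
    scores, labels = pd.Series(scores).align(pd.Series(labels), join="inner")
    use = labels.isin([positive, negative])
    s = scores[use].values.astype(float)
    y = (labels[use] == positive).values
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one sample in each class")
    r = rankdata(s)
    auc = (r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # threshold sweep for the curve (descending score), ties grouped
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    return ROCResult(
        auc=float(auc), points=np.column_stack([fpr, tpr]), positive_label=positive
    )


def score_response_correlation(
    scores: pd.DataFrame, labels: pd.Series, subtype: pd.Series | None = None
) -> pd.DataFrame:
    """Point-biserial correlation of each score column with the response.

    Response coded 1 = sensitive, 0 = resistant (higher score correlating
    with sensitivity gives +1).  Constant score columns yield a missing
    correlation with a reason, not a zero.  With ``subtype`` given, adds
    one row per subtype restricted to that subtype's samples.
    """
    labels = labels[labels.isin(["sensitive", "resistant"])]
    if len(labels) < 3:
        raise ValueError("need >= 3 labeled samples")
    y = (labels == "sensitive").astype(float)

    def corr_block(block_scores, block_y, tag):
        rows = []
        for col in block_scores.columns:
            x = block_scores[col].values.astype(float)
            if np.std(x) == 0 or np.std(block_y) == 0:
                rows.append((tag, col, np.nan, "zero variance"))
            else:
                rows.append((tag, col, float(np.corrcoef(x, block_y)[0, 1]), ""))
        return rows

    rows = corr_block(scores.loc[labels.index], y.values, "all")
    if subtype is not None:
        for st in pd.unique(subtype):
            idx = labels.index.intersection(subtype[subtype == st].index)
            if len(idx) >= 3 and y[idx].nunique() == 2:
                rows += corr_block(scores.loc[idx], y[idx].values, st)
    return pd.DataFrame(rows, columns=["grouping", "geneset", "correlation", "note"])


def random_signature_null(
    expression: pd.DataFrame,
    labels: pd.Series,
    n_genes: int = 105,
    n_iter: int = 200,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """AUC distribution of randomly drawn gene signatures.

    Each iteration samples ``n_genes`` genes uniformly without replacement,
    scores all samples by ssGSEA, and computes the sensitive-vs-resistant
    AUC.  With labels independent of expression this calibrates the null:
    the mean AUC sits at 0.5.  Returns mean, sd, quantiles and the AUCs.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_genes > expression.shape[0]:
        raise ValueError("n_genes exceeds the gene universe")
    rng = np.random.default_rng(seed)
    ranked = _RankedExpression(expression, alpha=alpha)
    aucs = np.empty(n_iter)
    n_univ = expression.shape[0]
    for i in range(n_iter):
        mask = np.zeros(n_univ, dtype=bool)
        mask[rng.choice(n_univ, size=n_genes, replace=False)] = True
        s = pd.Series(ranked.scores(mask), index=expression.columns)
        aucs[i] = roc_auc(s, labels).auc
    qs = np.quantile(aucs, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if n_iter > 1 else 0.0,
        "quantiles": {
            "q025": qs[0], "q25": qs[1], "median": qs[2], "q75": qs[3], "q975": qs[4]
        },
        "n_iter": n_iter,
        "n_genes": n_genes,
        "aucs": aucs,
    }
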