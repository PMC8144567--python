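"""Multi-caller somatic-variant consensus, filter cascade, burden summaries,
and 96-context mutational-catalog refitting.

A variant is keyed by (chrom, pos, ref, alt); calls present in at least two
of the callers are kept as consensus, then passed through a conjunction of
annotation filters: population allele frequency < 0.0004, tumor depth > 20,
tumor alt reads > 3, matched-normal alt reads < 1, and tumor VAF > 0.05
(plus an optional low-mappability BED mask).  Surviving SNVs are binned into
the 96 pyrimidine-centered trinucleotide substitution classes and refitted
against a reference-signature matrix by nonnegative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simulate import round_half_up

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: canonical 96-class order: substitution-major, then 5' and 3' flank
CONTEXT_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _FLANKS
    for three in _FLANKS
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter cascade (all comparisons strict).

    ``normal_clause`` selects the reading of the matched-normal criterion:
    'normal_alt' requires alt-supporting reads in the normal < max_n_alt
    (i.e. none at the default of 1); 'literal_ref_reads' is the literal
    reading — reference-supporting tumor reads < max_n_alt — kept only as a
    switch because it would discard nearly every real call.
    """

    max_pop_af: float = 0.0004
    min_t_depth: int = 20
    min_t_alt: int = 3
    max_n_alt: int = 1
    min_vaf: float = 0.05
    min_callers: int = 2
    normal_clause: str = "normal_alt"


def merge_callers(
    callsets, min_callers: int = 2, caller_col: str = "caller"
) -> pd.DataFrame:
    """Consensus of per-caller call tables: keep keys seen by >= min_callers.

    ``callsets`` is a mapping caller-name -> table or a list of >= 2 tables
    (each with a ``caller`` column).  Per-caller duplicates of a key are
    dropped before counting.  The surviving annotation record for each key is
    the one from the caller with the greatest tumor depth (ties broken by
    caller name order), and an ``n_callers`` column records support.
    """
    if isinstance(callsets, dict):
        frames = []
        for name, df in callsets.items():
            df = df.copy()
            df[caller_col] = name
            frames.append(df)
    else:
        frames = [df.copy() for df in callsets]
    if len(frames) < 2:
        raise ValueError("at least two callsets required for consensus")
    allcalls = pd.concat(frames, ignore_index=True)
    allcalls = allcalls.drop_duplicates(subset=VARIANT_KEY + [caller_col])
    support = (
        allcalls.groupby(VARIANT_KEY)[caller_col].nunique().rename("n_callers")
    )
    keep = support[support >= min_callers].index
    consensus = allcalls.set_index(VARIANT_KEY).loc[keep].reset_index()
    # representative record: deepest tumor coverage, then caller name
    consensus = consensus.sort_values(
        ["t_depth", caller_col], ascending=[False, True], kind="stable"
    ).drop_duplicates(subset=VARIANT_KEY)
    consensus = consensus.merge(support.reset_index(), on=VARIANT_KEY)
    return consensus.sort_values(VARIANT_KEY).reset_index(drop=True)


def _mask_hits(variants: pd.DataFrame, mask) -> np.ndarray:
    """True where a 1-based variant position falls in a 0-based half-open
    BED interval."""
    hit = np.zeros(len(variants), dtype=bool)
    for chrom, start, end in mask:
        pos0 = variants["pos"].values - 1
        hit |= (variants["chrom"].values == chrom) & (pos0 >= start) & (pos0 < end)
    return hit


def apply_filters(
    consensus: pd.DataFrame,
    config: FilterConfig | None = None,
    mask=None,
):
    """Run the annotation filter cascade; returns (retained, rejected).

    ``rejected`` carries a ``reason`` column naming the first failing
    criterion (pop_af, depth, alt_reads, normal_alt, vaf, mappability).
    Filtering is a conjunction of per-variant predicates, hence idempotent
    and order-independent.
    """
    cfg = config or FilterConfig()
    required = ["pop_af", "t_depth", "t_alt", "n_alt", "vaf"]
    missing = [c for c in required if c not in consensus.columns]
    if missing:
        raise ValueError(f"missing annotation columns: {missing}")
    if consensus[required].isna().any().any():
        raise ValueError("missing (NaN) annotations present")

    df = consensus
    if cfg.normal_clause == "normal_alt":
        normal_ok = df["n_alt"] < cfg.max_n_alt
    elif cfg.normal_clause == "literal_ref_reads":
        normal_ok = (df["t_depth"] - df["t_alt"]) < cfg.max_n_alt
    else:
        raise ValueError(f"unknown normal_clause: {cfg.normal_clause!r}")

    checks = [
        ("pop_af", df["pop_af"] < cfg.max_pop_af),
        ("depth", df["t_depth"] > cfg.min_t_depth),
        ("alt_reads", df["t_alt"] > cfg.min_t_alt),
        ("normal_alt", normal_ok),
        ("vaf", df["vaf"] > cfg.min_vaf),
    ]
    if mask is not None:
        checks.append(("mappability", ~_mask_hits(df, mask)))

    keep = np.ones(len(df), dtype=bool)
    reason = np.array([""] * len(df), dtype=object)
    for name, ok in checks:
        ok = np.asarray(ok)
        newly_failed = keep & ~ok
        reason[newly_failed] = name
        keep &= ok
    retained = df[keep].reset_index(drop=True)
    rejected = df[~keep].copy()
    rejected["reason"] = reason[~keep]
    return retained, rejected.reset_index(drop=True)


def burden_summary(filtered: pd.DataFrame, sample_ids) -> dict:
    """Per-sample mutation burden and consequence-class breakdown.

    ``mean_per_sample`` is total/n_samples rounded to one decimal for
    reporting (2662 variants over 88 samples -> 30.3).
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("sample list must be non-empty")
    if len(filtered) and "sample" not in filtered.columns:
        raise ValueError("variants must carry a 'sample' column")
    per_sample = {s: 0 for s in sample_ids}
    if len(filtered):
        counts = filtered["sample"].value_counts()
        unknown = set(counts.index) - set(sample_ids)
        if unknown:
            raise ValueError(f"variants assigned to unknown samples: {sorted(unknown)}")
        per_sample.update({s: int(c) for s, c in counts.items()})
    total = int(sum(per_sample.values()))
    by_class = {}
    if len(filtered) and "consequence" in filtered.columns:
        by_class = {
            k: int(v) for k, v in filtered["consequence"].value_counts().items()
        }
    return {
        "total": total,
        "n_samples": len(sample_ids),
        "per_sample": per_sample,
        "mean_per_sample": round_half_up(total / len(sample_ids), 1),
        "by_consequence": by_class,
    }


def gene_frequency_pct(
    variants: pd.DataFrame, gene: str, n_samples: int, decimals: int = 2
) -> float:
    """Percent of samples carrying >= 1 variant in ``gene`` (e.g. 1/106 -> 0.94)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    hit = variants[variants["gene"] == gene]["sample"].nunique() if len(variants) else 0
    return round_half_up(100.0 * hit / n_samples, decimals)


def classify_context(ref: str, alt: str, context: str) -> str:
    """96-class label for one SNV given its reference trinucleotide context.

    Purine-centered substitutions are reverse-complemented into the
    pyrimidine convention, e.g. G>A with context TGC collapses to G[C>T]A.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("classify_context expects a single-base substitution")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in "GA":
        context = context.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CONTEXT_SET:
        raise ValueError(f"unresolvable context class {label!r}")
    return label


_CONTEXT_SET = frozenset(CONTEXT_CLASSES)


def trinucleotide_contexts(snvs: pd.DataFrame, reference_lookup) -> pd.Series:
    """Bin SNVs into the 96 trinucleotide classes; indels are skipped.

    ``reference_lookup`` maps (chrom, pos) to the reference trinucleotide, or
    is a callable doing the same.  Raises if any SNV position cannot be
    resolved; the catalog total equals the number of classified SNVs.
    """
    get = reference_lookup if callable(reference_lookup) else reference_lookup.get
    counts = pd.Series(0, index=list(CONTEXT_CLASSES), dtype=int)
    unresolved = 0
    for row in snvs.itertuples():
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue  # indel
        ctx = get((row.chrom, int(row.pos)))
        if ctx is None:
            unresolved += 1
            continue
        counts[classify_context(row.ref, row.alt, ctx)] += 1
    if unresolved:
        raise ValueError(f"{unresolved} SNV positions lack a reference context")
    return counts


@dataclass(frozen=True)
class SignatureFit:
    """Nonnegative refit of a catalog onto reference signatures."""

    weights: pd.Series  # exposure per signature, sums to <= 1
    cosine: float  # reconstruction cosine similarity


def refit_signatures(
    catalog: pd.Series,
    reference: pd.DataFrame,
    normalization: str = "none",
    genome_exome_ratio: pd.Series | None = None,
) -> SignatureFit:
    """NNLS refit of a 96-context catalog against reference signatures.

    The catalog is normalized to frequencies; with
    ``normalization='exome2genome'`` each context frequency is first
    multiplied by the supplied genome/exome trinucleotide frequency ratio
    (re-weighting an exome-observed catalog to genome-wide expectation).
    Weights are rescaled to exposures summing to 1; the cosine compares the
    NNLS reconstruction to the (re-weighted) catalog.
    """
    catalog = catalog.reindex(list(CONTEXT_CLASSES))
    if catalog.isna().any():
        raise ValueError("catalog must cover all 96 context classes")
    total = float(catalog.sum())
    if total <= 0:
        raise ValueError("catalog total must be positive")
    ref = reference.reindex(list(CONTEXT_CLASSES))
    if ref.isna().any().any():
        raise ValueError("reference must cover all 96 context classes")
    colsums = ref.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")

    m = catalog.values.astype(float) / total
    if normalization == "exome2genome":
        if genome_exome_ratio is None:
            raise ValueError("exome2genome normalization needs a ratio vector")
        ratio = genome_exome_ratio.reindex(list(CONTEXT_CLASSES)).values
        m = m * ratio
        m = m / m.sum()
    elif normalization != "none":
        raise ValueError(f"unknown normalization: {normalization!r}")

    w, _ = nnls(ref.values, m)
    recon = ref.values @ w
    denom = np.linalg.norm(recon) * np.linalg.norm(m)
    cosine = float(recon @ m / denom) if denom > 0 else 0.0
    exposures = w / w.sum() if w.sum() > 0 else w
    return SignatureFit(
        weights=pd.Series(exposures, index=ref.columns), cosine=cosine
    )


def synthetic_reference_signatures() -> pd.DataFrame:
    """Deterministic synthetic 96x5 reference-signature matrix.

    These are synthetic stand-ins shaped like well-known mutational
    processes — NOT any published catalog: 'clocklike' (C>T at NpCpG),
    'apobec_like' (TpC C>G/C>T), 'tobacco_like' (C>A), 'mmr_like'
    (broad C>T plus T>C), and 'flat' (uniform background).  Columns sum to 1.
    """
    idx = list(CONTEXT_CLASSES)
    sigs = pd.DataFrame(0.0, index=idx, columns=[
        "clocklike", "apobec_like", "tobacco_like", "mmr_like", "flat"
    ])
    for ctx in idx:
        five, sub, three = ctx[0], ctx[2:5], ctx[6]
        if sub == "C>T" and three == "G":
            sigs.loc[ctx, "clocklike"] += 4.0
        if five == "T" and sub in ("C>G", "C>T"):
            sigs.loc[ctx, "apobec_like"] += 3.0
        if sub == "C>A":
            sigs.loc[ctx, "tobacco_like"] += 2.0 + (five in "CT")
        if sub == "C>T":
            sigs.loc[ctx, "mmr_like"] += 1.5
        if sub == "T>C":
            sigs.loc[ctx, "mmr_like"] += 1.0
        sigs.loc[ctx, "flat"] += 1.0
        sigs.loc[ctx, "clocklike"] += 0.05  # keep strictly positive support
        sigs.loc[ctx, "apobec_like"] += 0.05
        sigs.loc[ctx, "tobacco_like"] += 0.05
        sigs.loc[ctx, "mmr_like"] += 0.05
    return sigs / sigs.sum(axis=0)


def load_reference_signatures() -> pd.DataFrame:
    """Load the bundled synthetic reference-signature TSV (96 x 5)."""
    with resources.files("npcpgx.data").joinpath(
        "reference_signatures_synthetic.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df
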