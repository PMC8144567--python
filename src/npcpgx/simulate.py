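"""Synthetic cohort, drug-screen, variant-call and expression generators.

Every generator is deterministic given its seed and records enough ground
truth (:class:`SimTruth`-style side tables) that downstream statistics can be
checked analytically or by brute force.  The defaults emulate the study
conditions of a nasopharyngeal-carcinoma (NPC) organoid pharmacogenomics
screen: a 106-patient cohort split into four histological subtypes, 6-point
3-fold dilution viability plates spanning 0.08–20 µM, three-caller somatic
call sets, and negative-binomial bulk expression with subtype-structured
pathway signal tied to a continuous IC50 phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SUBTYPES = ("EC", "MSEC", "SC", "SCC")

#: Cohort subtype composition: 57/106 EC, 26/106 MSEC, 20/106 SC, 3/106 SCC.
DEFAULT_SUBTYPE_FRACTIONS = {
    "EC": 57 / 106,
    "MSEC": 26 / 106,
    "SC": 20 / 106,
    "SCC": 3 / 106,
}

#: Six-point 3-fold dilution series, 0.08–20 µM (top dose 20, ratio 3).
DEFAULT_DOSES_UM = tuple(20.0 / 3.0**k for k in range(5, -1, -1))

#: Organoid establishment rate observed in the emulated study: 40 of 43.
DEFAULT_PDO_RATE = 40 / 43

CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_del",
    "inframe_del",
    "frameshift_ins",
    "inframe_ins",
    "other",
)

CALLER_NAMES = ("callerA", "callerB", "callerC")

_BASES = np.array(list("ACGT"))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as screen reports do (30.25 -> 30.3).

    Python's built-in ``round`` uses banker's rounding, which would report
    2662/88 as 30.2 instead of the conventional 30.3.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def proportion_pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``100*k/n`` rounded for reporting (e.g. 57/106 -> 53.77)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, decimals)


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` into integer counts by the largest-remainder method.

    Counts sum exactly to ``n``; ties on remainders are broken by the
    iteration order of ``fractions`` for determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total!r}")
    keys = list(fractions)
    quotas = np.array([n * fractions[k] for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort: ties broken by input order
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def gen_cohort(
    n_patients: int,
    subtype_fractions: dict[str, float] | None = None,
    seed: int = 0,
    pdo_rate: float = DEFAULT_PDO_RATE,
) -> pd.DataFrame:
    """Generate a cohort table with subtype labels and organoid availability.

    Returns a frame with columns ``patient_id`` (unique), ``subtype`` and
    ``has_pdo``.  Subtype counts are the largest-remainder rounding of
    ``n_patients * fraction``; ``has_pdo`` is Bernoulli(``pdo_rate``).
    """
    fractions = dict(subtype_fractions or DEFAULT_SUBTYPE_FRACTIONS)
    counts = largest_remainder_counts(n_patients, fractions)
    rng = np.random.default_rng(seed)
    subtype = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(subtype)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
            "subtype": subtype,
            "has_pdo": rng.random(n_patients) < pdo_rate,
        }
    )


def cohort_report(cohort: pd.DataFrame) -> dict:
    """Descriptive arithmetic on a cohort table (counts and percentages)."""
    n = len(cohort)
    counts = cohort["subtype"].value_counts().to_dict()
    n_pdo = int(cohort["has_pdo"].sum())
    return {
        "n_patients": n,
        "subtype_counts": {k: int(counts.get(k, 0)) for k in SUBTYPES},
        "subtype_pct": {
            k: proportion_pct(int(counts.get(k, 0)), n) for k in SUBTYPES
        },
        "n_pdo": n_pdo,
        "pdo_rate_pct": proportion_pct(n_pdo, n, 0),
    }


@dataclass(frozen=True)
class DoseResponseTruth:
    """True four-parameter log-logistic curve for one sample/treatment.

    ``viability(d) = bottom + (top - bottom) / (1 + (d / ic50)**hill)``,
    expressed as % of control.
    """

    ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0

    def viability(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill
        )

    def inhibition(self, dose):
        """Inhibition fraction 1 - v/100, clipped to [0, 1]."""
        return np.clip(1.0 - self.viability(dose) / 100.0, 0.0, 1.0)


def _check_doses(doses) -> np.ndarray:
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must be non-empty")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    return doses


def gen_dose_response(
    truth: DoseResponseTruth,
    doses=DEFAULT_DOSES_UM,
    n_reps: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
    sample: str = "S1",
    drug: str = "drugX",
    ir_gy: float = 0.0,
) -> pd.DataFrame:
    """Simulate a tidy viability plate for one sample/drug arm.

    Additive Gaussian noise on the % scale, truncated at 0.  Columns:
    sample, drug, dose_uM, ir_gy, replicate, viability_pct.
    """
    doses = _check_doses(doses)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    expected = truth.viability(doses)
    rows = []
    for rep in range(1, n_reps + 1):
        noisy = expected + rng.normal(0.0, noise_sd, size=doses.size)
        noisy = np.maximum(noisy, 0.0)
        for d, v in zip(doses, noisy):
            rows.append((sample, drug, d, ir_gy, rep, v))
    return pd.DataFrame(
        rows,
        columns=["sample", "drug", "dose_uM", "ir_gy", "replicate", "viability_pct"],
    )


def gen_combo_screen(
    mono_truth: DoseResponseTruth,
    ir_inhibition_at_4gy: float,
    synergy_offset: float = 0.0,
    doses=DEFAULT_DOSES_UM,
    n_reps: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
    sample: str = "S1",
    drug: str = "drugX",
    ir_gy: float = 4.0,
) -> pd.DataFrame:
    """Simulate the drug+IR combination arm of a chemoradiotherapy screen.

    Expected combo inhibition at dose d is the Bliss-additive prediction
    ``E1 + E2(d) - E1*E2(d)`` plus ``synergy_offset``, clipped to [0, 1];
    offset 0 therefore reproduces exact additivity in expectation, and a
    positive offset pushes combo viability below the additive curve.
    """
    for name, val in (("ir_inhibition_at_4gy", ir_inhibition_at_4gy),
                      ("synergy_offset", synergy_offset)):
        if not -1.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [-1, 1]")
    doses = _check_doses(doses)
    rng = np.random.default_rng(seed)
    e2 = mono_truth.inhibition(doses)
    e1 = np.clip(ir_inhibition_at_4gy, 0.0, 1.0)
    e_total = np.clip(e1 + e2 - e1 * e2 + synergy_offset, 0.0, 1.0)
    expected = 100.0 * (1.0 - e_total)
    rows = []
    for rep in range(1, n_reps + 1):
        noisy = np.maximum(expected + rng.normal(0.0, noise_sd, doses.size), 0.0)
        for d, v in zip(doses, noisy):
            rows.append((sample, drug, d, ir_gy, rep, v))
    return pd.DataFrame(
        rows,
        columns=["sample", "drug", "dose_uM", "ir_gy", "replicate", "viability_pct"],
    )


@dataclass(frozen=True)
class DepthModel:
    """Sampling distributions for per-variant sequencing annotations.

    True somatic variants are drawn to clear the downstream filter cascade
    with high probability (deep tumor coverage, clean normal, absent from
    population databases); caller-private false positives are drawn shallow,
    low-VAF, normal-contaminated and sometimes population-polymorphic.
    """

    true_depth_mean: float = 100.0
    true_vaf_alpha: float = 8.0
    true_vaf_beta: float = 24.0
    fp_depth_mean: float = 40.0
    fp_vaf_alpha: float = 1.2
    fp_vaf_beta: float = 30.0
    fp_normal_alt_mean: float = 1.5
    fp_common_prob: float = 0.3


def _random_variant_keys(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Unique (chrom, pos, ref, alt) keys plus a trinucleotide context."""
    chroms = rng.integers(1, 23, size=n)
    pos = rng.integers(1, 50_000_000, size=n)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    up = _BASES[rng.integers(0, 4, size=n)]
    down = _BASES[rng.integers(0, 4, size=n)]
    df = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chroms],
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "context": [u + r + d for u, r, d in zip(up, _BASES[ref_i], down)],
        }
    )
    return df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)


def gen_caller_callsets(
    n_true: int,
    fp_per_caller=(5, 5, 5),
    depth_model: DepthModel | None = None,
    seed: int = 0,
    samples=("T1",),
    callers=CALLER_NAMES,
):
    """Emulate three somatic callers run on the same tumors.

    Every true variant is emitted by >= 2 callers (all three with
    probability 0.7); every false positive is private to one caller, so the
    >=2-caller consensus has known precision 1.  Returns
    ``(callsets, truth, reference_lookup)`` where *callsets* maps caller name
    to a call table, *truth* carries one row per distinct variant with its
    true/false label, and *reference_lookup* maps (chrom, pos) to the
    trinucleotide reference context for catalog building.
    """
    if n_true < 0 or any(f < 0 for f in fp_per_caller):
        raise ValueError("counts must be >= 0")
    if len(fp_per_caller) != len(callers):
        raise ValueError("fp_per_caller must have one entry per caller")
    dm = depth_model or DepthModel()
    rng = np.random.default_rng(seed)
    n_fp = int(sum(fp_per_caller))
    keys = _random_variant_keys(rng, (n_true + n_fp) * 2 + 16)
    if len(keys) < n_true + n_fp:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw enough unique variant positions")
    keys = keys.iloc[: n_true + n_fp].copy()
    keys["is_true"] = np.arange(len(keys)) < n_true
    keys["sample"] = np.array(samples)[rng.integers(0, len(samples), len(keys))]
    keys["gene"] = [f"GENE{i:05d}" for i in rng.integers(0, 20000, len(keys))]
    keys["consequence"] = np.array(CONSEQUENCE_CLASSES)[
        rng.choice(len(CONSEQUENCE_CLASSES), size=len(keys), p=_CONSEQ_P)
    ]

    records = []
    for i, row in keys.iterrows():
        if row.is_true:
            chosen = (
                list(callers)
                if rng.random() < 0.7
                else sorted(rng.choice(len(callers), 2, replace=False).tolist())
            )
            chosen = (
                chosen if isinstance(chosen[0], str) else [callers[j] for j in chosen]
            )
        else:
            # caller-private FP: pick the caller whose quota covers index i
            fp_idx = i - n_true
            bounds = np.cumsum(fp_per_caller)
            chosen = [callers[int(np.searchsorted(bounds, fp_idx, side="right"))]]
        for caller in chosen:
            if row.is_true:
                depth = max(int(rng.poisson(dm.true_depth_mean)), 25)
                vaf = rng.beta(dm.true_vaf_alpha, dm.true_vaf_beta)
                t_alt = max(int(rng.binomial(depth, vaf)), 4)
                n_alt = 0
                pop_af = 0.0
            else:
                depth = max(int(rng.poisson(dm.fp_depth_mean)), 1)
                vaf = rng.beta(dm.fp_vaf_alpha, dm.fp_vaf_beta)
                t_alt = int(rng.binomial(depth, vaf))
                n_alt = int(rng.poisson(dm.fp_normal_alt_mean))
                pop_af = 0.01 if rng.random() < dm.fp_common_prob else 0.0
            records.append(
                (
                    row.chrom, int(row.pos), row.ref, row.alt, caller,
                    depth, t_alt, n_alt, pop_af, t_alt / depth,
                    row["sample"], row.gene, row.consequence, row.context,
                )
            )
    calls = pd.DataFrame(
        records,
        columns=[
            "chrom", "pos", "ref", "alt", "caller",
            "t_depth", "t_alt", "n_alt", "pop_af", "vaf",
            "sample", "gene", "consequence", "context",
        ],
    )
    callsets = {
        c: calls[calls.caller == c].reset_index(drop=True) for c in callers
    }
    lookup = {
        (row.chrom, int(row.pos)): row.context for row in keys.itertuples()
    }
    truth = keys[
        ["chrom", "pos", "ref", "alt", "is_true", "sample", "gene", "consequence"]
    ].copy()
    return callsets, truth, lookup


# class mix loosely matching an exome screen dominated by missense calls
_CONSEQ_P = np.array([0.866, 0.072, 0.018, 0.019, 0.012, 0.008, 0.003, 0.002])
_CONSEQ_P = _CONSEQ_P / _CONSEQ_P.sum()


def default_ic50_link(activity: np.ndarray, rng: np.random.Generator,
                      noise_sd: float = 0.15) -> np.ndarray:
    """Map standardized signature activity to a µM IC50, monotone decreasing.

    High signature activity -> sensitive (low IC50).  Log10 IC50 is linear in
    activity with Gaussian noise, clipped to the tested range [0.08, 20].
    """
    log10 = 0.3 - 0.8 * activity + rng.normal(0.0, noise_sd, activity.shape)
    return np.clip(10.0**log10, 0.08, 20.0)


@dataclass
class ExpressionTruth:
    """Ground truth for one simulated expression cohort."""

    signature_genes: dict[str, list[str]]
    log2fc: pd.Series
    activity: pd.Series
    seed: int = 0
    extras: dict = field(default_factory=dict)


def gen_expression(
    n_genes: int = 2000,
    n_samples: int = 14,
    signature_sets: dict[str, list[str]] | None = None,
    group_log2fc: float = 2.0,
    dispersion=(0.05, 0.5),
    ic50_link=None,
    seed: int = 0,
    n_signature: int = 105,
    groups=("EC", "SC"),
):
    """Simulate a negative-binomial count matrix with pathway signal.

    A block of ``n_signature`` genes (or the union of ``signature_sets``) is
    shifted by ``group_log2fc`` in the first group; per-sample library sizes
    span an exact 2-fold range; gene-wise NB dispersions are drawn
    log-uniform over ``dispersion``.  A continuous IC50 phenotype is a noisy
    monotone (decreasing) function of true per-sample signature activity.

    Returns ``(counts, meta, truth)``: genes×samples integer frame, sample
    metadata (group, ic50, true activity), and :class:`ExpressionTruth`.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"PDO{i + 1:03d}" for i in range(n_samples)]
    group = np.array([groups[0]] * (n_samples // 2)
                     + [groups[1]] * (n_samples - n_samples // 2))

    if signature_sets is None:
        sig_genes = genes[:n_signature]
        signature_sets = {"signature_up_in_%s" % groups[0]: list(sig_genes)}
    else:
        sig_genes = sorted({g for gs in signature_sets.values() for g in gs})
        missing = set(sig_genes) - set(genes)
        if missing:
            raise ValueError(f"signature genes not in universe: {sorted(missing)[:5]}")

    log2fc = pd.Series(0.0, index=genes)
    log2fc.loc[sig_genes] = group_log2fc

    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    lo, hi = dispersion
    disp = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    # exact >=2-fold library-size spread, order shuffled
    sf = 2.0 ** np.linspace(-0.5, 0.5, n_samples)
    rng.shuffle(sf)

    in_first = (group == groups[0]).astype(float)
    mu = (
        base[:, None]
        * 2.0 ** (log2fc.values[:, None] * in_first[None, :])
        * sf[None, :]
    )
    size = 1.0 / disp[:, None]
    counts = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    # true activity: mean log2 expected expression of signature genes, z-scored
    sig_mu = np.log2(mu[np.isin(genes, sig_genes), :] + 1.0).mean(axis=0)
    activity = (sig_mu - sig_mu.mean()) / (sig_mu.std() + 1e-12)
    link = ic50_link or default_ic50_link
    ic50 = link(activity, rng)

    meta = pd.DataFrame(
        {"sample": samples, "group": group, "ic50_uM": ic50, "activity": activity}
    ).set_index("sample")
    truth = ExpressionTruth(
        signature_genes={k: list(v) for k, v in signature_sets.items()},
        log2fc=log2fc,
        activity=meta["activity"],
        seed=seed,
        extras={"dispersion": disp, "size_factors": sf},
    )
    return counts, meta, truth
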