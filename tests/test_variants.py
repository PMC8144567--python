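import numpy as np
import pandas as pd
import pytest

from npcpgx import simulate
from npcpgx.variants import (
    CONTEXT_CLASSES,
    FilterConfig,
    apply_filters,
    burden_summary,
    classify_context,
    gene_frequency_pct,
    load_reference_signatures,
    merge_callers,
    refit_signatures,
    trinucleotide_contexts,
)


class TestMergeCallers:
    def test_toy_enumeration(self, toy_callsets):
        consensus = merge_callers(toy_callsets)
        genes = set(consensus["gene"])
        assert genes == {"GENE_B", "GENE_C"}
        support = dict(zip(consensus["gene"], consensus["n_callers"]))
        assert support == {"GENE_B": 2, "GENE_C": 3}

    def test_identical_sets_pass_through(self, toy_callsets):
        c1 = toy_callsets["c1"]
        c2 = c1.assign(caller="c2")
        c3 = c1.assign(caller="c3")
        consensus = merge_callers({"c1": c1, "c2": c2, "c3": c3})
        assert set(consensus["gene"]) == set(c1["gene"])

    def test_disjoint_sets_empty(self, toy_callsets):
        c1 = toy_callsets["c1"].copy()
        c2 = c1.assign(pos=c1["pos"] + 1000, caller="c2")
        c3 = c1.assign(pos=c1["pos"] + 2000, caller="c3")
        assert len(merge_callers({"c1": c1, "c2": c2, "c3": c3})) == 0

    def test_annotation_from_deepest_caller(self, toy_callsets):
        consensus = merge_callers(toy_callsets)
        rec_b = consensus[consensus["gene"] == "GENE_B"].iloc[0]
        assert rec_b["caller"] == "c2" and rec_b["t_depth"] == 90
        rec_c = consensus[consensus["gene"] == "GENE_C"].iloc[0]
        assert rec_c["caller"] == "c3" and rec_c["t_depth"] == 80

    def test_fewer_than_two_callsets_rejected(self, toy_callsets):
        with pytest.raises(ValueError, match="two callsets"):
            merge_callers([toy_callsets["c1"]])

    def test_adding_caller_never_removes_consensus(self, toy_callsets):
        base = merge_callers({k: toy_callsets[k] for k in ("c1", "c2")})
        extended = merge_callers(toy_callsets)
        base_keys = set(map(tuple, base[["chrom", "pos"]].values))
        ext_keys = set(map(tuple, extended[["chrom", "pos"]].values))
        assert base_keys <= ext_keys


def _variant(**kw):
    base = dict(chrom="chr1", pos=100, ref="C", alt="T", caller="c1",
                t_depth=25, t_alt=4, n_alt=0, pop_af=0.0, vaf=0.10,
                sample="T1", gene="G", consequence="missense")
    base.update(kw)
    return base


class TestApplyFilters:
    def test_all_thresholds_cleared(self):
        retained, rejected = apply_filters(pd.DataFrame([_variant()]))
        assert len(retained) == 1 and len(rejected) == 0

    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"t_depth": 15}, "depth"),
            ({"pop_af": 0.001}, "pop_af"),
            ({"t_alt": 3}, "alt_reads"),
            ({"n_alt": 1}, "normal_alt"),
            ({"vaf": 0.05}, "vaf"),
        ],
    )
    def test_single_criterion_failures(self, override, reason):
        retained, rejected = apply_filters(pd.DataFrame([_variant(**override)]))
        assert len(retained) == 0
        assert rejected["reason"].iloc[0] == reason

    def test_idempotent(self):
        df = pd.DataFrame([_variant(), _variant(pos=200, t_depth=10)])
        once, _ = apply_filters(df)
        twice, _ = apply_filters(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_mask_uses_bed_half_open_convention(self):
        # BED [99, 105) covers 0-based 99..104, i.e. 1-based 100..105
        mask = [("chr1", 99, 105)]
        inside = pd.DataFrame([_variant(pos=100)])
        boundary = pd.DataFrame([_variant(pos=105)])
        outside = pd.DataFrame([_variant(pos=106)])
        assert len(apply_filters(inside, mask=mask)[0]) == 0
        assert len(apply_filters(boundary, mask=mask)[0]) == 0
        assert len(apply_filters(outside, mask=mask)[0]) == 1
        assert apply_filters(inside, mask=mask)[1]["reason"].iloc[0] == "mappability"

    def test_literal_reference_clause_discards_real_calls(self):
        df = pd.DataFrame([_variant()])  # 21 ref-supporting reads
        cfg = FilterConfig(normal_clause="literal_ref_reads")
        retained, rejected = apply_filters(df, cfg)
        assert len(retained) == 0 and rejected["reason"].iloc[0] == "normal_alt"

    def test_missing_annotation_rejected(self):
        df = pd.DataFrame([_variant()]).drop(columns=["vaf"])
        with pytest.raises(ValueError, match="missing annotation"):
            apply_filters(df)


class TestBurdenSummary:
    def test_mean_rounding(self):
        df = pd.DataFrame([_variant(pos=100 + i, sample=f"T{i % 2}")
                           for i in range(6)])
        out = burden_summary(df, ["T0", "T1"])
        assert out["mean_per_sample"] == 3.0
        assert out["total"] == 6

    def test_empty_set_zero_mean(self):
        out = burden_summary(pd.DataFrame(), ["T1", "T2"])
        assert out["mean_per_sample"] == 0.0
        assert out["per_sample"] == {"T1": 0, "T2": 0}

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            burden_summary(pd.DataFrame(), [])

    def test_class_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        rows = [
            _variant(pos=i + 1, sample="T1",
                     consequence=rng.choice(simulate.CONSEQUENCE_CLASSES))
            for i in range(40)
        ]
        out = burden_summary(pd.DataFrame(rows), ["T1"])
        assert sum(out["by_consequence"].values()) == out["total"] == 40

    def test_gene_frequency_pct(self):
        df = pd.DataFrame([_variant(gene="EGFR", sample="P1")])
        assert gene_frequency_pct(df, "EGFR", 106) == 0.94
        assert gene_frequency_pct(df, "ABSENT", 106) == 0.0


class TestTrinucleotideContexts:
    def test_pyrimidine_reference_direct(self):
        df = pd.DataFrame([_variant(ref="C", alt="T")])
        catalog = trinucleotide_contexts(df, {("chr1", 100): "ACA"})
        assert catalog["A[C>T]A"] == 1
        assert catalog.sum() == 1

    def test_purine_reference_reverse_complemented(self):
        df = pd.DataFrame([_variant(ref="G", alt="A")])
        catalog = trinucleotide_contexts(df, {("chr1", 100): "TGC"})
        assert catalog["G[C>T]A"] == 1

    def test_total_conservation_and_indel_skip(self):
        rows = [_variant(pos=1, ref="C", alt="A"),
                _variant(pos=2, ref="T", alt="G"),
                _variant(pos=3, ref="CA", alt="C")]  # indel: skipped
        lookup = {("chr1", 1): "ACT", ("chr1", 2): "GTA"}
        catalog = trinucleotide_contexts(pd.DataFrame(rows), lookup)
        assert catalog.sum() == 2

    def test_unresolvable_position_rejected(self):
        df = pd.DataFrame([_variant()])
        with pytest.raises(ValueError, match="lack a reference context"):
            trinucleotide_contexts(df, {})

    def test_classify_context_validates(self):
        with pytest.raises(ValueError, match="does not match"):
            classify_context("C", "T", "AAA")


class TestRefitSignatures:
    def test_pure_signature_recovered(self):
        ref = load_reference_signatures()
        catalog = (100 * ref["tobacco_like"]).round(6)
        fit = refit_signatures(catalog, ref)
        assert fit.weights["tobacco_like"] == pytest.approx(1.0, abs=1e-4)
        assert fit.cosine == pytest.approx(1.0, abs=1e-6)

    def test_exact_mixture_recovered(self):
        ref = load_reference_signatures()
        catalog = 1000 * (0.6 * ref["clocklike"] + 0.4 * ref["apobec_like"])
        fit = refit_signatures(catalog, ref)
        assert fit.weights["clocklike"] == pytest.approx(0.6, abs=1e-6)
        assert fit.weights["apobec_like"] == pytest.approx(0.4, abs=1e-6)
        assert fit.cosine == pytest.approx(1.0, abs=1e-9)

    def test_exome2genome_unit_ratio_is_identity(self):
        ref = load_reference_signatures()
        catalog = 500 * (0.5 * ref["flat"] + 0.5 * ref["mmr_like"])
        ones = pd.Series(1.0, index=list(CONTEXT_CLASSES))
        a = refit_signatures(catalog, ref, normalization="none")
        b = refit_signatures(catalog, ref, normalization="exome2genome",
                             genome_exome_ratio=ones)
        pd.testing.assert_series_equal(a.weights, b.weights)

    def test_exome2genome_reweights(self):
        ref = load_reference_signatures()
        catalog = 300 * ref["flat"]
        ratio = pd.Series(
            np.linspace(0.5, 2.0, 96), index=list(CONTEXT_CLASSES)
        )
        fit = refit_signatures(catalog, ref, normalization="exome2genome",
                               genome_exome_ratio=ratio)
        assert fit.weights["flat"] < 1.0  # re-weighting breaks the pure fit

    def test_zero_catalog_rejected(self):
        ref = load_reference_signatures()
        zero = pd.Series(0, index=list(CONTEXT_CLASSES))
        with pytest.raises(ValueError, match="positive"):
            refit_signatures(zero, ref)

    def test_bundled_reference_is_valid(self):
        ref = load_reference_signatures()
        assert ref.shape == (96, 5)
        assert list(ref.index) == list(CONTEXT_CLASSES)
        np.testing.assert_allclose(ref.sum(axis=0), 1.0, atol=1e-6)
        assert (ref.values >= 0).all()
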