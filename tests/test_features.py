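"""Feature extraction: GC, enthalpy, PAM, positional one-hots, registry."""

import itertools
import warnings

import numpy as np
import pytest

import cleavesite as cs
from cleavesite.features import (
    CONTEXT_TRUNCATED_FLAG,
    FEATURE_REGISTRY,
    extended_window,
    feature_columns,
    gc_content,
    nn_enthalpy,
    pam_features,
    positional_nucleotides,
)


class TestGcContent:
    @pytest.mark.parametrize("seq,expect", [("GGCC", 1.0), ("ATAT", 0.0), ("GATC", 0.5)])
    def test_known_values(self, seq, expect):
        assert gc_content(seq) == expect

    def test_n_excluded_both_sides(self):
        assert gc_content("GCNN") == 1.0

    def test_all_n_is_error(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestEnthalpy:
    def test_single_base_no_stacks(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert nn_enthalpy("A") == 0.0

    def test_aa_step_matches_table(self):
        # SantaLucia (1998) unified dH for the AA/TT stack
        assert nn_enthalpy("AA") == -7.9

    def test_additivity_all_64_trinucleotides(self):
        for a, b, c in itertools.product("ACGT", repeat=3):
            tri = a + b + c
            assert nn_enthalpy(tri) == pytest.approx(
                nn_enthalpy(tri[:2]) + nn_enthalpy(tri[1:])
            )

    def test_n_truncates_window(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert nn_enthalpy("AANGG") == nn_enthalpy("AA") + nn_enthalpy("GG")

    def test_strand_symmetry_of_table(self):
        # dH(seq) equals dH(reverse complement): stacks are strand pairs
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=10))
            rc = seq.translate(comp)[::-1]
            assert nn_enthalpy(seq) == pytest.approx(nn_enthalpy(rc))


class TestPamFeatures:
    @pytest.mark.parametrize(
        "pam,ptype", [("TGG", "NGG"), ("AGG", "NGG"), ("AAG", "NAG"), ("TTA", "OTHER")]
    )
    def test_pam_type_by_positions_2_3(self, pam, ptype):
        ctx = "AAAA" + pam + "CCCCCC"
        pf = pam_features(ctx, 4)
        assert pf.pam_type == ptype
        assert pf.pam_n == pam[0]

    def test_downstream_bases(self):
        ctx = "AAAA" + "TGG" + "CGTAC"
        pf = pam_features(ctx, 4)
        assert (pf.downstream_nt_1, pf.downstream_nt_2, pf.downstream_nt_5) == ("C", "G", "C")

    def test_short_context_flags_missing(self):
        pf = pam_features("AAAA" + "TGG" + "CG", 4)
        assert pf.downstream_nt_1 == "C" and pf.downstream_nt_5 is None
        with pytest.raises(ValueError):
            pam_features("AAAATG", 4)  # PAM itself cut off


class TestPositionalNucleotides:
    def test_direct_indexing(self):
        d = positional_nucleotides("ACGTACGTACGTACGTACGT")
        assert d == {
            "nt_position_2": "C",
            "nt_position_4": "T",
            "nt_positions_4_5": "TA",
            "nt_position_20": "T",
        }

    def test_short_guide_position_20_falls_back(self):
        d = positional_nucleotides("ACGTACGTACGTACGTG")  # 17 nt
        assert d["nt_position_20"] == "G"

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            positional_nucleotides("ACGT")


class TestFeatureVector:
    def test_on_target_block_is_clean(self, default_dataset):
        X = default_dataset.features
        labels = default_dataset.labels
        on = X.loc[labels == 1]
        assert (on["mismatches"] == 0).all()
        assert (on["rna_bulges"] == 0).all() and (on["dna_bulges"] == 0).all()
        assert (on["pam_type=NGG"] == 1).all()

    def test_off_targets_always_perturbed(self, default_dataset):
        X = default_dataset.features
        off = X.loc[default_dataset.labels == 0]
        assert ((off["mismatches"] + off["rna_bulges"] + off["dna_bulges"]) >= 1).all()

    def test_pure_function(self, tiny_dataset):
        g = tiny_dataset.guides[0]
        s = tiny_dataset.sites[0]
        a = cs.build_feature_vector(g, s)
        b = cs.build_feature_vector(g, s)
        assert (a == b).all()

    def test_registry_width_and_order(self, default_dataset):
        cols = feature_columns()
        assert list(default_dataset.features.columns) == cols
        expanded = sum(len(s.columns()) for s in FEATURE_REGISTRY) + 1  # + context flag
        assert len(cols) == expanded == 72
        assert len(FEATURE_REGISTRY) == 30

    def test_one_hot_groups_sum_to_one_or_flagged(self, default_dataset):
        X = default_dataset.features
        for spec in FEATURE_REGISTRY:
            if spec.kind != "categorical":
                continue
            group = X[[f"{spec.name}={lv}" for lv in spec.levels]].sum(axis=1)
            if spec.can_be_missing:
                flag = X[f"{spec.name}_missing"]
                assert ((group + flag) == 1).all()
            else:
                assert (group == 1).all()

    def test_gc_range_and_enthalpy_sign(self, default_dataset):
        X = default_dataset.features
        assert X["gc_content_extended"].between(0, 1).all()
        assert (X["dna_enthalpy_223"] < 0).all()  # stacking is exothermic

    def test_guide_site_linkage_checked(self, tiny_dataset):
        with pytest.raises(ValueError):
            cs.build_feature_vector(tiny_dataset.guides[1], tiny_dataset.sites[0])

    def test_bulge_cap_enforced(self):
        rng = np.random.default_rng(0)
        prof = cs.default_profile()
        g = cs.generate_guide(rng, 20, "g1")
        site = cs.embed_on_target(g, rng, prof, "s1")
        # fake a 3-bulge protospacer by shortening it
        import dataclasses

        short = g.sequence[:17]
        ctx = site.context[: site.protospacer_start] + short + site.pam + "A" * 200
        bad = cs.TargetSiteRecord(
            site_id="s1", guide_id="g1", protospacer=short, pam=site.pam,
            context=ctx, label=0, protospacer_start=site.protospacer_start,
        )
        with pytest.raises(ValueError, match="bulges"):
            cs.build_feature_vector(g, bad)


class TestExtendedWindow:
    def test_full_context_passes_through(self, default_dataset):
        s = default_dataset.sites[0]
        assert extended_window(s) == s.context  # generator emits exactly 223 nt

    def test_truncation_flag_set_for_short_context(self):
        proto = "ACGTACGTACGTACGTACGT"
        ctx = "AAAA" + proto + "TGG" + "AAAA"
        site = cs.TargetSiteRecord(
            site_id="s", guide_id="g", protospacer=proto, pam="TGG",
            context=ctx, label=1, protospacer_start=4,
        )
        guide = cs.GuideRecord("g", proto)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vec = cs.build_feature_vector(guide, site)
        assert vec[CONTEXT_TRUNCATED_FLAG] == 1.0

    def test_window_centered_when_context_longer(self):
        proto = "ACGTACGTACGTACGTACGT"
        ctx = "T" * 150 + proto + "AGG" + "T" * 150
        site = cs.TargetSiteRecord(
            site_id="s", guide_id="g", protospacer=proto, pam="AGG",
            context=ctx, label=1, protospacer_start=150,
        )
        w = extended_window(site)
        assert len(w) == 223 and proto in w
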