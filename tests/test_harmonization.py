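import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twosample_mr import (
    HarmonizationError,
    VariantAssociation,
    exclude_snps,
    filter_by_info,
    harmonize,
)
from twosample_mr.synthetic_data import NONPALINDROMIC_PAIRS, PALINDROMIC_PAIRS

from _oracles import harmonize_by_enumeration


def var(rsid, ea, oa, beta, se=0.01, eaf=None, **kw):
    return VariantAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, eaf=eaf, **kw)


class TestHarmonize:
    def test_outcome_label_swap_negates_beta(self):
        exp = [var("rs1", "A", "G", 0.03)]
        out = [var("rs1", "G", "A", 0.10)]
        (inst,) = harmonize(exp, out)
        assert inst.effect_allele == "A"
        assert inst.beta_gd == pytest.approx(-0.10)
        assert inst.allele_flipped

    def test_orients_to_exposure_increasing_allele(self):
        exp = [var("rs1", "C", "T", -0.02)]
        out = [var("rs1", "C", "T", 0.05)]
        (inst,) = harmonize(exp, out)
        assert inst.effect_allele == "T"
        assert inst.beta_gp == pytest.approx(0.02)
        assert inst.beta_gd == pytest.approx(-0.05)

    def test_strand_flip_resolved_for_nonpalindromic(self):
        # outcome reports the complementary strand: A/G vs T/C
        exp = [var("rs1", "A", "G", 0.03, eaf=0.3)]
        out = [var("rs1", "T", "C", 0.07, eaf=0.31)]
        (inst,) = harmonize(exp, out)
        assert inst.beta_gd == pytest.approx(0.07)

    def test_palindromic_frequency_alignment(self):
        # A/T SNP, clearly opposite minor alleles => outcome strand flipped
        exp = [var("rs1", "A", "T", 0.03, eaf=0.10)]
        out = [var("rs1", "A", "T", 0.10, eaf=0.88)]
        (inst,) = harmonize(exp, out, palindromic_policy="frequency")
        assert inst.retained
        assert inst.beta_gd == pytest.approx(-0.10)
        assert inst.eaf_outcome == pytest.approx(0.12)

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp = [var("rs1", "A", "T", 0.03, eaf=0.50)]
        out = [var("rs1", "A", "T", 0.10, eaf=0.52)]
        assert harmonize(exp, out, palindromic_policy="frequency") == []
        (inst,) = harmonize(exp, out, palindromic_policy="frequency",
                            drop_excluded=False)
        assert "ambiguous" in inst.excluded_reason

    def test_palindromic_policies(self):
        exp = [var("rs1", "C", "G", 0.03, eaf=0.10)]
        out = [var("rs1", "C", "G", 0.10, eaf=0.12)]
        assert harmonize(exp, out, palindromic_policy="drop") == []
        (kept,) = harmonize(exp, out, palindromic_policy="keep")
        assert kept.beta_gd == pytest.approx(0.10)
        (freq,) = harmonize(exp, out, palindromic_policy="frequency")
        assert freq.beta_gd == pytest.approx(0.10)  # same-side eaf: no flip

    def test_irreconcilable_alleles_excluded_with_reason(self):
        exp = [var("rs1", "A", "C", 0.03), var("rs2", "A", "G", 0.02)]
        out = [var("rs1", "A", "G", 0.10), var("rs2", "A", "G", 0.05)]
        kept = harmonize(exp, out)
        assert [i.rsid for i in kept] == ["rs2"]
        bad = [i for i in harmonize(exp, out, drop_excluded=False) if not i.retained]
        assert bad[0].rsid == "rs1" and "irreconcilable" in bad[0].excluded_reason

    def test_no_shared_rsids_is_error(self):
        with pytest.raises(HarmonizationError, match="no shared"):
            harmonize([var("rs1", "A", "G", 0.1)], [var("rs2", "A", "G", 0.1)])

    def test_matches_enumeration_oracle_on_randomized_records(self, rng):
        """Brute-force enumeration of the 4 strand/label configurations."""
        n_checked = 0
        for k in range(1000):
            palindromic = rng.random() < 0.3
            pair = (PALINDROMIC_PAIRS if palindromic else NONPALINDROMIC_PAIRS)[
                rng.integers(4 if palindromic else len(NONPALINDROMIC_PAIRS))]
            f = rng.uniform(0.02, 0.98)
            exp = var(f"rs{k}", *pair, rng.normal(0, 0.03), eaf=f)
            # random presentation of the same physical SNP in the outcome
            ea, oa = pair
            beta, eaf = rng.normal(0, 0.1), float(np.clip(f + rng.normal(0, 0.01), 0.01, 0.99))
            if rng.random() < 0.5:  # label swap
                ea, oa, beta, eaf = oa, ea, -beta, 1 - eaf
            if rng.random() < 0.5:  # strand flip
                from _oracles import COMPLEMENT
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            out = var(f"rs{k}", ea, oa, beta, eaf=eaf)

            (inst,) = harmonize([exp], [out], palindromic_policy="frequency",
                                drop_excluded=False)
            expected = harmonize_by_enumeration(exp, out)
            if isinstance(expected, str):
                assert not inst.retained
            else:
                assert inst.retained
                assert inst.beta_gp == pytest.approx(expected[0], abs=1e-12)
                assert inst.beta_gd == pytest.approx(expected[1], abs=1e-12)
                n_checked += 1
        assert n_checked > 500  # most random records should be resolvable

    def test_idempotent(self, rng):
        """Re-harmonizing an already-harmonized pair changes nothing."""
        exp, out = [], []
        for k in range(50):
            pair = NONPALINDROMIC_PAIRS[rng.integers(len(NONPALINDROMIC_PAIRS))]
            f = rng.uniform(0.05, 0.95)
            exp.append(var(f"rs{k}", *pair, rng.normal(0, 0.03), eaf=f))
            out.append(var(f"rs{k}", *pair, rng.normal(0, 0.1),
                           eaf=float(np.clip(f + rng.normal(0, 0.01), 0.01, 0.99))))
        first = harmonize(exp, out)
        exp2 = [var(i.rsid, i.effect_allele, i.other_allele, i.beta_gp,
                    se=i.se_gp, eaf=i.eaf_exposure) for i in first]
        out2 = [var(i.rsid, i.effect_allele, i.other_allele, i.beta_gd,
                    se=i.se_gd, eaf=i.eaf_outcome) for i in first]
        second = harmonize(exp2, out2)
        for a, b in zip(first, second):
            assert (a.effect_allele, a.beta_gp, a.beta_gd) == (
                b.effect_allele, b.beta_gp, b.beta_gd)

    @given(beta_gp=st.floats(-0.1, 0.1, allow_nan=False),
           beta_gd=st.floats(-0.3, 0.3, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_beta_gp_nonnegative_and_ratio_conserved(self, beta_gp, beta_gd):
        """Orientation keeps beta_gp >= 0 and leaves the Wald ratio invariant."""
        exp = [var("rs1", "A", "G", beta_gp)]
        out = [var("rs1", "A", "G", beta_gd)]
        exp_sw = [var("rs1", "G", "A", -beta_gp)]
        out_sw = [var("rs1", "G", "A", -beta_gd)]
        (a,) = harmonize(exp, out)
        (b,) = harmonize(exp_sw, out_sw)
        assert a.beta_gp >= 0 and b.beta_gp >= 0
        if beta_gp != 0:
            assert a.beta_gd / a.beta_gp == pytest.approx(beta_gd / beta_gp, abs=1e-12)
            assert b.beta_gd / b.beta_gp == pytest.approx(beta_gd / beta_gp, abs=1e-12)


class TestFilters:
    def make(self, n):
        exp = [var(f"rs{k}", "A", "G", 0.02 + 0.001 * k) for k in range(n)]
        out = [var(f"rs{k}", "A", "G", 0.05) for k in range(n)]
        return harmonize(exp, out)

    def test_info_filter_counting_pattern(self):
        inst = self.make(97)
        info = {f"rs{k}": 0.5 for k in range(5)}
        assert len(filter_by_info(inst, info, threshold=0.6)) == 92

    def test_info_threshold_is_strict(self):
        inst = self.make(3)
        kept = filter_by_info(inst, {"rs0": 0.6, "rs1": 0.6000001, "rs2": None}, 0.6)
        assert [i.rsid for i in kept] == ["rs1", "rs2"]

    def test_all_high_info_identity(self):
        inst = self.make(10)
        assert filter_by_info(inst, {f"rs{k}": 1.0 for k in range(10)}, 0.6) == inst

    def test_exclude_named_snp(self):
        inst = self.make(97)
        assert len(exclude_snps(inst, ["rs10"])) == 96

    def test_exclude_empty_and_absent(self, caplog):
        inst = self.make(5)
        assert exclude_snps(inst, []) == inst
        with caplog.at_level("WARNING", logger="twosample_mr"):
            assert len(exclude_snps(inst, ["rs_none"])) == 5
        assert "not present" in " ".join(caplog.messages)

    def test_exclude_all_leaves_empty_with_warning(self, caplog):
        inst = self.make(3)
        with caplog.at_level("WARNING", logger="twosample_mr"):
            assert exclude_snps(inst, [i.rsid for i in inst]) == []
        assert "all instruments excluded" in " ".join(caplog.messages)
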