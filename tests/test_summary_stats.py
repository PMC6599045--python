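"""Scale conversions, harmonization, variance explained, and file I/O."""

import math

import pytest
from hypothesis import given, strategies as st

from ivmr.exceptions import (
    ConfigurationError,
    DomainError,
    FrequencyRequiredError,
    HarmonizationError,
    InconsistencyError,
    ValidationError,
)
from ivmr.summary_stats import (
    SnpAssociation,
    harmonize,
    logor_to_or_ci,
    or_ci_to_logor,
    read_sumstats,
    se_from_beta_pvalue,
    variance_explained,
    write_sumstats,
)


def snp(rsid="rs1", ea="C", oa="T", beta=0.243, se=0.025, p=1e-8, eaf=0.64, **kw):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, eaf=eaf, **kw,
    )


class TestOrCiConversions:
    @pytest.mark.parametrize(
        "or_point, lo, hi, exp_logor, exp_se",
        [
            (1.05, 1.02, 1.09, 0.0488, 0.0169),
            (1.07, 0.97, 1.18, 0.0677, 0.0500),
            (1.00, 1.00, 1.00, 0.0, 0.0),
        ],
    )
    def test_or_ci_to_logor(self, or_point, lo, hi, exp_logor, exp_se):
        logor, se = or_ci_to_logor(or_point, lo, hi, 0.95)
        assert logor == pytest.approx(exp_logor, abs=5e-5)
        assert se == pytest.approx(exp_se, abs=5e-5)

    def test_logor_to_or_ci_matches_hand_calculation(self):
        or_point, lo, hi = logor_to_or_ci(0.1943, 0.0480, 0.95)
        assert (round(or_point, 2), round(lo, 2), round(hi, 2)) == (1.21, 1.11, 1.33)

    def test_null_effect_gives_symmetric_ci_on_log_scale(self):
        or_point, lo, hi = logor_to_or_ci(0.0, 0.1, 0.95)
        assert or_point == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_degenerate(self):
        assert logor_to_or_ci(math.log(2), 0.0, 0.95) == pytest.approx((2.0, 2.0, 2.0))

    @pytest.mark.parametrize(
        "args, exc",
        [
            ((0.0, 1.0, 1.0, 0.95), DomainError),
            ((1.0, -1.0, 2.0, 0.95), DomainError),
            ((1.5, 1.6, 1.7, 0.95), InconsistencyError),
        ],
    )
    def test_invalid_inputs(self, args, exc):
        with pytest.raises(exc):
            or_ci_to_logor(*args)

    def test_negative_se_rejected(self):
        with pytest.raises(DomainError):
            logor_to_or_ci(0.1, -0.01)

    @given(
        logor=st.floats(-2, 2),
        se=st.floats(1e-6, 1.0),
        level=st.floats(0.5, 0.999),
    )
    def test_round_trip_identity(self, logor, se, level):
        """or_ci_to_logor inverts logor_to_or_ci to 6 significant figures."""
        back_logor, back_se = or_ci_to_logor(*logor_to_or_ci(logor, se, level), level)
        assert back_logor == pytest.approx(logor, rel=1e-6, abs=1e-9)
        assert back_se == pytest.approx(se, rel=1e-6)


class TestSeFromPvalue:
    def test_consistent_with_published_ci(self):
        # beta 0.27 with 95% CI 0.21-0.32 implies se ~ 0.028; the p-value
        # route from (0.267, 3.1e-22) must land nearby.
        assert se_from_beta_pvalue(0.267, 3.1e-22) == pytest.approx(0.028, abs=0.002)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(DomainError):
            se_from_beta_pvalue(0.0, 0.05)
        with pytest.raises(DomainError):
            se_from_beta_pvalue(0.1, 0.0)


class TestVarianceExplained:
    def test_hand_value(self):
        assert variance_explained(0.64, 0.243) == pytest.approx(0.0272, abs=5e-5)

    def test_monomorphic_is_zero(self):
        assert variance_explained(0.0, 1.3) == 0.0

    def test_table_sum(self, il18_instruments):
        total = sum(variance_explained(r.eaf, r.beta) for r in il18_instruments)
        assert total == pytest.approx(0.062, abs=0.001)

    @given(eaf=st.floats(0.0, 1.0), beta=st.floats(-1, 1))
    def test_symmetric_and_maximized_at_half(self, eaf, beta):
        r2 = variance_explained(eaf, beta)
        assert r2 == pytest.approx(variance_explained(1.0 - eaf, beta), rel=1e-12, abs=1e-15)
        assert r2 <= variance_explained(0.5, beta) + 1e-15

    def test_frequency_required(self):
        with pytest.raises(FrequencyRequiredError):
            variance_explained(None, 0.2)
        with pytest.raises(DomainError):
            variance_explained(1.2, 0.2)


class TestHarmonize:
    def test_already_aligned(self):
        pair = harmonize(snp(beta=0.243), snp(beta=0.049, se=0.017))
        assert pair.action_taken == "none"
        assert pair.outcome.beta == pytest.approx(0.049)

    def test_allele_flip_antisymmetry(self):
        out = snp(ea="T", oa="C", beta=-0.049, se=0.017, eaf=0.36)
        pair = harmonize(snp(beta=0.243), out)
        assert pair.action_taken == "sign_flip"
        assert pair.outcome.beta == pytest.approx(0.049)
        assert pair.outcome.effect_allele == "C"

    def test_strand_complement_match(self):
        out = snp(ea="G", oa="A", beta=0.049, se=0.017)
        pair = harmonize(snp(beta=0.243), out)
        assert pair.action_taken == "strand_flip"
        assert pair.outcome.beta == pytest.approx(0.049)

    def test_palindrome_near_half_dropped(self):
        exp = snp(ea="A", oa="T", eaf=0.49)
        out = snp(ea="A", oa="T", eaf=0.50, beta=0.01, se=0.02)
        pair = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert pair.action_taken == "dropped_palindromic"
        assert pair.dropped

    def test_palindrome_resolved_by_frequency(self):
        exp = snp(ea="C", oa="G", eaf=0.2)
        aligned = harmonize(exp, snp(ea="C", oa="G", eaf=0.22, beta=0.05, se=0.02))
        assert aligned.action_taken == "none"
        flipped = harmonize(exp, snp(ea="C", oa="G", eaf=0.78, beta=0.05, se=0.02))
        assert flipped.action_taken == "sign_flip"
        assert flipped.outcome.beta == pytest.approx(-0.05)

    def test_palindrome_missing_frequency_raises(self):
        with pytest.raises(FrequencyRequiredError):
            harmonize(snp(ea="A", oa="T", eaf=None), snp(ea="A", oa="T", eaf=0.3))

    def test_negative_exposure_reoriented(self):
        pair = harmonize(snp(beta=-0.243), snp(beta=0.049, se=0.017))
        assert pair.exposure.beta == pytest.approx(0.243)
        assert pair.exposure.effect_allele == "T"
        assert pair.outcome.beta == pytest.approx(-0.049)

    def test_opposite_strand_report_is_reconciled(self):
        # C/T and its reverse-strand report G/A describe the same locus
        pair = harmonize(snp(beta=0.243), snp(ea="A", oa="G", beta=-0.05, se=0.02))
        assert pair.action_taken == "sign_flip"
        assert pair.outcome.effect_allele == "C"
        assert pair.outcome.beta == pytest.approx(0.05)

    def test_irreconcilable_alleles(self):
        with pytest.raises(HarmonizationError):
            harmonize(snp(), snp(ea="A", oa="C"))

    def test_rsid_mismatch(self):
        with pytest.raises(ValidationError):
            harmonize(snp(rsid="rs1"), snp(rsid="rs2"))

    def test_idempotent(self):
        out = snp(ea="T", oa="C", beta=-0.049, se=0.017, eaf=0.36)
        once = harmonize(snp(beta=0.243), out)
        twice = harmonize(once.exposure, once.outcome)
        assert twice.action_taken == "none"
        assert twice.exposure == once.exposure
        assert twice.outcome == once.outcome


class TestSnpAssociationInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(se=0.0),
            dict(se=-1.0),
            dict(p=0.0),
            dict(p=1.5),
            dict(eaf=1.2),
            dict(ea="C", oa="C"),
            dict(ea="N"),
        ],
    )
    def test_invalid_records_rejected(self, kw):
        with pytest.raises(ValidationError):
            snp(**kw)


class TestReadSumstats:
    def test_packaged_fixture(self, il18_instruments, ibd_outcomes):
        assert [r.rsid for r in il18_instruments] == [
            "rs385076", "rs17229943", "rs71478720",
        ]
        assert [r.rsid for r in ibd_outcomes] == [r.rsid for r in il18_instruments]
        assert all(r.trait_type == "quantitative" for r in il18_instruments)
        assert all(r.trait_type == "binary" for r in ibd_outcomes)
        # OR 1.05 (1.02-1.09) converts to logor ~ 0.0488, se ~ 0.0169
        nlrc4 = ibd_outcomes[0]
        assert nlrc4.beta == pytest.approx(0.0488, abs=5e-5)
        assert nlrc4.se == pytest.approx(0.0169, abs=5e-5)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("rsid\teffect_allele\tother_allele\tbeta\tse\tpvalue\n")
        assert read_sumstats(path) == []

    def test_zero_se_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "rsid\teffect_allele\tother_allele\tbeta\tse\tpvalue\n"
            "rs1\tC\tT\t0.1\t0.02\t0.01\n"
            "rs2\tC\tT\t0.1\t0\t0.01\n"
        )
        with pytest.raises(ValidationError, match="line 3"):
            read_sumstats(path)

    def test_missing_mapped_column(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("rsid\tea\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path, {"rsid": "rsid", "effect_allele": "ea",
                                 "other_allele": "oa", "beta": "b", "se": "s",
                                 "pvalue": "p"})

    def test_comma_dialect_autodetected(self, tmp_path):
        path = tmp_path / "stats.csv"
        path.write_text(
            "rsid,effect_allele,other_allele,beta,se,pvalue\n"
            "rs1,C,T,0.1,0.02,0.01\n"
        )
        (rec,) = read_sumstats(path)
        assert rec.beta == pytest.approx(0.1)

    def test_write_read_round_trip(self, tmp_path, il18_instruments):
        path = tmp_path / "roundtrip.tsv"
        write_sumstats(il18_instruments, path)
        back = read_sumstats(path, trait_type="quantitative")
        for orig, new in zip(il18_instruments, back):
            assert new.rsid == orig.rsid
            assert new.beta == pytest.approx(orig.beta, rel=1e-12)
            assert new.se == pytest.approx(orig.se, rel=1e-12)
            assert new.eaf == pytest.approx(orig.eaf, rel=1e-12)
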