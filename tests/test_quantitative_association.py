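"""Roll-up, inverse-normal transform, pQTL/PWAS models, regimen classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

from pavprot.gene_model import PavRecord
from pavprot.library_builder import build_libraries
from pavprot.quantitative_association import (
    EPITOPE_EFFECT,
    ROBUST_PQTL,
    UNDERPOWERED,
    PqtlResult,
    QuantError,
    call_mspqtls,
    classify_regimens,
    compare_library_quants,
    inverse_normal,
    pqtl_lm,
    pwas_lm,
    rollup_protein,
)


class TestInverseNormal:
    def test_symmetric_vector_middle_maps_to_zero(self):
        out = inverse_normal([10.0, 20.0, 30.0, 40.0, 50.0])
        assert out[2] == pytest.approx(0.0)
        assert out[0] == pytest.approx(-out[4])

    def test_blom_quantile_oracle_elementwise(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(5, 40))
            ties = rng.random(v.size) < 0.2
            v[ties] = np.round(v[ties], 1)  # introduce ties
            out = inverse_normal(v)
            ranks = rankdata(v, method="average")
            expect = norm.ppf((ranks - 0.375) / (v.size + 0.25))
            np.testing.assert_allclose(out, expect, rtol=1e-12)

    def test_smallest_of_five_distinct(self):
        out = inverse_normal([3.0, 1.0, 4.0, 1.5, 5.0])
        assert out.min() == pytest.approx(norm.ppf((1 - 0.375) / 5.25))
        assert out.min() == pytest.approx(-1.18, abs=0.005)

    def test_monotone_and_mean_zero(self, rng):
        v = rng.normal(size=101)
        out = inverse_normal(v)
        assert np.array_equal(np.argsort(out), np.argsort(v))
        assert abs(out.mean()) < 1e-6

    def test_missing_values_stay_missing(self):
        out = inverse_normal([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_constant_input_rejected(self):
        with pytest.raises(QuantError, match="identical"):
            inverse_normal([2.0, 2.0, 2.0, 2.0])


def _long_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "nanoparticle", "sequence", "quantity"])


class TestRollup:
    PROTEINS = {"P1": "MAAAAAAKDDDSDDRWWWWWWK"}
    PAV = PavRecord("chr1:50:A:G", "P1", 12, "S", "G", 0.3, "rs9")

    def test_single_peptide_protein_equals_peptide_trace(self):
        libs = build_libraries({"P2": "MCCCCCCK"}, [])
        long = _long_frame(
            [("S1", "NP1", "MCCCCCCK", 8.0), ("S2", "NP1", "MCCCCCCK", 32.0)]
        )
        roll = rollup_protein(long, libs.reference, method="median_log")
        assert roll.loc[("P2", "NP1"), "S1"] == pytest.approx(3.0)
        assert roll.loc[("P2", "NP1"), "S2"] == pytest.approx(5.0)

    def test_median_of_equal_peptides(self):
        libs = build_libraries(self.PROTEINS, [])
        long = _long_frame(
            [("S1", "NP1", "MAAAAAAK", 16.0), ("S1", "NP1", "DDDSDDR", 16.0)]
        )
        roll = rollup_protein(long, libs.reference, method="median_log")
        assert roll.loc[("P1", "NP1"), "S1"] == pytest.approx(4.0)

    def test_epitope_scenario_membership_sensitivity(self):
        # ref-allele peptide halves in heterozygotes and is absent in
        # alternate homozygotes; invariant peptides are flat
        libs = build_libraries(self.PROTEINS, [self.PAV])
        rows = []
        for sample, dosage in (("G0", 0), ("G1", 1), ("G2", 2)):
            rows.append((sample, "NP1", "MAAAAAAK", 100.0))
            rows.append((sample, "NP1", "WWWWWWK", 100.0))
            if dosage < 2:
                rows.append((sample, "NP1", "DDDSDDR", 100.0 * (2 - dosage) / 2))
        long = _long_frame(rows)
        ref_roll = rollup_protein(long, libs.reference, method="sum")
        excl_roll = rollup_protein(long, libs.pav_exclusive, method="sum")
        assert ref_roll.loc[("P1", "NP1")].tolist() == [300.0, 250.0, 200.0]
        assert excl_roll.loc[("P1", "NP1")].tolist() == [200.0, 200.0, 200.0]

    def test_nonmember_peptides_never_contribute(self):
        libs = build_libraries(self.PROTEINS, [self.PAV])
        long = _long_frame([("S1", "NP1", "DDDGDDR", 50.0), ("S1", "NP1", "MAAAAAAK", 10.0)])
        roll = rollup_protein(long, libs.pav_exclusive, method="sum")
        assert roll.loc[("P1", "NP1"), "S1"] == pytest.approx(10.0)

    def test_unknown_method_rejected(self):
        libs = build_libraries(self.PROTEINS, [])
        with pytest.raises(QuantError):
            rollup_protein(_long_frame([]), libs.reference, method="mean")


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(18, 80, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(28, 4, n),
            "diabetes": rng.integers(0, 2, n).astype(float),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        }
    )


class TestPqtlLm:
    def test_matches_simple_regression_without_covariates(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.5 * g + rng.normal(size=200)
        res = pqtl_lm(y, g)
        y_t = inverse_normal(y)
        slope = np.polyfit(g, y_t, 1)[0]
        assert res.beta == pytest.approx(slope, abs=1e-8)

    def test_constant_genotype_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(QuantError, match="constant"):
            pqtl_lm(rng.normal(size=50), np.ones(50), _covariates(rng, 50))

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(1)
        cov = _covariates(rng, 60)
        cov["bmi2"] = cov["bmi"]  # exact collinearity
        g = rng.binomial(2, 0.3, 60).astype(float)
        with pytest.raises(QuantError, match="bmi"):
            pqtl_lm(rng.normal(size=60), g, cov)

    def test_too_few_complete_cases_rejected(self):
        rng = np.random.default_rng(2)
        y = np.full(50, np.nan)
        y[:5] = rng.normal(size=5)
        with pytest.raises(QuantError, match="complete cases"):
            pqtl_lm(y, rng.binomial(2, 0.3, 50), _covariates(rng, 50))

    def test_missing_protein_values_excluded_not_zeroed(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 300).astype(float)
        y = 0.8 * g + rng.normal(size=300)
        y_missing = y.copy()
        drop = rng.random(300) < 0.2
        y_missing[drop] = np.nan
        res = pqtl_lm(y_missing, g)
        assert res.n == int((~drop).sum())


class TestCallMspqtls:
    def _res(self, p):
        return PqtlResult("v", "P", "pav_exclusive", 0.5, 0.1, p, 300)

    def test_strict_genome_wide_threshold(self):
        called = call_mspqtls([self._res(4.9e-8), self._res(5e-8)])
        assert len(called) == 1
        assert called.iloc[0]["p_y"] == pytest.approx(4.9e-8)

    def test_empty_input(self):
        assert call_mspqtls([]).empty


class TestClassifyRegimens:
    def _pair(self, p_ref, p_excl):
        ref = PqtlResult("v", "P", "reference", 0.5, 0.1, p_ref, 300)
        excl = PqtlResult("v", "P", "pav_exclusive", 0.5, 0.1, p_excl, 300)
        return ref, excl

    @pytest.mark.parametrize(
        "p_ref,p_excl,regimen,discordant",
        [
            (1e-10, 1e-9, ROBUST_PQTL, False),
            (1e-10, 0.4, EPITOPE_EFFECT, False),
            (0.5, 0.9, UNDERPOWERED, False),
            (0.4, 1e-10, ROBUST_PQTL, True),
        ],
    )
    def test_rule_application(self, p_ref, p_excl, regimen, discordant):
        call = classify_regimens(*self._pair(p_ref, p_excl), threshold=5e-8)
        assert call.regimen == regimen
        assert call.discordant is discordant


class TestPwas:
    def test_age_effect_recovered(self):
        rng = np.random.default_rng(9)
        cov = _covariates(rng, 300)
        beta_age = 0.03
        y = beta_age * cov["age"].to_numpy() + rng.normal(0, 0.5, 300)
        # the transform standardizes the outcome; compare on the standardized scale
        scale = np.std(beta_age * cov["age"].to_numpy()) ** 2 + 0.25
        out = pwas_lm(y, cov)
        age = out.set_index("determinant").loc["age"]
        expect = beta_age / np.sqrt(scale)
        assert abs(age["coef"] - expect) < 2 * age["se"]
        assert age["p"] < 1e-10

    def test_all_null_type_one_error(self):
        rng = np.random.default_rng(10)
        hits = total = 0
        for _ in range(100):
            cov = _covariates(rng, 80)
            y = rng.normal(size=80)
            out = pwas_lm(y, cov)
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_insufficient_cases_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(QuantError):
            pwas_lm(rng.normal(size=6), _covariates(rng, 6))


class TestCompareLibraryQuants:
    def test_identical_matrices(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 20)), index=[f"P{i}" for i in range(5)])
        rho, summary = compare_library_quants(m, m.copy())
        assert (rho == 1.0).all()
        assert summary["frac_high"] == 1.0 and summary["n_low"] == 0

    def test_permuted_values_uncorrelated(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 40)), index=[f"P{i}" for i in range(30)])
        shuffled = m.copy()
        for i in range(len(m)):
            shuffled.iloc[i] = rng.permutation(shuffled.iloc[i].to_numpy())
        rho, summary = compare_library_quants(m, shuffled)
        assert abs(rho.median()) < 0.2

    def test_insufficient_overlap_excluded(self, rng, caplog):
        a = pd.DataFrame(rng.normal(size=(2, 5)), index=["P1", "P2"])
        b = a.copy()
        b.iloc[0, 2:] = np.nan  # only 2 shared observations for P1
        with caplog.at_level("WARNING"):
            rho, summary = compare_library_quants(a, b)
        assert "P1" not in rho.index
        assert summary["n_excluded"] == 1
        assert summary["n_compared"] == 1
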