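"""Chi-square DE machinery, correlations, composition and qPCR/morphology
summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatmir.expression import (
    Contrast,
    ExpressionMatrix,
    call_differential,
    chisq_test,
    composition_stats,
    ddct_fold_change,
    de_overlap_table,
    dvalue_summary,
    replicate_correlation,
    tissue_specificity,
)
from heatmir.oracles import chi2_closed_form


class TestChisq:
    def test_worked_example(self):
        chi2, p = chisq_test(100, 10**6, 50, 10**6)
        assert chi2 == pytest.approx(16.67, abs=0.01)
        assert p == pytest.approx(4.5e-5, rel=0.02)

    def test_identical_proportions(self):
        assert chisq_test(50, 10**6, 50, 10**6) == (0.0, 1.0)

    def test_symmetry(self):
        x1, p1 = chisq_test(120, 10**6, 30, 2 * 10**6)
        x2, p2 = chisq_test(30, 2 * 10**6, 120, 10**6)
        assert x1 == pytest.approx(x2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_closed_form_on_random_tables(self, rng):
        """Implementation (scipy contingency) vs the textbook
        N(ad-bc)^2/margins closed form, to 1e-9 relative."""
        for _ in range(200):
            ta, tb = int(rng.integers(10, 10**6)), int(rng.integers(10, 10**6))
            a, b = int(rng.integers(0, ta + 1)), int(rng.integers(0, tb + 1))
            chi2, _ = chisq_test(a, ta, b, tb)
            ref = chi2_closed_form(a, ta, b, tb)
            assert chi2 == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("args", [(-1, 10, 0, 10), (11, 10, 0, 10), (0, 0, 1, 10)])
    def test_invalid_tables_rejected(self, args):
        with pytest.raises(ValueError):
            chisq_test(*args)

    @given(
        st.integers(0, 1000), st.integers(0, 1000),
        st.integers(1, 10**6), st.integers(1, 10**6),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_property(self, a, b, ta, tb):
        ta, tb = ta + a, tb + b  # guarantee count <= total
        x1, p1 = chisq_test(a, ta, b, tb)
        x2, p2 = chisq_test(b, tb, a, ta)
        assert x1 == pytest.approx(x2, rel=1e-12, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-12)


def _matrix(counts_by_mirna, totals):
    counts = pd.DataFrame(counts_by_mirna).T
    tpm = counts.div(pd.Series(totals)[counts.columns], axis=1) * 1e6
    return ExpressionMatrix(counts=counts, tpm=tpm, totals=pd.Series(totals))


class TestCallDifferential:
    TOTALS = {"hs1": 10**6, "hs2": 10**6, "ck1": 10**6, "ck2": 10**6}
    CONTRAST = Contrast("t", ("hs1", "hs2"), ("ck1", "ck2"))

    def test_up_call(self):
        m = _matrix({"m1": {"hs1": 40, "hs2": 40, "ck1": 10, "ck2": 10}}, self.TOTALS)
        (r,) = call_differential(m, self.CONTRAST)
        assert r.call == "up"
        assert r.log2fc == pytest.approx(2.0, abs=0.1)
        assert r.p < 0.001

    def test_small_fold_change_not_called(self):
        m = _matrix(
            {"m1": {"hs1": 1500, "hs2": 1500, "ck1": 1000, "ck2": 1000}}, self.TOTALS
        )
        (r,) = call_differential(m, self.CONTRAST)
        assert r.p < 0.001 and abs(r.log2fc) < 1
        assert r.call == "ns"

    def test_twofold_but_nonsignificant_not_called(self):
        m = _matrix({"m1": {"hs1": 3, "hs2": 3, "ck1": 1, "ck2": 1}}, self.TOTALS)
        (r,) = call_differential(m, self.CONTRAST)
        assert abs(r.log2fc) >= 1 and r.p > 0.05
        assert r.call == "ns"

    def test_contrast_antisymmetry(self):
        m = _matrix({"m1": {"hs1": 80, "hs2": 70, "ck1": 20, "ck2": 25}}, self.TOTALS)
        (fwd,) = call_differential(m, self.CONTRAST)
        (rev,) = call_differential(m, Contrast("r", ("ck1", "ck2"), ("hs1", "hs2")))
        assert fwd.log2fc == pytest.approx(-rev.log2fc, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)

    def test_zero_counts_stay_finite(self):
        m = _matrix({"m1": {"hs1": 0, "hs2": 0, "ck1": 50, "ck2": 50}}, self.TOTALS)
        (r,) = call_differential(m, self.CONTRAST)
        assert np.isfinite(r.log2fc)
        assert r.call == "down"

    def test_missing_condition_rejected(self):
        m = _matrix({"m1": {"hs1": 1, "ck1": 1}}, {"hs1": 100, "ck1": 100})
        with pytest.raises(ValueError, match="missing"):
            call_differential(m, Contrast("bad", ("nope",), ("ck1",)))

    def test_per_replicate_policy(self):
        m = _matrix({"m1": {"hs1": 40, "hs2": 40, "ck1": 10, "ck2": 10}}, self.TOTALS)
        (r,) = call_differential(m, self.CONTRAST, replicate_policy="per_replicate")
        assert r.call == "up"


class TestReplicateCorrelation:
    def test_identical_columns(self):
        tpm = pd.DataFrame({"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0]})
        out = replicate_correlation(tpm, [("a", "b")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 3.0, 7.0])
        y = 2.0 ** (np.log2(1 + x).max() + np.log2(1 + x).min() - np.log2(1 + x)) - 1
        tpm = pd.DataFrame({"a": x, "b": y})
        out = replicate_correlation(tpm, [("a", "b")])
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_independent_poisson_uncorrelated(self, rng):
        tpm = pd.DataFrame(
            {"a": rng.poisson(50, 500).astype(float), "b": rng.poisson(50, 500).astype(float)}
        )
        out = replicate_correlation(tpm, [("a", "b")])
        assert abs(out.loc[0, "r"]) < 0.2

    def test_zero_variance_flagged_not_raised(self):
        tpm = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 5.0, 9.0]})
        out = replicate_correlation(tpm, [("a", "b")])
        assert bool(out.loc[0, "undefined"]) is True
        assert np.isnan(out.loc[0, "r"])


class TestTissueSpecificity:
    def test_labels(self):
        totals = {"s1": 10**6, "p1": 10**6}
        m = _matrix(
            {
                "m_spec": {"s1": 120, "p1": 0},
                "m_pref": {"s1": 400, "p1": 90},
                "m_shared": {"s1": 100, "p1": 95},
            },
            totals,
        )
        out = tissue_specificity(m, {"stamen": ("s1",), "pistil": ("p1",)})
        assert out.loc["m_spec", "label"] == "stamen-specific"
        assert out.loc["m_pref", "label"] == "stamen-preferential"
        assert out.loc["m_shared", "label"] == "shared"


class TestComposition:
    def test_single_length_class(self):
        counts = pd.DataFrame({"l": [3, 7]}, index=["A" * 24, "C" * 24])
        comp = composition_stats(counts)
        assert comp.length_dist.loc[24, "l"] == 1.0

    def test_first_nucleotide_fraction(self):
        # 5 of 10 reads start with U (T-form tags)
        counts = pd.DataFrame({"l": [5, 5]}, index=["T" + "C" * 20, "G" + "C" * 20])
        comp = composition_stats(counts)
        assert comp.first_nt.loc["U", "l"] == pytest.approx(0.5)

    def test_positional_frequencies_sum_to_one(self, rng):
        tags = ["".join("ACGT"[i] for i in rng.integers(0, 4, 21)) for _ in range(50)]
        counts = pd.DataFrame({"l": rng.integers(1, 100, 50)}, index=tags)
        comp = composition_stats(counts)
        sums = comp.positional.sum(axis=0)
        assert np.allclose(sums[:21], 1.0, atol=1e-9)


class TestDdct:
    def test_worked_examples(self):
        assert ddct_fold_change(20, 18, 22, 18) == pytest.approx(4.0)
        assert ddct_fold_change(20, 20, 20, 20) == pytest.approx(1.0)
        assert ddct_fold_change(24, 18, 22, 18) == pytest.approx(0.25)

    def test_replicate_triplets_propagate_se(self):
        res = ddct_fold_change(
            [20.1, 20.0, 19.9], [18.0, 18.1, 17.9], [22.0, 22.1, 21.9], [18.0, 18.0, 18.0]
        )
        assert res.n == 3
        assert res.fold_change == pytest.approx(4.0, rel=0.15)
        assert res.se_ddct > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan, 18, 22, 18)


class TestDvalue:
    def test_mean_difference(self):
        res = dvalue_summary([8.0, 8.0, 8.0], [8.37, 8.37, 8.37])
        assert res.d == pytest.approx(-0.37)
        assert res.undefined_variance

    def test_identical_samples(self):
        res = dvalue_summary([8.0, 8.0, 8.0], [8.0, 8.0, 8.0])
        assert res.d == 0.0 and res.p == 1.0

    def test_shifted_normals_detected(self, rng):
        """Monte-Carlo check: a -0.37 mm shift with sigma 0.1 and n=10 is
        reliably significant."""
        s = rng.normal(8.0, 0.1, 10)
        p = rng.normal(8.37, 0.1, 10)
        res = dvalue_summary(s, p)
        assert res.d < 0
        assert res.p < 0.05

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            dvalue_summary([8.0, 8.1], [8.3, 8.4, 8.5])


def test_overlap_table_membership():
    from heatmir.expression import DEResult

    def r(name, call, contrast):
        return DEResult(
            mirna=name, contrast=contrast, tpm_a=1, tpm_b=1,
            log2fc=-2.0 if call != "ns" else 0.0,
            chi2=10.0, p=0.001 if call != "ns" else 0.9, q=1.0, call=call,
        )

    table = de_overlap_table(
        {
            "c1": [r("mA", "down", "c1"), r("mB", "down", "c1")],
            "c2": [r("mA", "down", "c2"), r("mB", "ns", "c2")],
        }
    )
    assert bool(table.loc["mA", "c1"]) and bool(table.loc["mA", "c2"])
    assert table.loc["mA", "n_contrasts"] == 2
    assert table.loc["mB", "n_contrasts"] == 1
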