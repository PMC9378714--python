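"""Reading, windowing, harmonisation and conditional adjustment of sumstats."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colocscreen.ldpanel import LDMatrix
from colocscreen.sumstats import (
    Region,
    SumstatsError,
    conditional_adjust,
    extract_region,
    harmonise_pair,
    read_sumstats,
    study_coverage_filter,
    table_from_arrays,
)

IDENTITY_MAP = {
    "variant": "ID", "chrom": "CHR", "pos": "POS", "ea": "EA", "nea": "NEA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "p": "P", "n": "N",
    "coverage": "COVERAGE",
}

HEADER = "ID CHR POS EA NEA EAF BETA SE P N COVERAGE"


def _read(text, **kw):
    return read_sumstats(io.StringIO(textwrap.dedent(text)), "t", "quantitative",
                         IDENTITY_MAP, **kw)


class TestReadSumstats:
    def test_lowercase_alleles_uppercased_and_values_kept(self):
        # the lead ELF5 cis-pQTL row, as printed with lowercase alleles
        t = _read(f"{HEADER}\nrs766826 11 34500000 t c 0.36 -0.07 0.01 5.38e-6 10708 1\n")
        rec = next(t.records())
        assert (rec.variant.ea, rec.variant.nea) == ("T", "C")
        assert rec.variant.eaf == 0.36
        assert rec.beta == -0.07
        assert rec.se == 0.01

    def test_header_only_is_fatal(self):
        with pytest.raises(SumstatsError, match="zero valid rows"):
            _read(f"{HEADER}\n")

    def test_degenerate_rows_dropped(self):
        # se=0 and a non-ACGT allele both dropped, valid row kept
        t = _read(
            f"{HEADER}\n"
            "rs1 1 100 A G 0.5 0.1 0.0 0.5 100 1\n"
            "rs2 1 200 A I 0.5 0.1 0.1 0.5 100 1\n"
            "rs3 1 300 A G 0.5 0.1 0.1 0.5 100 1\n"
        )
        assert list(t.variant_ids) == ["rs3"]

    def test_missing_required_column_fatal(self):
        with pytest.raises(SumstatsError, match="missing required columns"):
            read_sumstats(io.StringIO("ID CHR POS\nrs1 1 2\n"), "t",
                          "quantitative", IDENTITY_MAP)

    def test_coverage_denominator_converts_counts(self):
        t = _read(f"{HEADER}\nrs1 1 100 A G 0.5 0.1 0.1 0.5 100 8\n",
                  coverage_denominator=10)
        assert next(t.records()).coverage == pytest.approx(0.8)


def _toy_table(ids, pos, ea, nea, eaf, beta, label="t1"):
    k = len(ids)
    return table_from_arrays(
        label, "quantitative", ids, "1", pos, ea, nea, eaf, beta,
        se=[0.1] * k, p=[0.5] * k, n=100,
    )


class TestExtractRegion:
    @pytest.mark.parametrize(
        "pos,kept",
        [(500_000, True), (499_999, False), (1_500_000, True), (1_500_001, False)],
    )
    def test_inclusive_boundaries(self, pos, kept):
        t = _toy_table(["v1"], [pos], ["A"], ["G"], [0.3], [0.1])
        out = extract_region(t, Region("1", 1_000_000, 1_000_000, "g"), 500_000)
        assert (len(out) == 1) is kept

    def test_zero_flank_keeps_only_anchor_interval(self):
        t = _toy_table(["a", "b", "c"], [99, 100, 101], "AAA", "GGG",
                       [0.3] * 3, [0.1] * 3)
        out = extract_region(t, Region("1", 100, 100, "g"), 0)
        assert list(out.variant_ids) == ["b"]


class TestHarmonise:
    def _pair(self):
        t1 = _toy_table(["v1", "v2", "v3"], [100, 200, 300], ["A", "A", "C"],
                        ["G", "T", "T"], [0.2, 0.45, 0.2], [0.1, 0.2, 0.3])
        t2 = _toy_table(["v1", "v2", "v3"], [100, 200, 300], ["G", "A", "C"],
                        ["A", "T", "T"], [0.8, 0.45, 0.2], [0.1, 0.2, 0.3], "t2")
        return t1, t2

    def test_allele_swap_flips_beta_and_eaf(self):
        t1, t2 = self._pair()
        h1, h2 = harmonise_pair(t1, t2)
        row = h2.df.set_index("ID").loc["v1"]
        assert row["BETA"] == pytest.approx(-0.1)
        assert row["EAF"] == pytest.approx(0.2)
        assert (row["EA"], row["NEA"]) == ("A", "G")

    def test_palindromic_in_band_dropped(self):
        t1, t2 = self._pair()
        h1, _ = harmonise_pair(t1, t2)
        assert "v2" not in h1.variant_ids  # A/T with MAF 0.45
        assert "v3" in h1.variant_ids      # C/T is not palindromic

    def test_self_harmonisation_is_identity(self):
        t1, _ = self._pair()
        h1, h2 = harmonise_pair(t1, t1, drop_palindromic_maf_band=None)
        pd.testing.assert_frame_equal(h1.df, t1.df)
        pd.testing.assert_frame_equal(h2.df, t1.df)

    def test_idempotent(self):
        t1, t2 = self._pair()
        once = harmonise_pair(t1, t2)
        twice = harmonise_pair(*once)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a.df, b.df)

    def test_commutes_with_region_extraction(self):
        t1, t2 = self._pair()
        reg = Region("1", 100, 200, "g")
        a1, a2 = harmonise_pair(extract_region(t1, reg, 0), extract_region(t2, reg, 0))
        b1, b2 = (extract_region(t, reg, 0) for t in harmonise_pair(t1, t2))
        pd.testing.assert_frame_equal(a1.df, b1.df)
        pd.testing.assert_frame_equal(a2.df, b2.df)

    def test_incompatible_alleles_dropped(self):
        t1 = _toy_table(["v1"], [100], ["A"], ["G"], [0.2], [0.1])
        t2 = _toy_table(["v1"], [100], ["A"], ["C"], [0.2], [0.1], "t2")
        with pytest.raises(SumstatsError):
            harmonise_pair(t1, t2)


class TestCoverageFilter:
    def test_threshold_and_missing_rule(self):
        t = table_from_arrays(
            "t", "binary", ["a", "b", "c"], "1", [1, 2, 3], "AAA", "GGG",
            [0.1] * 3, [0.1] * 3, [0.1] * 3, [0.5] * 3, 100,
            coverage=[0.79, np.nan, 1.0],
        )
        out = study_coverage_filter(t, 0.8)
        assert list(out.variant_ids) == ["b", "c"]

    def test_full_coverage_unchanged(self):
        t = table_from_arrays("t", "binary", ["a", "b"], "1", [1, 2], "AA", "GG",
                              [0.1] * 2, [0.1] * 2, [0.1] * 2, [0.5] * 2, 100,
                              coverage=[1.0, 1.0])
        assert len(study_coverage_filter(t)) == 2


def _ld_and_table(R, z, ids=None):
    q = len(z)
    ids = ids or [f"v{i}" for i in range(q)]
    ld = LDMatrix(ids, R)
    se = np.full(q, 0.1)
    t = table_from_arrays("t", "quantitative", ids, "1", range(100, 100 + q),
                          ["A"] * q, ["G"] * q, [0.3] * q, np.asarray(z) * se,
                          se, 2 * stats.norm.sf(np.abs(z)), 1000)
    return t, ld


class TestConditionalAdjust:
    def test_empty_lead_set_is_identity(self):
        t, ld = _ld_and_table(np.eye(3), [1.0, 2.0, 3.0])
        out = conditional_adjust(t, ld, [])
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_self_conditioning_zeroes_lead(self):
        t, ld = _ld_and_table(np.eye(3), [1.0, 2.0, 3.0])
        out = conditional_adjust(t, ld, ["v1"])
        assert out.df.set_index("ID").loc["v1", "BETA"] == 0.0

    def test_identity_ld_leaves_non_leads(self):
        t, ld = _ld_and_table(np.eye(3), [1.0, 2.0, 3.0])
        out = conditional_adjust(t, ld, ["v0"])
        z = (out.df["BETA"] / out.df["SE"]).to_numpy()
        assert z[1:] == pytest.approx([2.0, 3.0])

    def test_matches_ols_residualisation_oracle(self, rng):
        # construct genotypes whose sample correlation is exactly R, so the
        # summary-level adjustment must equal explicit OLS residualisation
        q, n = 5, 4000
        A = rng.standard_normal((q, q))
        C = A @ A.T + 5 * np.eye(q)
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        X = rng.standard_normal((n, q))
        X = X - X.mean(0)
        X = X @ np.linalg.inv(np.linalg.cholesky(np.cov(X, rowvar=False, bias=True)).T)
        X = X @ np.linalg.cholesky(R).T  # now X'X/n == R exactly
        y = X @ np.array([0.5, 0.0, 0.0, -0.3, 0.0]) + rng.standard_normal(n)
        z_marg = np.sqrt(n) * (X.T @ y) / n / y.std()
        leads = [0, 3]
        Xs = X[:, leads]
        resid = y - Xs @ np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
        z_oracle = np.sqrt(n) * (X.T @ resid) / n / y.std()
        z_oracle[leads] = 0.0

        t, ld = _ld_and_table(R, z_marg)
        out = conditional_adjust(t, ld, ["v0", "v3"])
        z_adj = (out.df["BETA"] / out.df["SE"]).to_numpy()
        np.testing.assert_allclose(z_adj, z_oracle, atol=1e-8)

    def test_collinear_leads_fatal(self):
        R = np.ones((3, 3)) * 0.9999999999
        np.fill_diagonal(R, 1.0)
        t, ld = _ld_and_table(R, [1.0, 2.0, 3.0])
        with pytest.raises(SumstatsError, match="collinear"):
            conditional_adjust(t, ld, ["v0", "v1"], max_condition_number=1e6)


def test_p_z_consistency_on_simulated_records(panel, ld):
    """|z| reconstructed from simulated p-values agrees with beta/se within 10%."""
    from colocscreen.simulate import Scenario, simulate_sumstats

    mid = panel.variant_ids[50]
    tabs, _ = simulate_sumstats(panel, Scenario("H4", {mid: 0.01}, {mid: 0.01}, seed=5),
                                ld=ld)
    for t in tabs:
        z = np.abs(t.zscores())
        z_from_p = stats.norm.isf(t.df["P"].to_numpy() / 2)
        ok = z_from_p > 0.1  # inverse map is ill-conditioned at p ~ 1
        assert np.all(np.abs(z[ok] - z_from_p[ok]) <= 0.1 * np.maximum(z[ok], z_from_p[ok]))
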