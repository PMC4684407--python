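"""Expression preprocessing, differential tests, overlay and candidate selection."""

import math
import subprocess
import sys
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from pathring.model import BioEntity, BioRelation, Evidence, PathwayMap
from pathring.overlay import (
    ColorScale,
    ExpressionMatrix,
    benjamini_hochberg,
    fit_variance_prior,
    minimum_signal_filter,
    moderated_t,
    ordinary_t,
    overlay_map,
    preprocess,
    quantile_normalize,
    select_candidates,
    trigamma_inverse,
)
from pathring.simulate import ExprSimSpec, synth_expression


def make_matrix(values, features=None, n1=None, log2_scale=True):
    values = np.asarray(values, dtype=float)
    n1 = n1 if n1 is not None else values.shape[1] // 2
    n2 = values.shape[1] - n1
    samples = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    features = features or [f"f{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        groups=pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples),
        log2_scale=log2_scale,
    )


class TestPreprocess:
    def test_duplicate_rows_averaged_then_log2(self):
        m = make_matrix([[4, 8], [4, 8]], features=["a", "a"], n1=1, log2_scale=False)
        out = preprocess(m)
        assert out.values.shape == (1, 2)
        assert out.values.loc["a"].tolist() == pytest.approx([2.0, 3.0])
        assert out.log2_scale

    def test_all_ones_become_zero(self):
        out = preprocess(make_matrix([[1, 1, 1, 1]], n1=2, log2_scale=False))
        assert (out.values == 0).all().all()

    def test_triplicate_mean_then_log2(self):
        # replicates 2, 4, 6 average to 4 -> log2 = 2 in every sample
        m = make_matrix(
            [[2, 2], [4, 4], [6, 6]], features=["x", "x", "x"], n1=1, log2_scale=False
        )
        out = preprocess(m)
        assert out.values.loc["x"].tolist() == pytest.approx([2.0, 2.0])

    def test_nonpositive_value_names_feature(self):
        m = make_matrix([[1, 2], [0, 5]], features=["ok", "bad"], n1=1, log2_scale=False)
        with pytest.raises(ValueError, match="bad"):
            preprocess(m)

    def test_minimum_signal_filter_drops_all_low_rows(self):
        m = make_matrix([[0.5, 0.8], [0.5, 2.0]], features=["lo", "hi"], n1=1,
                        log2_scale=False)
        out = minimum_signal_filter(m, threshold=1.0)
        assert list(out.values.index) == ["hi"]


class TestQuantileNormalize:
    def test_two_column_mean_of_order_statistics(self):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 6.0]]), n1=1)
        out = quantile_normalize(m)
        assert out.values.iloc[:, 0].tolist() == pytest.approx([1.5, 4.5])
        assert out.values.iloc[:, 1].tolist() == pytest.approx([1.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_matrix(np.column_stack([col, col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_columns_share_sorted_vector_and_preserve_ranks(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(50, 6)), n1=3)
        out = quantile_normalize(m)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            np.testing.assert_array_equal(np.sort(arr[:, j]), ref)
            assert (
                stats.rankdata(arr[:, j]).tolist()
                == stats.rankdata(m.values.to_numpy()[:, j]).tolist()
            )

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(30, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )

    def test_single_sample_is_noop_with_warning(self):
        m = make_matrix(np.array([[1.0], [2.0]]), n1=1)
        m.groups[:] = "g1"  # bypass the two-group check; QN is group-agnostic
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)


class TestOrdinaryT:
    def test_identical_group_means_give_zero_statistic(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], n1=3)
        out = ordinary_t(m)
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates_statistic_and_logfc(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(20, 6))
        fwd = ordinary_t(make_matrix(vals, n1=3))
        swapped = make_matrix(vals[:, [3, 4, 5, 0, 1, 2]], n1=3)
        rev = ordinary_t(swapped)
        np.testing.assert_allclose(fwd["statistic"], -rev["statistic"], atol=1e-12)
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(50, 6))
        out = ordinary_t(make_matrix(vals, n1=3))
        ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(out["statistic"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(out["p_value"], ref.pvalue, atol=1e-12)

    def test_zero_variance_everywhere_is_undefined(self):
        m = make_matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], n1=3)
        out = ordinary_t(m)
        assert math.isnan(out["statistic"].iloc[0])
        assert math.isnan(out["p_value"].iloc[0])

    def test_ranking_agrees_with_exhaustive_permutation_oracle(self):
        # 20 features with a spread of effects; the exact permutation test
        # over all C(6,3) relabelings should order them like the t p-values
        rng = np.random.default_rng(4)
        effects = np.linspace(0, 4, 20)
        vals = rng.normal(size=(20, 6)) * 0.5
        vals[:, :3] += effects[:, None]
        m = make_matrix(vals, n1=3)
        out = ordinary_t(m)

        def perm_p(row):
            obs = abs(stats.ttest_ind(row[:3], row[3:], equal_var=True).statistic)
            count = 0
            total = 0
            for idx in combinations(range(6), 3):
                g1 = row[list(idx)]
                g2 = row[[i for i in range(6) if i not in idx]]
                t = abs(stats.ttest_ind(g1, g2, equal_var=True).statistic)
                count += t >= obs - 1e-12
                total += 1
            return count / total

        perm = np.array([perm_p(vals[i]) for i in range(20)])
        # the permutation p has 1/20 granularity and floors at 2/20, so many
        # strong features tie at the minimum; wherever it does distinguish two
        # features, the parametric p must order them the same way
        param = out["p_value"].to_numpy()
        for i in range(20):
            for j in range(20):
                if perm[i] < perm[j]:
                    assert param[i] < param[j], (i, j)


def oracle_moderated(vals, n1):
    """Literal transcription of the moderated-t formulas, independent code path.

    Shrinks each pooled variance toward a prior fitted by matching the mean
    and variance of log s² under the scaled-F marginal; the trigamma
    inversion uses bracketed root-finding rather than Newton iteration.
    """
    g1, g2 = vals[:, :n1], vals[:, n1:]
    n2 = g2.shape[1]
    d = n1 + n2 - 2
    logfc = g1.mean(1) - g2.mean(1)
    s2 = (g1.var(1, ddof=1) * (n1 - 1) + g2.var(1, ddof=1) * (n2 - 1)) / d
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    assert evar > 0, "oracle expects heterogeneous variances"
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - evar, 1e-6, 1e8, xtol=1e-14
    )
    d0 = 2 * half_d0
    s0_2 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
    t = logfc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df=d + d0)
    return d0, s0_2, t, p


def heterogeneous_matrix(seed, n=1000, d0=8.0, s0=0.25, n1=3, n2=3):
    rng = np.random.default_rng(seed)
    sigma2 = s0 * d0 / rng.chisquare(d0, size=n)
    vals = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n, n1 + n2))
    vals += rng.normal(7, 2, size=n)[:, None]
    return vals


class TestModeratedT:
    def test_matches_independent_formula_oracle(self):
        vals = heterogeneous_matrix(seed=7)
        m = make_matrix(vals, n1=3)
        out = moderated_t(m)
        d0, s0_2, t, p = oracle_moderated(vals, n1=3)
        assert out.attrs["d0"] == pytest.approx(d0, abs=1e-6)
        assert out.attrs["s0_2"] == pytest.approx(s0_2, abs=1e-6)
        np.testing.assert_allclose(out["statistic"], t, atol=1e-6)
        np.testing.assert_allclose(out["p_value"], p, atol=1e-6)

    def test_matches_bioconductor_limma(self, tmp_path):
        """Cross-check hyperparameters, t and p against limma's eBayes."""
        vals = heterogeneous_matrix(seed=13, n=400)
        m = make_matrix(vals, n1=3)
        expr_path = tmp_path / "expr.tsv"
        m.values.to_csv(expr_path, sep="\t")
        r_out = tmp_path / "limma.tsv"
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{expr_path}", row.names=1))\n'
            'design <- cbind(Intercept=1, G1vsG2=c(1,1,1,0,0,0))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(logFC=fit$coefficients[,2], t=fit$t[,2],'
            ' p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{r_out}", sep="\\t", quote=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(r_out, sep="\t", index_col=0)
        out = moderated_t(m)
        assert out.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert out.attrs["s0_2"] == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(out["statistic"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(out["p_value"], ref["p"], atol=1e-8)

    def test_small_d0_approaches_ordinary_t(self):
        # very heterogeneous variances -> tiny prior df -> near-ordinary t
        vals = heterogeneous_matrix(seed=5, n=2000, d0=0.05)
        m = make_matrix(vals, n1=3)
        mod = moderated_t(m)
        ordn = ordinary_t(m)
        assert mod.attrs["d0"] < 1.0
        # shrinkage weight d0/(d0+d) is small, so statistics are close
        rho = stats.spearmanr(mod["statistic"], ordn["statistic"]).statistic
        assert rho > 0.99

    def test_homogeneous_variances_give_infinite_prior(self):
        # identical pooled variances -> d0 = inf, every posterior variance
        # collapses onto s0^2 = the common variance
        rng = np.random.default_rng(21)
        vals = rng.normal(0, 0.5, size=(200, 6))
        # rescale each feature's within-group residuals to pooled s^2 = 0.25
        g1, g2 = vals[:, :3], vals[:, 3:]
        resid = np.concatenate(
            [g1 - g1.mean(1, keepdims=True), g2 - g2.mean(1, keepdims=True)], axis=1
        )
        s2 = (resid**2).sum(1) / 4
        vals = np.concatenate(
            [
                g1.mean(1, keepdims=True) + (g1 - g1.mean(1, keepdims=True)) * np.sqrt(0.25 / s2)[:, None],
                g2.mean(1, keepdims=True) + (g2 - g2.mean(1, keepdims=True)) * np.sqrt(0.25 / s2)[:, None],
            ],
            axis=1,
        )
        m = make_matrix(vals, n1=3)
        out = moderated_t(m)
        assert math.isinf(out.attrs["d0"])
        assert out.attrs["s0_2"] == pytest.approx(0.25, abs=1e-12)
        # statistics reduce to logFC / sqrt(s0^2 * (1/3 + 1/3)), normal reference
        expected_t = out["log2_fold_change"] / np.sqrt(0.25 * (2 / 3))
        np.testing.assert_allclose(out["statistic"], expected_t, atol=1e-10)

    def test_few_features_fall_back_to_ordinary(self):
        vals = np.random.default_rng(1).normal(size=(4, 6))
        m = make_matrix(vals, n1=3)
        with pytest.warns(UserWarning, match="falling back"):
            out = moderated_t(m)
        assert (out["test_kind"] == "ordinary_t").all()

    def test_trigamma_inverse_round_trip(self):
        x = np.array([0.05, 0.5, 2.0, 30.0, 1e4])
        np.testing.assert_allclose(
            trigamma_inverse(special.polygamma(1, x)), x, rtol=1e-8
        )

    def test_prior_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(99)
        d, d0_true, s0_true = 4, 6.0, 0.3
        s2 = s0_true * (rng.chisquare(d, 20000) / d) * (d0_true / rng.chisquare(d0_true, 20000))
        d0, s0_2 = fit_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0_2 == pytest.approx(s0_true, rel=0.05)


class TestNullCalibrationAndRecovery:
    def test_null_p_values_uniform_for_both_tests(self):
        spec = ExprSimSpec(n_features=5000, n_per_group=3, noise_sd=0.5, seed=42)
        matrix, _ = synth_expression(spec)
        for test in (ordinary_t, moderated_t):
            frac = (test(matrix)["p_value"] < 0.05).mean()
            assert 0.035 <= frac <= 0.065, f"{test.__name__}: {frac}"

    def test_planted_logfc_recovered(self):
        planted = {f"hit{i:03d}": 3.0 for i in range(200)}
        spec = ExprSimSpec(
            n_features=1000, planted_features=planted, noise_sd=0.5, seed=7
        )
        matrix, truth = synth_expression(spec)
        est = ordinary_t(matrix).loc[truth["feature_id"], "log2_fold_change"]
        mae = (est - 3.0).abs().mean()
        assert mae < 0.5


class TestColorScale:
    def test_zero_maps_to_midpoint(self):
        scale = ColorScale(vmin=-2, vmax=2)
        assert scale(0.0) == scale(0.0)
        # midpoint of yellow (ffff00) and red (ff0000) is ff8000
        assert scale(0.0) == "#ff8000"

    def test_endpoints_and_clamping(self):
        scale = ColorScale(vmin=-3, vmax=3)
        assert scale(3.0) == "#ff0000"  # max -> red
        assert scale(-3.0) == "#ffff00"  # min -> yellow
        assert scale(99.0) == scale(3.0)
        assert scale(-99.0) == scale(-3.0)

    def test_monotone_in_logfc(self):
        scale = ColorScale(vmin=-2, vmax=2)
        reds = [int(scale(v)[1:3], 16) for v in np.linspace(-2, 2, 9)]
        greens = [int(scale(v)[3:5], 16) for v in np.linspace(-2, 2, 9)]
        assert reds == sorted(reds)  # red channel constant-or-rising
        assert greens == sorted(greens, reverse=True)


@pytest.fixture
def overlay_fixtures():
    pmap = PathwayMap.from_parts(
        [
            BioEntity("mmp3", "intracellular_protein"),
            BioEntity("il6", "extracellular_protein"),
            BioEntity("fgfr1", "receptor"),
            BioEntity("edn1", "gene_expression"),
            BioEntity("aspirin", "drug"),
            BioEntity("fibrosis", "phenotype"),
        ],
        name="overlaytoy",
    )
    diff = pd.DataFrame(
        {
            "log2_fold_change": [3.1, -2.8, 0.4, 2.2, 4.0, 5.0],
            "statistic": [9, -8, 1, 6, 10, 11],
            "p_value": [0.001, 0.002, 0.5, 0.01, 0.0005, 0.0001],
            "test_kind": "moderated_t",
        },
        index=["Mmp3", "Il6", "Fgfr1", "Edn1", "aspirin", "notinmap"],
    )
    return pmap, diff


class TestOverlayMap:
    def test_only_allowed_classes_annotated(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        ann = overlay_map(pmap, diff)
        assert set(ann) == {"mmp3", "il6", "edn1", "fgfr1"}
        assert "aspirin" not in ann  # drug matched by symbol stays unannotated

    def test_annotation_carries_logfc_and_colour(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        scale = ColorScale(vmin=-4, vmax=4)
        ann = overlay_map(pmap, diff, scale=scale)
        assert ann["mmp3"]["log2_fold_change"] == pytest.approx(3.1)
        assert ann["il6"]["color"] != ann["mmp3"]["color"]

    def test_no_match_warns_and_returns_empty(self):
        pmap = PathwayMap.from_parts([BioEntity("x", "receptor")])
        diff = pd.DataFrame(
            {"log2_fold_change": [1.0], "statistic": [1.0], "p_value": [0.5],
             "test_kind": "ordinary_t"},
            index=["unrelated"],
        )
        with pytest.warns(UserWarning, match="no differential feature"):
            assert overlay_map(pmap, diff) == {}


class TestSelectCandidates:
    def test_thresholds_and_membership(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        out = select_candidates(pmap, diff, p_threshold=0.05, abs_logfc_threshold=2.0)
        # notinmap passes thresholds but is absent from the map; aspirin is a
        # drug; fgfr1 fails both thresholds
        assert out.genes == ("Mmp3", "Il6", "Edn1")
        assert list(out.table["gene"]) == ["Mmp3", "Il6", "Edn1"]

    def test_sorted_by_absolute_logfc(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        out = select_candidates(pmap, diff, p_threshold=0.05, abs_logfc_threshold=0.1)
        abs_fc = out.table["log2_fold_change"].abs()
        assert abs_fc.is_monotonic_decreasing

    def test_antitone_in_both_thresholds(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        loose = select_candidates(pmap, diff, 0.05, 0.5)
        tight_fc = select_candidates(pmap, diff, 0.05, 3.0)
        tight_p = select_candidates(pmap, diff, 0.0015, 0.5)
        assert set(tight_fc.genes) <= set(loose.genes)
        assert set(tight_p.genes) <= set(loose.genes)

    def test_invariant_to_feature_order(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        shuffled = diff.sample(frac=1, random_state=0)
        a = select_candidates(pmap, diff, 0.05, 2.0)
        b = select_candidates(pmap, shuffled, 0.05, 2.0)
        assert a.genes == b.genes

    def test_bh_adjustment_is_more_conservative(self, overlay_fixtures):
        pmap, diff = overlay_fixtures
        raw = select_candidates(pmap, diff, 0.01, 0.5)
        adj = select_candidates(pmap, diff, 0.01, 0.5, adjust=True)
        assert set(adj.genes) <= set(raw.genes)


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.uniform(size=100) ** 2
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)
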