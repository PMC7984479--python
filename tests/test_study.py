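import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betapet.pvc import fit_rc_models
from betapet.study import (
    ReaderScore,
    SweepConfig,
    apply_pvc_to_metrics,
    best_beta_by_group,
    build_report,
    cohens_kappa,
    load_reader_scores,
    overall_score,
    paired_t_test,
    pearson_correlation,
    run_sweep,
)

# --- independent textbook-formula oracles -----------------------------------


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))


def kappa_oracle(r1, r2):
    cats = sorted(set(r1) | set(r2))
    n = len(r1)
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1, r2):
        table[cats.index(a), cats.index(b)] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(1) * table.sum(0)).sum()) / n**2
    return (p_o - p_e) / (1 - p_e)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert 0 <= p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_identical_pairs_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(paired_t_oracle(a, b), abs=1e-10)
        assert 0 <= p <= 1


class TestKappa:
    def test_perfect_agreement(self):
        r = [1, 2, 3, 1, 2, 3]
        assert cohens_kappa(r, r) == pytest.approx(1.0)

    def test_chance_level_outer_product_table(self):
        # contingency table equals the outer product of its margins -> kappa 0
        r1 = [1, 1, 2, 2]
        r2 = [1, 2, 1, 2]
        assert cohens_kappa(r1, r2) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r1 = rng.integers(1, 5, size=20).tolist()
        r2 = rng.integers(1, 5, size=20).tolist()
        if len(set(r1)) == 1 and set(r1) == set(r2):
            return
        assert cohens_kappa(r1, r2) == pytest.approx(kappa_oracle(r1, r2), abs=1e-12)

    def test_both_raters_constant_equal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa([2, 2, 2], [2, 2, 2])


class TestOverallScore:
    @pytest.mark.parametrize(
        "components,expected",
        [((5, 4, 4), 13.0), ((4, 4, 4), 12.0), ((2.5, 2, 2), 6.5), ((1, 1, 1), 3.0)],
    )
    def test_sum_of_components(self, components, expected):
        assert overall_score(*components) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            overall_score(0.5, 3, 3)
        with pytest.raises(ValueError):
            overall_score(3, 6, 3)

    def test_reader_score_overall_property(self):
        s = ReaderScore("<10 mm", 300.0, 1, 5, 4, 4)
        assert s.overall == 13.0


class TestReaderScoresFixture:
    def test_fixture_shape_and_invariants(self):
        df = load_reader_scores()
        assert len(df) == 40  # 2 groups x 10 betas x 2 readers
        assert set(df["group"]) == {"<10 mm", "10-30 mm"}
        for (_, _), g in df.groupby(["group", "reader"]):
            assert len(g) == 10
        comp = df[["general_quality", "sharpness", "conspicuity"]].sum(axis=1)
        assert np.allclose(df["overall"], comp)

    def test_best_beta_per_group_and_reader(self):
        best = best_beta_by_group(load_reader_scores())
        for reader in (1, 2):
            assert (
                best.query("group == '<10 mm' and reader == @reader").best_beta.iloc[0]
                == 300.0
            )
            assert (
                best.query("group == '10-30 mm' and reader == @reader").best_beta.iloc[0]
                == 400.0
            )


@pytest.fixture(scope="module")
def tiny_nema_sweep():
    """Two-beta noiseless NEMA sweep on the default grid (module-shared)."""
    config = SweepConfig(
        mode="nema",
        betas=(100.0, 1000.0),
        noiseless=True,
        seed=5,
        n_iterations=10,
    )
    return config, run_sweep(config)


class TestRunSweep:
    def test_row_counting_contract(self, tiny_nema_sweep):
        config, metrics = tiny_nema_sweep
        assert len(metrics) == len(config.betas) * 1 * 6  # noiseless: 1 replicate
        assert set(metrics["diameter_mm"]) == {10.0, 13.0, 17.0, 22.0, 28.0, 37.0}

    def test_identical_seeds_identical_table(self):
        config = SweepConfig(
            mode="nema", betas=(350.0,), seed=9, n_replicates=1, n_iterations=4
        )
        assert run_sweep(config).equals(run_sweep(config))

    def test_noiseless_rc_decreases_with_beta(self, tiny_nema_sweep):
        _, metrics = tiny_nema_sweep
        for d, g in metrics.groupby("diameter_mm"):
            g = g.sort_values("beta")
            assert g["rc_pct"].iloc[-1] < g["rc_pct"].iloc[0]

    def test_smoothing_bias_mean_in_voi_decreases(self, tiny_nema_sweep):
        # the propagated-VOI mean of a hot sphere falls as beta rises
        _, metrics = tiny_nema_sweep
        for d, g in metrics.groupby("diameter_mm"):
            g = g.sort_values("beta")
            assert g["cr_pct"].iloc[-1] < g["cr_pct"].iloc[0]


@pytest.fixture(scope="module")
def tiny_clinical():
    config = SweepConfig(
        mode="clinical",
        betas=(100.0, 1000.0),
        n_replicates=1,
        seed=5,
        n_iterations=10,
        lesion_diameters=(5.7, 15.0, 29.4),
    )
    return config, run_sweep(config)


class TestClinicalSweepAndPvc:
    def test_clinical_rows_and_columns(self, tiny_clinical):
        config, metrics = tiny_clinical
        assert len(metrics) == 2 * 3  # betas x lesions
        assert metrics["snr"].gt(0).all()
        assert metrics["suv_peak"].le(metrics["suv_max"] + 1e-12).all()

    def test_pvc_appends_corrected_rows(self, tiny_clinical, tiny_nema_sweep):
        _, clinical = tiny_clinical
        _, nema = tiny_nema_sweep
        models = fit_rc_models(nema)
        full = apply_pvc_to_metrics(clinical, models)
        raw = full[~full.pvc_applied].reset_index()
        cor = full[full.pvc_applied].reset_index()
        assert len(cor) == len(raw)
        ratio = cor["suv_max"].to_numpy() / raw["suv_max"].to_numpy()
        assert np.allclose(ratio, 1.0 / cor["rc_predicted"].to_numpy())
        # sub-centimeter lesion predictions are extrapolations of the model
        assert cor.loc[cor.diameter_mm < 10, "extrapolated"].all()


class TestBuildReport:
    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_report(pd.DataFrame(), load_reader_scores())

    def test_report_bundle_contents(self, tiny_nema_sweep, tmp_path):
        _, metrics = tiny_nema_sweep
        report = build_report(metrics, load_reader_scores(), out_dir=tmp_path)
        assert "nema_curves" in report and "best_beta" in report
        assert (tmp_path / "nema_curves.csv").exists()
        assert (tmp_path / "nema_curves.png").exists()
        kappa = report["reader_kappa"].set_index("component")["kappa"]
        assert 0 < kappa["overall"] <= 1  # the two readers largely agree

    def test_report_regeneration_is_identical(self, tiny_nema_sweep, tmp_path):
        _, metrics = tiny_nema_sweep
        scores = load_reader_scores()
        build_report(metrics, scores, out_dir=tmp_path / "a")
        build_report(metrics, scores, out_dir=tmp_path / "b")
        a = (tmp_path / "a" / "nema_curves.csv").read_bytes()
        b = (tmp_path / "b" / "nema_curves.csv").read_bytes()
        assert a == b
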