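"""Mixed-model LS means, normality screen, correlations and trait PCA."""

import numpy as np
import pandas as pd
import pytest

from seedgwas import phenostats, simdata
from seedgwas._util import UserInputError
from seedgwas.phenostats import TraitMatrix
from seedgwas.simdata import DesignSpec


def simulate_raw(sim, seed=1, **design_kw):
    design_kw.setdefault(
        "treatment_means", {"t1": {t: 0.0 for t in simdata.TREATMENTS}}
    )
    design = DesignSpec(**design_kw)
    raw, _ = simdata.simulate_phenotypes(sim, [], design, seed=seed)
    return raw


@pytest.fixture(scope="module")
def tiny_sim():
    cfg = simdata.SimConfig(
        n_lines=20, n_snps=40, chrom_lengths=(400_000,), missing_rate=0.0,
        het_rate=0.0, seed=31,
    )
    return simdata.simulate_genotypes(cfg)


class TestFitTraitModel:
    def test_zero_tray_variance_estimated_near_zero(self):
        """var_tray = 0 simulations put the random variance well under the
        residual variance in almost every replicate."""
        cfg = simdata.SimConfig(
            n_lines=30, n_snps=40, chrom_lengths=(400_000,), missing_rate=0.0,
            het_rate=0.0, seed=33,
        )
        sim = simdata.simulate_genotypes(cfg)
        hits, n_rep = 0, 50
        for s in range(n_rep):
            raw = simulate_raw(sim, seed=200 + s, var_tray=0.0, var_resid=1.0,
                               n_replicates=10, n_trays_per_treatment=4)
            fit = phenostats.fit_trait_model(raw, "t1")
            hits += fit.random_variance() < 0.10 * fit.residual_variance()
        assert hits >= 0.9 * n_rep

    def test_noise_free_balanced_data_reproduces_generating_means(self, tiny_sim):
        raw = simulate_raw(
            tiny_sim, var_line=0, var_line_treatment=0, var_tray=0, var_resid=0,
            treatment_means={"t1": {"well-watered": 1.5, "water-limited": -2.0}},
        )
        fit = phenostats.fit_trait_model(raw, "t1")
        lsm = phenostats.ls_means(fit)
        for t, mu in (("well-watered", 1.5), ("water-limited", -2.0)):
            got = lsm.loc[lsm["treatment"] == t, "value"]
            np.testing.assert_allclose(got, mu, atol=1e-8)

    def test_planted_tray_variance_recovered(self):
        cfg = simdata.SimConfig(
            n_lines=80, n_snps=40, chrom_lengths=(400_000,), missing_rate=0.0,
            het_rate=0.0, seed=37,
        )
        sim = simdata.simulate_genotypes(cfg)
        truth = 0.5
        ests = []
        for s in range(5):
            raw = simulate_raw(sim, seed=300 + s, var_tray=truth, var_resid=1.0,
                               n_trays_per_treatment=20)
            ests.append(phenostats.fit_trait_model(raw, "t1").random_variance())
        assert truth / 2 <= np.median(ests) <= truth * 2


class TestNormalityScreen:
    def test_gaussian_residuals_keep_identity(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=5, var_resid=1.0)
        fit = phenostats.fit_trait_model(raw, "t1")
        fit = phenostats.check_normality_and_transform(fit, raw, "t1")
        assert fit.transform == "identity"

    def test_lognormal_trait_gets_log_tag(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=6, var_resid=1.0)
        raw["t1"] = np.exp(raw["t1"])
        fit = phenostats.fit_trait_model(raw, "t1")
        fit = phenostats.check_normality_and_transform(fit, raw, "t1")
        assert fit.transform == "log"
        # LS means are on the log scale
        lsm = phenostats.ls_means(fit)
        assert lsm["value"].abs().max() < 10

    def test_skewed_but_nonpositive_keeps_identity(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=7, var_resid=1.0)
        raw["t1"] = -np.exp(raw["t1"])  # skewed, strictly negative
        fit = phenostats.fit_trait_model(raw, "t1")
        fit = phenostats.check_normality_and_transform(fit, raw, "t1")
        assert fit.transform == "identity"

    def test_constant_residuals_inapplicable(self, tiny_sim):
        raw = simulate_raw(tiny_sim, var_line=0, var_line_treatment=0, var_tray=0,
                           var_resid=0)
        fit = phenostats.fit_trait_model(raw, "t1")
        fit = phenostats.check_normality_and_transform(fit, raw, "t1")
        assert fit.transform == "identity"


class TestLsMeans:
    def test_balanced_complete_block_equals_cell_mean(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=8, n_trays_per_treatment=1, var_tray=0.3)
        fit = phenostats.fit_trait_model(raw, "t1")
        lsm = phenostats.ls_means(fit).set_index(["line", "treatment"])["value"]
        cm = raw.groupby(["line", "treatment"])["t1"].mean()
        assert (lsm - cm).abs().max() < 1e-10

    def test_unbalanced_matches_explicit_gls_oracle(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=9, var_tray=0.4, n_trays_per_treatment=2)
        raw = raw.drop(index=raw.index[5]).reset_index(drop=True)  # unbalance
        fit = phenostats.fit_trait_model(raw, "t1")
        assert not fit.random_dropped
        lsm = phenostats.ls_means(fit).set_index(["line", "treatment"])["value"]

        # oracle: explicit GLS on the saturated cell-means design at the
        # model's estimated variance components
        df = fit.data
        cells = sorted(map(tuple, df[["line", "treatment"]].drop_duplicates().to_numpy()))
        cidx = {c: k for k, c in enumerate(cells)}
        X = np.zeros((len(df), len(cells)))
        for r, (l, t) in enumerate(df[["line", "treatment"]].to_numpy()):
            X[r, cidx[(l, t)]] = 1.0
        groups = sorted(df["tray_group"].unique())
        Z = np.zeros((len(df), len(groups)))
        for r, g in enumerate(df["tray_group"]):
            Z[r, groups.index(g)] = 1.0
        V = fit.residual_variance() * np.eye(len(df)) + fit.random_variance() * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["y"].to_numpy())
        for (l, t), k in cidx.items():
            assert lsm.loc[(l, t)] == pytest.approx(beta[k], abs=1e-6)

    def test_line_absent_from_one_treatment_flagged_missing(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=10)
        line = raw["line"].iloc[0]
        raw = raw[~((raw["line"] == line) & (raw["treatment"] == "well-watered"))]
        fit = phenostats.fit_trait_model(raw, "t1")
        lsm = phenostats.ls_means(fit).set_index(["line", "treatment"])
        assert bool(lsm.loc[(line, "well-watered"), "missing"])
        assert np.isnan(lsm.loc[(line, "well-watered"), "value"])

    def test_invariant_to_row_order(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=11)
        shuffled = raw.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = phenostats.trait_matrix(raw, engine="cell_mean").wide()
        b = phenostats.trait_matrix(shuffled, engine="cell_mean").wide()
        pd.testing.assert_frame_equal(a, b)


def _toy_tm(columns: dict[tuple[str, str], np.ndarray], lines=None) -> TraitMatrix:
    rows = []
    for (trait, treatment), vals in columns.items():
        for i, v in enumerate(vals):
            rows.append(
                {"line": lines[i] if lines else f"L{i:03d}", "treatment": treatment,
                 "trait": trait, "value": v}
            )
    return TraitMatrix(values=pd.DataFrame(rows))


class TestTraitCorrelations:
    def test_perfectly_linear_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        tm = _toy_tm({("a", "ww"): x, ("b", "ww"): 2 * x + 1e-12 * rng.normal(size=30)})
        out = phenostats.trait_correlations(tm)
        assert out["r"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert bool(out["significant"].iloc[0])

    def test_familywise_error_controlled_on_independent_traits(self):
        """Bonferroni over all tested pairs keeps the family-wise error at or
        below the nominal level (binomial check over simulations)."""
        rng = np.random.default_rng(42)
        n_sims, n_cols, n_lines = 200, 8, 40
        fails = 0
        for _ in range(n_sims):
            cols = {
                (f"t{j}", tr): rng.normal(size=n_lines)
                for j in range(n_cols // 2)
                for tr in ("ww", "wl")
            }
            out = phenostats.trait_correlations(_toy_tm(cols))
            fails += bool(out["significant"].any())
        # Binomial(200, 0.05) 97.5th percentile is about 16
        assert fails <= 16

    def test_too_few_pairs_missing(self):
        tm = _toy_tm({("a", "ww"): np.array([1.0, 2.0]), ("b", "ww"): np.array([2.0, 1.0])})
        out = phenostats.trait_correlations(tm)
        assert np.isnan(out["r"].iloc[0])


class TestTraitPca:
    def test_variance_fractions_sum_to_one(self, tiny_sim):
        raw = simulate_raw(
            tiny_sim, seed=12,
            treatment_means={
                "a": {t: 0.0 for t in simdata.TREATMENTS},
                "b": {t: 1.0 for t in simdata.TREATMENTS},
                "c": {t: -1.0 for t in simdata.TREATMENTS},
            },
        )
        tm = phenostats.trait_matrix(raw, engine="cell_mean")
        pca = phenostats.trait_pca(tm)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_trait_loads_equally_on_pc1(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        tm = _toy_tm({("a", "ww"): x, ("b", "ww"): x.copy(), ("c", "ww"): y})
        pca = phenostats.trait_pca(tm)
        la, lb = pca.loadings.loc["a", "PC1"], pca.loadings.loc["b", "PC1"]
        assert la == pytest.approx(lb, abs=1e-10)

    def test_treatment_shift_separates_scores(self):
        rng = np.random.default_rng(2)
        n = 50
        shared = {tr: rng.normal(0, 0.1, n) for tr in ("ww", "wl")}
        # two correlated shifted traits so the treatment axis owns a dominant PC
        tm = _toy_tm(
            {
                ("shifted_a", "ww"): 0.0 + shared["ww"],
                ("shifted_a", "wl"): 3.0 + shared["wl"],
                ("shifted_b", "ww"): 0.0 + shared["ww"] + rng.normal(0, 0.05, n),
                ("shifted_b", "wl"): 3.0 + shared["wl"] + rng.normal(0, 0.05, n),
                ("flat", "ww"): rng.normal(size=n),
                ("flat", "wl"): rng.normal(size=n),
            }
        )
        pca = phenostats.trait_pca(tm)
        # the correlated shifted pair dominates PC1 by construction
        assert abs(pca.loadings.loc["shifted_a", "PC1"]) > abs(
            pca.loadings.loc["flat", "PC1"]
        )
        pc = pca.scores["PC1"]
        ww = pc.xs("ww", level="treatment")
        wl = pc.xs("wl", level="treatment")
        gap = abs(ww.mean() - wl.mean())
        assert gap > 2 * (ww.std() + wl.std())

    def test_constant_trait_dropped(self):
        rng = np.random.default_rng(3)
        tm = _toy_tm({("a", "ww"): rng.normal(size=20), ("b", "ww"): np.zeros(20)})
        pca = phenostats.trait_pca(tm)
        assert "b" not in pca.loadings.index


class TestTraitMatrix:
    def test_range_is_exact_max_minus_min(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=13)
        tm = phenostats.trait_matrix(raw, engine="cell_mean")
        v = tm.vector("t1", "well-watered")
        assert tm.range("t1", "well-watered") == pytest.approx(v.max() - v.min())

    def test_requires_two_treatments(self, tiny_sim):
        raw = simulate_raw(tiny_sim, seed=14)
        with pytest.raises(UserInputError):
            phenostats.fit_trait_model(raw[raw["treatment"] == "well-watered"], "t1")
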