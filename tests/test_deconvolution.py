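"""Deconvolution: locus selection, simplex fits vs a grid-search oracle,
purity validation, cell-type expression recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stromapat as sp
import stromapat.synthetic as syn
from stromapat.deconvolution import simplex_lstsq


def grid_search_simplex(A, b, step=0.01):
    """Brute-force oracle: best point of the 3-simplex grid at resolution step."""
    best, best_obj = None, np.inf
    n = int(round(1 / step))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            p = np.array([i, j, n - i - j]) / n
            obj = float(((A @ p - b) ** 2).sum())
            if obj < best_obj:
                best, best_obj = p, obj
    return best, best_obj


class TestSelectLoci:
    def test_all_loci_when_n_equals_total(self, reference_panel):
        panel, _ = reference_panel
        sel = sp.select_informative_loci(panel, n_loci=panel.beta.shape[0])
        assert set(sel) == set(panel.beta.index)

    def test_planted_loci_dominate_selection(self, reference_panel):
        """≥ 95% of the top-400 selected loci are planted informative ones."""
        panel, informative = reference_panel
        sel = sp.select_informative_loci(panel, n_loci=400)
        # only 200 informative loci exist; they should all rank in front
        hit = len(set(sel[:200]) & set(informative)) / 200
        assert hit >= 0.95

    def test_noiseless_panel_selects_only_planted(self):
        panel, informative = sp.generate_reference_methylation(
            n_loci=500, cell_types=["a", "b", "c"], n_informative=100,
            profiles_per_type=3, delta=0.4, noise_sd=0.0, seed=1)
        sel = sp.select_informative_loci(panel, n_loci=100)
        assert set(sel) <= set(informative)

    def test_class_with_single_profile_rejected(self):
        beta = pd.DataFrame(np.random.default_rng(0).uniform(size=(10, 3)),
                            columns=["p1", "p2", "p3"])
        labels = pd.Series(["x", "x", "y"], index=beta.columns)
        with pytest.raises(ValueError, match="< 2"):
            sp.ReferencePanel(beta=beta, class_labels=labels)


class TestEstimateProportions:
    def _pure_panel(self, seed=3):
        panel, _ = sp.generate_reference_methylation(
            n_loci=300, cell_types=["cancer", "stromal", "immune"],
            n_informative=60, profiles_per_type=4, delta=0.5, noise_sd=0.0,
            seed=seed)
        return panel

    def test_pure_sample_recovered(self):
        panel = self._pure_panel()
        bulk = panel.class_means[["stromal"]].rename(columns={"stromal": "s0"})
        pm, _ = sp.estimate_proportions(bulk, panel, mode="reference_fixed")
        assert pm.fractions.loc["s0", "stromal"] == pytest.approx(1.0, abs=1e-6)
        assert pm.fractions.loc["s0", "cancer"] == pytest.approx(0.0, abs=1e-6)

    def test_even_mixture_recovered(self):
        panel = self._pure_panel()
        cm = panel.class_means
        bulk = pd.DataFrame(
            {"s0": 0.5 * cm["cancer"] + 0.5 * cm["stromal"]})
        pm, _ = sp.estimate_proportions(bulk, panel, mode="reference_fixed")
        got = pm.fractions.loc["s0"]
        assert got["cancer"] == pytest.approx(0.5, abs=1e-6)
        assert got["stromal"] == pytest.approx(0.5, abs=1e-6)
        assert got["immune"] == pytest.approx(0.0, abs=1e-6)

    def test_dirichlet_mixture_mae_and_grid_oracle(self, reference_panel):
        panel, _ = reference_panel
        panel.selected_loci = sp.select_informative_loci(panel, n_loci=400)
        bulk, props_true = sp.generate_bulk_mixtures(
            panel, n_samples=100, dirichlet_alpha=[2.0, 2.0, 2.0],
            noise_sd=0.03, seed=11)
        pm, _ = sp.estimate_proportions(bulk, panel, mode="reference_fixed")
        mae = np.abs(pm.fractions.to_numpy() - props_true.to_numpy()).mean()
        assert mae < 0.05
        # per-sample fit matches the exhaustive simplex grid oracle
        A = panel.class_means.loc[panel.selected_loci].to_numpy()
        B = bulk.loc[panel.selected_loci].to_numpy()
        for j in [0, 17, 42, 63, 99]:
            p_grid, obj_grid = grid_search_simplex(A, B[:, j])
            p_fit = pm.fractions.iloc[j].to_numpy()
            obj_fit = float(((A @ p_fit - B[:, j]) ** 2).sum())
            assert obj_fit <= obj_grid + 1e-12
            assert np.abs(p_fit - p_grid).max() <= 0.01 + 1e-9

    def test_refine_mode_converges_and_stays_on_simplex(self, reference_panel):
        panel, _ = reference_panel
        panel.selected_loci = sp.select_informative_loci(panel, n_loci=200)
        bulk, props_true = sp.generate_bulk_mixtures(
            panel, n_samples=40, dirichlet_alpha=[2.0, 2.0, 2.0],
            noise_sd=0.03, seed=12)
        pm, fitted = sp.estimate_proportions(bulk, panel, mode="refine")
        rows = pm.fractions.to_numpy().sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)
        assert (fitted.to_numpy() >= 0).all() and (fitted.to_numpy() <= 1).all()
        mae = np.abs(pm.fractions.to_numpy() - props_true.to_numpy()).mean()
        assert mae < 0.05
        # fitted profiles stay recognisable as their reference classes
        for cls in panel.classes:
            r = np.corrcoef(fitted[cls],
                            panel.class_means.loc[fitted.index, cls])[0, 1]
            assert r > 0.9

    def test_collinear_class_means_raise(self):
        beta = pd.DataFrame(
            np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 4)),
            columns=["a1", "a2", "b1", "b2"])
        labels = pd.Series(["a", "a", "b", "b"], index=beta.columns)
        panel = sp.ReferencePanel(beta=beta, class_labels=labels)
        bulk = beta[["a1"]].rename(columns={"a1": "s"})
        with pytest.raises(np.linalg.LinAlgError):
            sp.estimate_proportions(bulk, panel)

    @pytest.mark.parametrize("seed", range(4))
    def test_simplex_solver_exact_on_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(30, 3))
        b = rng.uniform(size=30)
        p = simplex_lstsq(A, b)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert (p >= -1e-12).all()
        p_grid, obj_grid = grid_search_simplex(A, b)
        assert float(((A @ p - b) ** 2).sum()) <= obj_grid + 1e-12


class TestValidatePurity:
    def _pm(self):
        f = pd.DataFrame({"cancer": [0.6, 0.3, 0.8, 0.5],
                          "stromal": [0.4, 0.7, 0.2, 0.5]},
                         index=list("abcd"))
        return sp.ProportionMatrix(fractions=f)

    def test_identical_vector_r_one(self):
        pm = self._pm()
        r, p = sp.validate_purity(pm, "cancer", pm.fractions["cancer"])
        assert r == pytest.approx(1.0)

    def test_constant_purity_is_nan(self):
        pm = self._pm()
        r, p = sp.validate_purity(pm, "cancer",
                                  pd.Series(0.5, index=list("abcd")))
        assert np.isnan(r)

    def test_generator_truth_high_correlation(self, reference_panel):
        panel, _ = reference_panel
        panel.selected_loci = sp.select_informative_loci(panel, n_loci=400)
        bulk, props_true = sp.generate_bulk_mixtures(
            panel, n_samples=60, dirichlet_alpha=[2.0, 2.0, 2.0],
            noise_sd=0.03, seed=21)
        pm, _ = sp.estimate_proportions(bulk, panel, mode="reference_fixed")
        r, p = sp.validate_purity(pm, "cancer", props_true["cancer"])
        assert r >= 0.95 and p < 1e-4

    def test_too_few_overlapping_samples_raise(self):
        pm = self._pm()
        with pytest.raises(ValueError):
            sp.validate_purity(pm, "cancer", pd.Series({"a": 0.5, "b": 0.2}))


class TestCellTypeExpression:
    def test_single_type_equals_group_mean(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.gamma(2.0, 1.0, size=(5, 8)),
                         columns=[f"s{i}" for i in range(8)])
        f = pd.DataFrame({"only": np.ones(8)}, index=X.columns)
        pm = sp.ProportionMatrix(fractions=f)
        groups = pd.Series("g", index=X.columns)
        est = sp.estimate_celltype_expression(X, pm, groups)["g"]
        np.testing.assert_allclose(est.estimate["only"], X.mean(axis=1),
                                   rtol=1e-10)

    def test_exclusive_gene_recovered_exactly(self):
        rng = np.random.default_rng(2)
        P = rng.dirichlet([2, 2, 2], size=12)
        E = np.array([[10.0, 0.0, 0.0]])
        X = pd.DataFrame(E @ P.T, index=["g0"],
                         columns=[f"s{i}" for i in range(12)])
        pm = sp.ProportionMatrix(fractions=pd.DataFrame(
            P, index=X.columns, columns=["A", "B", "C"]))
        est = sp.estimate_celltype_expression(
            X, pm, pd.Series("g", index=X.columns))["g"]
        np.testing.assert_allclose(est.estimate.loc["g0"].to_numpy(),
                                   [10.0, 0.0, 0.0], atol=1e-6)

    def test_planted_stromal_group_difference_detected(self):
        """Δ=2 stromal shift on 50 marker genes, σ=0.3, n=60/group →
        ≥ 90% detected at z > 2 in the stromal column."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        classes = ["cancer", "stromal", "immune"]
        E_lo = pd.DataFrame(rng.uniform(2, 6, size=(200, 3)), index=genes,
                            columns=classes)
        E_hi = E_lo.copy()
        planted = genes[:50]
        E_hi.loc[planted, "stromal"] += 2.0
        P = rng.dirichlet([2, 2, 2], size=120)
        samples = [f"s{i}" for i in range(120)]
        props = pd.DataFrame(P, index=samples, columns=classes)
        groups = pd.Series(["lo"] * 60 + ["hi"] * 60, index=samples)
        X = syn.generate_bulk_expression({"lo": E_lo, "hi": E_hi}, props,
                                         groups, noise_sd=0.3, seed=3)
        pm = sp.ProportionMatrix(fractions=props)
        ests = sp.estimate_celltype_expression(X, pm, groups)
        contrast = sp.celltype_expression_contrast(ests["hi"], ests["lo"])
        z_stromal = contrast[("z", "stromal")]
        detected = (z_stromal.loc[planted] > 2).mean()
        assert detected >= 0.9
        false_rate = (contrast[("z", "cancer")].loc[planted].abs() > 2).mean()
        assert false_rate < 0.5  # the shift is attributed to the right type

    def test_group_too_small_raises(self):
        X = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        f = pd.DataFrame(np.full((4, 3), 1 / 3), index=list("abcd"),
                         columns=["x", "y", "z"])
        pm = sp.ProportionMatrix(fractions=f)
        with pytest.raises(ValueError, match="need"):
            sp.estimate_celltype_expression(X, pm,
                                            pd.Series("g", index=list("abcd")))

    def test_estimates_nonnegative(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.gamma(1.0, 1.0, size=(30, 20)),
                         columns=[f"s{i}" for i in range(20)])
        P = rng.dirichlet([1, 1, 1], size=20)
        pm = sp.ProportionMatrix(fractions=pd.DataFrame(
            P, index=X.columns, columns=["a", "b", "c"]))
        est = sp.estimate_celltype_expression(
            X, pm, pd.Series("g", index=X.columns))["g"]
        assert (est.estimate.to_numpy() >= 0).all()
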