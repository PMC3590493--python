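"""Penalized functional Fisher discriminant: oracles, invariances, LOOCV."""

import dataclasses

import numpy as np
import pytest
from scipy import linalg

import thermocit as tc
from thermocit import discriminant as fld
from thermocit import smoothing as smo

from .conftest import smoothed_functions


def make_functions(basis, coef_rows, condition=None):
    fns = []
    for k, c in enumerate(coef_rows):
        fns.append(
            smo.SmoothFunction(
                basis=basis, coefficients=np.asarray(c, dtype=float),
                participant_id=f"P{k}", condition=condition, question_id=f"Q{k}",
            )
        )
    return fns


def two_constant_classes(basis, n=6, gap=1.0, sd=0.01, seed=0):
    """Constant functions at 0 (innocent) vs gap (guilty) + small jitter."""
    rng = np.random.default_rng(seed)
    nb = basis.n_basis
    guilty = [np.full(nb, gap) + sd * rng.standard_normal(nb) for _ in range(n)]
    innocent = [np.full(nb, 0.0) + sd * rng.standard_normal(nb) for _ in range(n)]
    fns = make_functions(basis, guilty, "guilty") + make_functions(basis, innocent, "innocent")
    return fns


def eigh_oracle(fns, labels, rho):
    """Explicit generalized-eigenproblem solution eigh(B, W + rho R)."""
    basis = fns[0].basis
    C = np.stack([f.coefficients for f in fns])
    G, R = basis.gram_matrix, basis.penalty_matrix
    masks = {cls: np.asarray(labels, dtype=object) == cls for cls in ("guilty", "innocent")}
    grand = C.mean(axis=0)
    Sw = np.zeros((C.shape[1], C.shape[1]))
    Sb = np.zeros_like(Sw)
    for mask in masks.values():
        rows = C[mask]
        m = rows.mean(axis=0)
        Sw += (rows - m).T @ (rows - m)
        Sb += len(rows) * np.outer(m - grand, m - grand)
    Sw /= len(C) - 2
    vals, vecs = linalg.eigh(G @ Sb @ G, G @ Sw @ G + rho * R)
    return vals[-1], vecs[:, -1]


class TestFit:
    def test_separates_constant_classes(self):
        basis = tc.build_basis(10.0, 6, 4)
        fns = two_constant_classes(basis)
        model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=0.0))
        scores = np.array([tc.project(model, f) for f in fns])
        g, i = scores[:6], scores[6:]
        assert g.min() > model.threshold > i.max()
        gap = model.class_means_projected["guilty"] - model.class_means_projected["innocent"]
        pooled_sd = np.sqrt((g.var(ddof=1) + i.var(ddof=1)) / 2)
        assert gap > 10 * pooled_sd

    def test_no_signal_leading_eigenvalue_vanishes(self):
        """Duplicating one class's data under both labels makes the between
        scatter exactly zero, hence a zero leading eigenvalue."""
        basis = tc.build_basis(10.0, 6, 4)
        rng = np.random.default_rng(1)
        rows = rng.standard_normal((5, 6))
        fns = make_functions(basis, rows, "guilty") + make_functions(basis, rows, "innocent")
        model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=1.0))
        assert abs(model.eigenvalue) < 1e-6

    def test_matches_generalized_eigenvector_oracle(self):
        """Closed-form direction equals the leading eigh(B, W + rho R)
        eigenvector (up to scale) on 20 random instances."""
        for k in range(20):
            rng = np.random.default_rng(200 + k)
            basis = tc.build_basis(10.0, int(rng.integers(5, 9)), 4)
            nb = basis.n_basis
            n_g, n_i = int(rng.integers(4, 9)), int(rng.integers(4, 9))
            C = np.vstack([
                rng.standard_normal((n_g, nb)) + rng.normal(0, 1, nb),
                rng.standard_normal((n_i, nb)),
            ])
            fns = make_functions(basis, C[:n_g], "guilty") + make_functions(basis, C[n_g:], "innocent")
            rho = float(10.0 ** rng.integers(-1, 4))
            model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=rho))
            val, vec = eigh_oracle(fns, [f.condition for f in fns], rho)
            w = model.weight.coefficients
            cos = abs(w @ vec) / (np.linalg.norm(w) * np.linalg.norm(vec))
            assert cos > 1 - 1e-8
            assert model.eigenvalue == pytest.approx(val, rel=1e-8)

    def test_two_basis_toy_closed_form(self):
        """On a 2-function basis the direction is (W + rho R)^-1 G (m1 - m2),
        verifiable with hand-sized 2x2 matrices."""
        basis = tc.build_basis(1.0, 2, 2)  # two linear hat functions
        C = np.array([[1.0, 0.2], [1.2, 0.1], [0.1, 1.0], [0.2, 1.3]])
        fns = make_functions(basis, C[:2], "guilty") + make_functions(basis, C[2:], "innocent")
        rho = 0.5
        model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=rho))
        G, R = basis.gram_matrix, basis.penalty_matrix
        Sw = np.zeros((2, 2))
        for rows in (C[:2], C[2:]):
            m = rows.mean(axis=0)
            Sw += (rows - m).T @ (rows - m)
        Sw /= 2.0
        expected = np.linalg.solve(G @ Sw @ G + rho * R, G @ (C[:2].mean(0) - C[2:].mean(0)))
        w = model.weight.coefficients
        cos = abs(w @ expected) / (np.linalg.norm(w) * np.linalg.norm(expected))
        assert cos > 1 - 1e-8

    def test_single_class_rejected(self):
        basis = tc.build_basis(10.0, 6, 4)
        fns = make_functions(basis, np.eye(6)[:4], "guilty")
        with pytest.raises(tc.ValidationError):
            tc.fit_fld(fns)


class TestProject:
    def test_zero_weight_projects_to_zero(self):
        basis = tc.build_basis(10.0, 6, 4)
        w = smo.SmoothFunction(basis=basis, coefficients=np.zeros(6))
        model = fld.DiscriminantModel(
            weight=w, rho=1.0, threshold=0.0,
            class_means_projected={"guilty": 0.0, "innocent": 0.0}, eigenvalue=0.0,
        )
        fn = smo.SmoothFunction(basis=basis, coefficients=np.ones(6))
        assert tc.project(model, fn) == 0.0

    def test_unit_weight_integrates_constants(self):
        basis = tc.build_basis(10.0, 6, 4)
        w = smo.SmoothFunction(basis=basis, coefficients=np.ones(6))  # w(t) = 1
        model = fld.DiscriminantModel(
            weight=w, rho=1.0, threshold=0.5,
            class_means_projected={"guilty": 1.0, "innocent": 0.0}, eigenvalue=0.0,
        )
        fn = smo.SmoothFunction(basis=basis, coefficients=np.full(6, 3.0))  # fn(t) = 3
        assert tc.project(model, fn) == pytest.approx(30.0, abs=1e-9)  # int over [0,10]

    def test_matches_dense_quadrature(self):
        basis = tc.build_basis(10.0, 9, 4)
        rng = np.random.default_rng(3)
        w = smo.SmoothFunction(basis=basis, coefficients=rng.standard_normal(9))
        fn = smo.SmoothFunction(basis=basis, coefficients=rng.standard_normal(9))
        model = fld.DiscriminantModel(
            weight=w, rho=1.0, threshold=0.5,
            class_means_projected={"guilty": 1.0, "innocent": 0.0}, eigenvalue=0.0,
        )
        t = np.linspace(0.0, 10.0, 200_001)
        ref = np.trapezoid(w(t) * fn(t), t)
        assert tc.project(model, fn) == pytest.approx(ref, abs=1e-6)

    def test_basis_mismatch_rejected(self):
        b1, b2 = tc.build_basis(10.0, 6, 4), tc.build_basis(10.0, 7, 4)
        w = smo.SmoothFunction(basis=b1, coefficients=np.zeros(6))
        model = fld.DiscriminantModel(
            weight=w, rho=1.0, threshold=0.0,
            class_means_projected={"guilty": 0.0, "innocent": 0.0}, eigenvalue=0.0,
        )
        with pytest.raises(tc.ValidationError):
            tc.project(model, smo.SmoothFunction(basis=b2, coefficients=np.zeros(7)))


class TestClassify:
    def test_engineered_89_of_90(self):
        """89 of 90 correct prints the study's 98.89% / 1.11% split."""
        basis = tc.build_basis(10.0, 6, 4)
        rng = np.random.default_rng(7)
        guilty = [np.full(6, 1.0) + 0.01 * rng.standard_normal(6) for _ in range(54)]
        innocent = [np.full(6, 0.0) + 0.01 * rng.standard_normal(6) for _ in range(36)]
        fns = make_functions(basis, guilty, "guilty") + make_functions(basis, innocent, "innocent")
        model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=1.0))
        labels = [f.condition for f in fns]
        labels[0] = "innocent"  # one deliberately wrong truth label
        report = tc.classify(model, fns, labels)
        assert (report.n_total, report.n_correct) == (90, 89)
        assert report.to_dict()["rate_correct"] == 98.89
        assert report.to_dict()["rate_misclassified"] == 1.11

    def test_rate_arithmetic_248_of_360(self):
        report = fld.ClassificationReport(n_total=360, n_correct=248)
        assert report.to_dict()["rate_correct"] == 68.89
        assert report.to_dict()["rate_misclassified"] == 31.11
        assert report.rate_correct + report.rate_misclassified == pytest.approx(100.0)

    def test_all_correct(self):
        report = fld.ClassificationReport(n_total=10, n_correct=10)
        assert report.rate_correct == 100.0 and report.rate_misclassified == 0.0

    def test_scale_invariance(self):
        """Multiplying all data by c > 0 leaves every assignment unchanged."""
        basis = tc.build_basis(10.0, 6, 4)
        fns = two_constant_classes(basis, gap=0.6, sd=0.3, seed=5)
        cfg = fld.DiscriminantConfig(rho=10.0)
        base = tc.classify(tc.fit_fld(fns, config=cfg), fns)
        scaled = [dataclasses.replace(f, coefficients=7.3 * f.coefficients) for f in fns]
        after = tc.classify(tc.fit_fld(scaled, config=cfg), scaled)
        assert [a["predicted"] for a in base.assignments] == [a["predicted"] for a in after.assignments]


class TestRhoEffects:
    def test_weight_roughness_nonincreasing_in_rho(self):
        basis = tc.build_basis(10.0, 12, 4)
        fns = two_constant_classes(basis, n=8, gap=0.5, sd=0.3, seed=11)
        roughs = []
        for rho in 10.0 ** np.arange(-2, 7):
            model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=float(rho)))
            w = model.weight.coefficients
            w = w / np.linalg.norm(w)  # scale-free comparison
            roughs.append(float(w @ basis.penalty_matrix @ w))
        assert np.all(np.diff(roughs) <= 1e-9)


class TestLoocv:
    def test_single_value_grid(self):
        basis = tc.build_basis(10.0, 6, 4)
        fns = two_constant_classes(basis)
        rho, cv = tc.loocv_select_rho(fns, rho_grid=(3.0,))
        assert rho == 3.0 and set(cv) == {3.0}

    def test_well_separated_selects_largest_zero_error(self):
        basis = tc.build_basis(10.0, 8, 4)
        fns = two_constant_classes(basis, n=8, gap=1.0, sd=0.05, seed=13)
        grid = tuple(10.0 ** k for k in range(-2, 5))
        rho, cv = tc.loocv_select_rho(fns, rho_grid=grid)
        zeros = [r for r, e in cv.items() if e == 0.0]
        assert zeros, "classes are separated by 20 within-SDs"
        assert rho == max(zeros)

    def test_agrees_with_naive_refit_loocv(self):
        """The rank-one-downdate implementation equals a naive leave-one-out
        loop that refits with fit_fld from scratch."""
        basis = tc.build_basis(10.0, 7, 4)
        fns = two_constant_classes(basis, n=4, gap=0.3, sd=0.4, seed=17)
        labels = np.array([f.condition for f in fns], dtype=object)
        grid = (0.1, 10.0, 1000.0)
        _, cv = tc.loocv_select_rho(fns, rho_grid=grid)
        for rho in grid:
            errors = 0
            for i in range(len(fns)):
                rest = [f for j, f in enumerate(fns) if j != i]
                model = tc.fit_fld(rest, labels[np.arange(len(fns)) != i],
                                   fld.DiscriminantConfig(rho=rho))
                pred = "guilty" if tc.project(model, fns[i]) > model.threshold else "innocent"
                errors += pred != labels[i]
            assert cv[rho] == pytest.approx(errors / len(fns))

    def test_too_few_per_class_rejected(self):
        basis = tc.build_basis(10.0, 6, 4)
        fns = two_constant_classes(basis, n=2)
        with pytest.raises(tc.ValidationError):
            tc.loocv_select_rho(fns, rho_grid=(1.0,))


class TestEndToEnd:
    def test_relevant_question_functions_classify_above_95_percent(self, paper_design):
        """Full pipeline on the default synthetic study: the penalized
        discriminant with LOOCV-selected rho classifies the 90
        relevant-question functions at >= 95% (training-set rate)."""
        fns, _ = smoothed_functions(paper_design.replace(seed=3), keep_every=1, relevance="RE")
        assert len(fns) == 90
        rho, cv = tc.loocv_select_rho(fns, rho_grid=fld.DEFAULT_RHO_GRID)
        model = tc.fit_fld(fns, config=fld.DiscriminantConfig(rho=rho))
        report = tc.classify(model, fns)
        assert report.rate_correct >= 95.0
        assert cv[rho] <= 0.05  # held-out error consistent with the separation
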