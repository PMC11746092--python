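"""Genotype sampling, the mixed probability model, and theoretical AUC."""

import numpy as np
import pytest

from epibench.penetrance import solve_penetrance
from epibench.simulate import (
    Dataset,
    GenotypeMatrix,
    LinearEffectModel,
    MixedPhenotypeModel,
    alpha_sweep,
    assign_phenotypes,
    balanced_dataset,
    gametes_experiment,
    linear_prob,
    mixed_prob,
    read_dataset,
    sample_genotypes,
    sample_linear_model,
    theoretical_auc,
    write_dataset,
)


def make_model(table, alpha=0.0, k=0, seed=0):
    linear = sample_linear_model(k, 0.5, seed)
    return MixedPhenotypeModel(
        alpha=alpha, linear=linear, epistatic=table,
        linear_columns=tuple(range(k)),
        epistatic_columns=tuple(range(k, k + table.order)),
    )


# -- genotype sampling -----------------------------------------------------

def test_genotype_frequencies_match_hardy_weinberg():
    g = sample_genotypes(100_000, [0.5], seed=1)
    counts = np.bincount(g.values[:, 0], minlength=3) / 100_000
    for observed, expected in zip(counts, (0.25, 0.5, 0.25)):
        sd = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(observed - expected) < 3 * sd


def test_monomorphic_locus_is_all_zero():
    g = sample_genotypes(500, [0.0, 0.3], seed=2)
    assert (g.values[:, 0] == 0).all()


def test_genotype_sampling_is_deterministic():
    a = sample_genotypes(200, [0.25] * 5, seed=7)
    b = sample_genotypes(200, [0.25] * 5, seed=7)
    assert (a.values == b.values).all()
    assert a.snp_ids == b.snp_ids


def test_genotype_sampling_rejects_bad_maf():
    with pytest.raises(ValueError):
        sample_genotypes(10, [0.7], seed=0)


def test_genotype_matrix_invariants():
    with pytest.raises(ValueError):
        GenotypeMatrix(values=np.array([[0, 3]]), snp_ids=("a", "b"))
    with pytest.raises(ValueError):
        GenotypeMatrix(values=np.zeros((2, 2), dtype=int), snp_ids=("a",))


# -- linear model ----------------------------------------------------------

def test_linear_model_shapes_and_determinism():
    m = sample_linear_model(25, 0.5, seed=3)
    assert len(m.coefficients) == 25
    again = sample_linear_model(25, 0.5, seed=3)
    assert m.intercept == again.intercept
    assert (m.coefficients == again.coefficients).all()
    zero = sample_linear_model(4, 0.0, seed=3)
    assert zero.intercept == 0.0 and (zero.coefficients == 0.0).all()


@pytest.mark.parametrize(
    "intercept, coefs, row, expected",
    [
        (0.0, [0.0, 0.0], [1, 2], 0.5),
        (-1.0, [0.5], [2], 0.5),
        (0.0, [np.log(2)], [1], 2.0 / 3.0),
    ],
)
def test_linear_prob_closed_forms(intercept, coefs, row, expected):
    model = LinearEffectModel(intercept, np.array(coefs))
    assert linear_prob(model, np.array(row)) == pytest.approx(expected,
                                                              abs=1e-12)


def test_linear_prob_stable_for_extreme_logits():
    model = LinearEffectModel(0.0, np.array([500.0]))
    assert linear_prob(model, np.array([2])) == pytest.approx(1.0)
    assert linear_prob(model, np.array([-0.0])) == pytest.approx(0.5)
    model = LinearEffectModel(-1000.0, np.array([0.0]))
    assert linear_prob(model, np.array([1])) == pytest.approx(0.0)


# -- mixed model -----------------------------------------------------------

def test_mixed_prob_alpha_limits(threshold_table, rng):
    model1 = make_model(threshold_table, alpha=1.0, k=3)
    model0 = make_model(threshold_table, alpha=0.0, k=3)
    rows = rng.integers(0, 3, size=(50, 5))
    lin = linear_prob(model1.linear, rows[:, :3])
    assert mixed_prob(model1, rows) == pytest.approx(lin, abs=0)
    pen = threshold_table.as_array()[rows[:, 3], rows[:, 4]]
    assert mixed_prob(model0, rows) == pytest.approx(pen, abs=0)


def test_mixed_prob_is_affine_in_alpha(threshold_table, rng):
    rows = rng.integers(0, 3, size=(20, 4))
    p = {a: mixed_prob(make_model(threshold_table, alpha=a, k=2), rows)
         for a in (0.0, 0.5, 1.0)}
    assert p[0.5] == pytest.approx(0.5 * (p[0.0] + p[1.0]), abs=1e-15)


def test_mixed_prob_mean_structure(parity_table):
    model = MixedPhenotypeModel(
        alpha=0.5, linear=LinearEffectModel(np.log(1.5), np.array([0.0])),
        epistatic=parity_table, linear_columns=(0,), epistatic_columns=(1, 2))
    # linear part = 0.6, penetrance cell (0,1) = 0.75 -> 0.5*0.6+0.5*0.75
    assert mixed_prob(model, np.array([1, 0, 1])) == pytest.approx(0.675)


def test_model_validation():
    table = solve_penetrance("threshold", (0.25, 0.25), 0.25)
    linear = sample_linear_model(2, 0.5, 0)
    with pytest.raises(ValueError, match="disjoint"):
        MixedPhenotypeModel(alpha=0.5, linear=linear, epistatic=table,
                            linear_columns=(0, 1), epistatic_columns=(1, 2))
    with pytest.raises(ValueError, match="alpha"):
        MixedPhenotypeModel(alpha=1.5, linear=linear, epistatic=table,
                            linear_columns=(0, 1), epistatic_columns=(2, 3))


# -- phenotype assignment --------------------------------------------------

def test_assign_phenotypes_degenerate_probabilities():
    assert (assign_phenotypes(np.zeros(100), seed=0) == 0).all()
    assert (assign_phenotypes(np.ones(100), seed=0) == 1).all()
    with pytest.raises(ValueError):
        assign_phenotypes(np.array([1.2]), seed=0)


def test_assign_phenotypes_concentrates_at_rate():
    p = np.full(100_000, 0.3)
    y = assign_phenotypes(p, seed=5)
    sd = np.sqrt(0.3 * 0.7 / 100_000)
    assert abs(y.mean() - 0.3) < 3 * sd


# -- balanced cohorts ------------------------------------------------------

def test_balanced_dataset_exact_quotas(threshold_table):
    model = make_model(threshold_table)
    ds = balanced_dataset(model, n=2_000, noise_snps=18, seed=9)
    assert int(ds.labels.sum()) == 1_000
    assert ds.genotypes.n_snps == 20
    assert ds.provenance["design"] == "balanced_rejection"


def test_balanced_dataset_matches_conditional_oracle(threshold_table):
    """Genotype distribution among sampled cases matches P(g|case) =
    P(g) p_g / prevalence within 3 sd per cell."""
    from epibench.penetrance import prevalence

    model = make_model(threshold_table)
    n = 100_000
    ds = balanced_dataset(model, n=n, noise_snps=0,
                          snp_mafs=np.array(threshold_table.mafs), seed=12)
    cases = ds.genotypes.values[ds.labels == 1]
    pi = prevalence(threshold_table)
    probs = threshold_table.genotype_probs()
    pen = threshold_table.as_array()
    for g1 in range(3):
        for g2 in range(3):
            expected = probs[g1, g2] * pen[g1, g2] / pi
            observed = np.mean((cases[:, 0] == g1) & (cases[:, 1] == g2))
            sd = np.sqrt(expected * (1 - expected) / cases.shape[0])
            assert abs(observed - expected) < 3 * sd + 1e-9


def test_balanced_dataset_rejects_hopeless_quota(parity_table):
    near_zero = {g: 1e-6 for g in parity_table.values}
    from epibench.penetrance import PenetranceTable

    table = PenetranceTable(order=2, mafs=(0.5, 0.5), values=near_zero)
    with pytest.raises(ValueError, match="infeasible balance"):
        balanced_dataset(make_model(table), n=100, noise_snps=0, seed=1)


# -- alpha sweep -----------------------------------------------------------

def test_alpha_sweep_shares_one_genotype_matrix(threshold_table):
    linear = sample_linear_model(4, 0.5, 1)
    genotypes = sample_genotypes(300, [0.5] * 6, seed=2)
    datasets = alpha_sweep(genotypes, linear, threshold_table, seed=3)
    assert len(datasets) == 10  # default grid: 10 evenly spaced alphas
    assert all(ds.genotypes is genotypes for ds in datasets)
    alphas = [ds.provenance["alpha"] for ds in datasets]
    assert alphas == pytest.approx(list(np.linspace(1.0, 0.0, 10)))


def test_alpha_sweep_deterministic(threshold_table):
    linear = sample_linear_model(4, 0.5, 1)
    genotypes = sample_genotypes(300, [0.5] * 6, seed=2)
    a = alpha_sweep(genotypes, linear, threshold_table, [0.3], seed=3)
    b = alpha_sweep(genotypes, linear, threshold_table, [0.3], seed=3)
    assert (a[0].labels == b[0].labels).all()


def test_alpha_one_ignores_epistatic_loci(threshold_table, additive_table):
    """At alpha=1 the labels do not depend on the penetrance table."""
    linear = sample_linear_model(4, 0.5, 1)
    genotypes = sample_genotypes(300, [0.5] * 6, seed=2)
    a = alpha_sweep(genotypes, linear, threshold_table, [1.0], seed=3)
    b = alpha_sweep(genotypes, linear, additive_table, [1.0], seed=3)
    assert (a[0].labels == b[0].labels).all()


# -- GAMETES experiment ----------------------------------------------------

def test_gametes_experiment_structure():
    datasets = gametes_experiment("threshold", replicates=2, n=400,
                                  total_snps=12, seed=4)
    assert len(datasets) == 2
    for r, ds in enumerate(datasets):
        assert ds.genotypes.n_snps == 12
        assert int(ds.labels.sum()) == 200
        assert ds.provenance["replicate"] == r
        assert ds.provenance["target_h2"] == 0.25
    # replicates differ
    assert not (datasets[0].genotypes.values == datasets[1].genotypes.values).all()


def test_gametes_three_forms_yield_thirty_datasets_at_paper_scale():
    # structural check only, at tiny n: 3 forms x replicates datasets
    out = [gametes_experiment(f, replicates=2, n=100, total_snps=4, seed=1)
           for f in ("additive", "multiplicative", "threshold")]
    assert sum(len(d) for d in out) == 6


# -- theoretical AUC -------------------------------------------------------

def test_constant_score_gives_half_auc():
    from epibench.penetrance import PenetranceTable
    import itertools

    const = PenetranceTable(order=2, mafs=(0.5, 0.5), values={
        g: 0.3 for g in itertools.product((0, 1, 2), repeat=2)})
    assert theoretical_auc(make_model(const)) == pytest.approx(0.5)


def test_deterministic_table_gives_perfect_auc(parity_table):
    from epibench.penetrance import PenetranceTable

    values = {g: float(p > 0.5) for g, p in parity_table.values.items()}
    det = PenetranceTable(order=2, mafs=(0.5, 0.5), values=values)
    assert theoretical_auc(make_model(det)) == pytest.approx(1.0)


def test_exact_auc_matches_monte_carlo(threshold_table):
    model = make_model(threshold_table)
    exact = theoretical_auc(model, "exact")
    mc = theoretical_auc(model, "monte_carlo", mc_draws=200_000, seed=8)
    assert mc == pytest.approx(exact, abs=0.01)


def test_exact_auc_capacity_error():
    table = solve_penetrance("threshold", (0.25, 0.25), 0.25)
    model = make_model(table, alpha=0.5, k=13)  # 3^15 > 10^6 classes
    with pytest.raises(ValueError, match="monte_carlo"):
        theoretical_auc(model, "exact")


def test_auc_increases_with_epistatic_effect():
    aucs = [theoretical_auc(make_model(solve_penetrance(
        "threshold", (0.25, 0.25), h2))) for h2 in (0.05, 0.15, 0.30)]
    assert aucs[0] < aucs[1] < aucs[2]
    assert all(a >= 0.5 for a in aucs)


def test_empirical_score_auc_converges_to_exact(threshold_table):
    from sklearn.metrics import roc_auc_score

    model = make_model(threshold_table)
    g = sample_genotypes(200_000, list(threshold_table.mafs), seed=6)
    scores = mixed_prob(model, g.values)
    labels = assign_phenotypes(scores, seed=7)
    exact = theoretical_auc(model, "exact")
    assert roc_auc_score(labels, scores) == pytest.approx(exact, abs=0.01)


# -- I/O -------------------------------------------------------------------

def test_dataset_round_trip(tmp_path, threshold_table):
    model = make_model(threshold_table)
    ds = balanced_dataset(model, n=100, noise_snps=3, seed=2)
    path = tmp_path / "data.tsv"
    write_dataset(ds, path)
    back = read_dataset(path)
    assert (back.genotypes.values == ds.genotypes.values).all()
    assert (back.labels == ds.labels).all()
    assert back.genotypes.snp_ids == ds.genotypes.snp_ids
    assert back.provenance["design"] == "balanced_rejection"


def test_read_dataset_requires_class_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("snp0\tsnp1\n0\t1\n")
    with pytest.raises(ValueError, match="Class"):
        read_dataset(path)
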