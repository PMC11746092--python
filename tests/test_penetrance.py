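"""Penetrance tables: construction, moments, solver, serialization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibench.penetrance import (
    EpistasisForm,
    FORMS,
    InfeasibleModelError,
    PenetranceTable,
    heritability,
    hwe_genotype_freqs,
    marchini_table,
    prevalence,
    read_table,
    solve_penetrance,
    write_table,
)


# -- independent enumeration oracles --------------------------------------

def prevalence_oracle(table):
    """Literal nested-loop sum over all cells."""
    total = 0.0
    per_locus = [hwe_genotype_freqs(m) for m in table.mafs]
    for g in itertools.product((0, 1, 2), repeat=table.order):
        pg = 1.0
        for locus, geno in enumerate(g):
            pg *= per_locus[locus][geno]
        total += pg * table.values[g]
    return total


def heritability_oracle(table):
    pi = prevalence_oracle(table)
    per_locus = [hwe_genotype_freqs(m) for m in table.mafs]
    var = 0.0
    for g in itertools.product((0, 1, 2), repeat=table.order):
        pg = 1.0
        for locus, geno in enumerate(g):
            pg *= per_locus[locus][geno]
        var += pg * (table.values[g] - pi) ** 2
    return var / (pi * (1 - pi))


# -- Hardy-Weinberg --------------------------------------------------------

@pytest.mark.parametrize(
    "maf, expected",
    [
        (0.5, (0.25, 0.5, 0.25)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.25, (0.5625, 0.375, 0.0625)),
    ],
)
def test_hwe_genotype_freqs(maf, expected):
    freqs = hwe_genotype_freqs(maf)
    assert freqs == pytest.approx(expected, abs=1e-15)
    assert sum(freqs) == pytest.approx(1.0)


@pytest.mark.parametrize("maf", [-0.01, 0.51, 1.0])
def test_hwe_rejects_out_of_range_maf(maf):
    with pytest.raises(ValueError):
        hwe_genotype_freqs(maf)


# -- table construction ----------------------------------------------------

def test_zero_effect_gives_constant_table():
    for name in FORMS:
        t = marchini_table(EpistasisForm(name, baseline=0.3, effect=0.0),
                           (0.25, 0.25))
        assert set(t.values.values()) == {0.3}


def test_threshold_form_has_exactly_two_levels():
    t = marchini_table(EpistasisForm("threshold", 0.2, 1.5), (0.25, 0.25))
    assert len(set(t.values.values())) == 2
    minor = t.values[(0, 0)]
    major = t.values[(2, 2)]
    for g, p in t.values.items():
        assert p == (major if min(g) >= 1 else minor)


def test_multiplicative_background_cells_share_one_value():
    t = marchini_table(EpistasisForm("multiplicative", 0.05, 1.0), (0.25, 0.25))
    background = {p for g, p in t.values.items() if 0 in g}
    assert background == {0.05}
    # interaction cells grow with the product of allele counts
    assert t.values[(2, 2)] > t.values[(1, 2)] > t.values[(1, 1)] > 0.05


def test_additive_form_grows_with_total_allele_count():
    t = marchini_table(EpistasisForm("additive", 0.01, 1.0), (0.25, 0.25))
    for g in t.values:
        assert t.values[g] == pytest.approx(0.01 * 2.0 ** (g[0] + g[1]))


def test_infeasible_parameters_name_the_offending_cell():
    with pytest.raises(InfeasibleModelError, match=r"genotype\s+cell \(0, 2\)"):
        marchini_table(EpistasisForm("additive", 0.5, 1.0), (0.25, 0.25))


def test_table_invariants_enforced():
    good = {g: 0.1 for g in itertools.product((0, 1, 2), repeat=2)}
    with pytest.raises(ValueError):
        PenetranceTable(order=2, mafs=(0.25,), values=good)
    bad_count = dict(list(good.items())[:-1])
    with pytest.raises(ValueError):
        PenetranceTable(order=2, mafs=(0.25, 0.25), values=bad_count)
    bad_value = {**good, (0, 0): 1.2}
    with pytest.raises(ValueError):
        PenetranceTable(order=2, mafs=(0.25, 0.25), values=bad_value)


# -- prevalence and heritability -------------------------------------------

def test_prevalence_of_constant_table():
    t = marchini_table(EpistasisForm("threshold", 0.37, 0.0), (0.3, 0.2))
    assert prevalence(t) == pytest.approx(0.37, abs=1e-15)


def test_prevalence_of_point_mass_cell():
    values = {g: 0.0 for g in itertools.product((0, 1, 2), repeat=2)}
    values[(2, 2)] = 1.0
    t = PenetranceTable(order=2, mafs=(0.5, 0.5), values=values)
    assert prevalence(t) == pytest.approx(0.0625, abs=1e-15)


def test_constant_table_has_zero_heritability():
    t = marchini_table(EpistasisForm("additive", 0.3, 0.0), (0.25, 0.25))
    assert heritability(t) == pytest.approx(0.0, abs=1e-14)


def test_deterministic_table_has_unit_heritability(parity_table):
    values = {g: float(p > 0.5) for g, p in parity_table.values.items()}
    t = PenetranceTable(order=2, mafs=(0.5, 0.5), values=values)
    assert prevalence(t) == pytest.approx(0.5)
    assert heritability(t) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("order", [2, 3])
@pytest.mark.parametrize("form", FORMS)
def test_moments_match_enumeration_oracle(form, order):
    mafs = (0.1, 0.3, 0.45)[:order]
    t = marchini_table(EpistasisForm(form, 0.01, 0.5), mafs)
    assert prevalence(t) == pytest.approx(prevalence_oracle(t), abs=1e-12)
    assert heritability(t) == pytest.approx(heritability_oracle(t), abs=1e-12)


def test_locus_permutation_symmetry():
    t = marchini_table(EpistasisForm("multiplicative", 0.05, 1.0), (0.1, 0.4))
    swapped = PenetranceTable(
        order=2, mafs=(0.4, 0.1),
        values={(g2, g1): p for (g1, g2), p in t.values.items()},
    )
    assert prevalence(swapped) == pytest.approx(prevalence(t), abs=1e-15)
    assert heritability(swapped) == pytest.approx(heritability(t), abs=1e-15)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    effect_lo=st.floats(0.1, 1.5),
    bump=st.floats(0.01, 0.6),
)
def test_penetrance_monotone_in_effect(effect_lo, bump):
    """Interaction-cell penetrance never decreases as effect grows."""
    baseline = 0.01
    for form in FORMS:
        lo = marchini_table(EpistasisForm(form, baseline, effect_lo), (0.25, 0.25))
        hi = marchini_table(EpistasisForm(form, baseline, effect_lo + bump),
                            (0.25, 0.25))
        for g in lo.values:
            if min(g) >= 1:
                assert hi.values[g] >= lo.values[g] - 1e-15


# -- solver ----------------------------------------------------------------

@pytest.mark.parametrize("form", FORMS)
@pytest.mark.parametrize("maf", [0.1, 0.25, 0.5])
@pytest.mark.parametrize("target", [0.10, 0.25, 0.50])
def test_solver_recovers_target_heritability(form, maf, target):
    t = solve_penetrance(form, (maf, maf), target)
    assert abs(heritability(t) - target) <= 1e-6
    assert all(0.0 <= p <= 1.0 for p in t.values.values())


def test_solver_small_target_limit_is_nearly_constant():
    t = solve_penetrance("additive", (0.25, 0.25), 1e-8)
    spread = max(t.values.values()) - min(t.values.values())
    assert spread < 1e-2


def test_solver_boundary_maximizes_prevalence():
    """Grid scan over interior (baseline, effect) pairs at the same
    heritability never beats the boundary solution's prevalence."""
    target = 0.25
    solved = solve_penetrance("threshold", (0.25, 0.25), target)
    best = prevalence(solved)
    from scipy.optimize import brentq

    for shrink in np.linspace(0.5, 0.99, 20):
        base, eff = solved.params
        baseline = base * shrink  # move off the max-cell=1 boundary

        def h2(e, b=baseline):
            return heritability(marchini_table(
                EpistasisForm("threshold", b, e), (0.25, 0.25))) - target

        cap = 1.0 / baseline - 1.0 - 1e-9
        hi = min(1.0, cap)
        while h2(hi) < 0 and hi < cap:
            hi = min(hi * 1.5, cap)
        if h2(hi) < 0:
            continue  # target unreachable at this interior baseline
        e = brentq(h2, 1e-9, hi)
        interior = marchini_table(EpistasisForm("threshold", baseline, e),
                                  (0.25, 0.25))
        assert prevalence(interior) <= best + 1e-9


def test_solver_rejects_invalid_targets():
    with pytest.raises(ValueError):
        solve_penetrance("additive", (0.25, 0.25), 0.0)
    with pytest.raises(ValueError):
        solve_penetrance("additive", (0.25, 0.25), 1.0)
    with pytest.raises(ValueError):
        solve_penetrance("nonsense", (0.25, 0.25), 0.25)


def test_solver_reports_unreachable_heritability():
    with pytest.raises(InfeasibleModelError, match="maximum achievable"):
        solve_penetrance("threshold", (0.5, 0.5), 1.0 - 1e-13)


# -- serialization ---------------------------------------------------------

def test_write_read_round_trip(tmp_path, additive_table):
    path = tmp_path / "table.txt"
    write_table(additive_table, path)
    back = read_table(path)
    assert back.order == additive_table.order
    assert back.mafs == additive_table.mafs
    for g in additive_table.values:
        assert back.values[g] == pytest.approx(additive_table.values[g],
                                               rel=1e-11)


def test_read_rejects_wrong_cell_count(tmp_path, additive_table):
    path = tmp_path / "table.txt"
    write_table(additive_table, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:-1]) + "\n")  # drop one cell
    with pytest.raises(ValueError, match="expected 9 cells"):
        read_table(path)


def test_read_rejects_out_of_range_penetrance(tmp_path, additive_table):
    path = tmp_path / "table.txt"
    write_table(additive_table, path)
    text = path.read_text().splitlines()
    text[-1] = "2,2\t1.2"
    path.write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="outside"):
        read_table(path)
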