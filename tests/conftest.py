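"""Shared fixtures: small solved tables and deterministic generators."""

import itertools

import numpy as np
import pytest

from epibench.penetrance import PenetranceTable, solve_penetrance


@pytest.fixture(scope="session")
def threshold_table():
    return solve_penetrance("threshold", (0.25, 0.25), 0.25)


@pytest.fixture(scope="session")
def additive_table():
    return solve_penetrance("additive", (0.25, 0.25), 0.25)


@pytest.fixture(scope="session")
def parity_table():
    """XOR-like deterministic-free table: penetrance 0.75 when the total
    allele count is odd, 0.25 otherwise; at MAF 0.5 both marginal effects
    vanish exactly while prevalence is 0.5 and heritability 0.25."""
    values = {
        g: 0.75 if (g[0] + g[1]) % 2 else 0.25
        for g in itertools.product((0, 1, 2), repeat=2)
    }
    return PenetranceTable(order=2, mafs=(0.5, 0.5), values=values,
                           form="parity")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
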