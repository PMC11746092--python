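"""Epistatic penetrance tables and the heritability-constrained solver.

A penetrance table maps each genotype combination of the interacting loci
(coded 0/1/2 copies of the minor allele) to the probability of disease.
Tables here follow the classical two-locus disease-odds taxonomy of
additive, multiplicative and threshold interaction, parameterized on the
penetrance scale as ``p(g) = baseline * (1 + effect)^f(g)`` with

* additive        f(g) = g1 + g2 (+ g3)          — risk grows with every
  causal allele, within and between loci;
* multiplicative  f(g) = g1 * g2 (* g3) when all loci carry at least one
  causal allele, else 0 — a constant background unless every locus is hit;
* threshold       f(g) = 1 when all loci carry at least one causal allele,
  else 0 — exactly two penetrance levels.

Given a target broad-sense heritability on the observed binary scale,
``solve_penetrance`` finds the (baseline, effect) pair that attains it
while maximizing the population prevalence; the maximum is reached on the
feasibility boundary where the largest table cell equals 1, which reduces
the search to a one-dimensional root-find in ``effect``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PenetranceTable",
    "EpistasisForm",
    "FORMS",
    "hwe_genotype_freqs",
    "marchini_table",
    "prevalence",
    "heritability",
    "solve_penetrance",
    "read_table",
    "write_table",
    "InfeasibleModelError",
]

FORMS = ("additive", "multiplicative", "threshold")

#: Tolerance on |heritability(table) - target| accepted by the solver.
SOLVER_TOL = 1e-10


class InfeasibleModelError(ValueError):
    """No penetrance table satisfies the requested constraints."""


def hwe_genotype_freqs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities (P(g=0), P(g=1), P(g=2)).

    Parameters
    ----------
    maf : minor-allele frequency, in [0, 0.5].
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    q = float(maf)
    return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


@dataclass(frozen=True)
class PenetranceTable:
    """Disease probabilities for every genotype combination of ``order`` loci.

    Attributes
    ----------
    order : number of interacting loci (2 or 3 in practice).
    mafs : per-locus minor-allele frequencies, each in (0, 0.5].
    values : mapping from genotype tuples in {0,1,2}^order to penetrance.
    form : optional name of the generating interaction form.
    params : optional (baseline, effect) used to generate the table.
    """

    order: int
    mafs: tuple[float, ...]
    values: dict[tuple[int, ...], float]
    form: str | None = None
    params: tuple[float, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if len(self.mafs) != self.order:
            raise ValueError("one MAF per locus required")
        for m in self.mafs:
            if not 0.0 < m <= 0.5:
                raise ValueError(f"MAF must lie in (0, 0.5], got {m}")
        cells = set(itertools.product((0, 1, 2), repeat=self.order))
        if set(self.values) != cells:
            raise ValueError(
                f"table must have exactly {3**self.order} cells, one per "
                f"genotype tuple; got {len(self.values)}"
            )
        for g, p in self.values.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance at {g} outside [0, 1]: {p}")

    # -- convenience views ------------------------------------------------
    def genotypes(self) -> list[tuple[int, ...]]:
        """Genotype tuples in lexicographic order."""
        return sorted(self.values)

    def as_array(self) -> np.ndarray:
        """Penetrances as an array of shape (3,)*order."""
        arr = np.empty((3,) * self.order)
        for g, p in self.values.items():
            arr[g] = p
        return arr

    def genotype_probs(self) -> np.ndarray:
        """Hardy-Weinberg probability of each cell, shape (3,)*order."""
        per_locus = [np.array(hwe_genotype_freqs(m)) for m in self.mafs]
        probs = per_locus[0]
        for v in per_locus[1:]:
            probs = np.multiply.outer(probs, v)
        return probs

    def lookup(self, genotype: tuple[int, ...]) -> float:
        return self.values[tuple(int(g) for g in genotype)]


@dataclass(frozen=True)
class EpistasisForm:
    """Interaction form with its penetrance-scale parameters.

    ``baseline`` is the penetrance of the background cells and ``effect``
    the multiplicative per-step risk increase (Marchini's alpha and theta).
    """

    name: str
    baseline: float
    effect: float

    def __post_init__(self) -> None:
        if self.name not in FORMS:
            raise ValueError(f"unknown form {self.name!r}; expected one of {FORMS}")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")


def _exponent(name: str, genotype: tuple[int, ...]) -> int:
    if name == "additive":
        return sum(genotype)
    all_hit = all(g >= 1 for g in genotype)
    if name == "multiplicative":
        return math.prod(genotype) if all_hit else 0
    # threshold
    return 1 if all_hit else 0


def _max_exponent(name: str, order: int) -> int:
    return _exponent(name, (2,) * order)


def marchini_table(
    form: EpistasisForm, mafs: tuple[float, ...] | list[float]
) -> PenetranceTable:
    """Build the penetrance table for a parameterized interaction form.

    Raises
    ------
    InfeasibleModelError
        If any cell's penetrance ``baseline * (1+effect)^f(g)`` exceeds 1;
        the error names the offending genotype cell.
    """
    mafs = tuple(float(m) for m in mafs)
    order = len(mafs)
    values: dict[tuple[int, ...], float] = {}
    for g in itertools.product((0, 1, 2), repeat=order):
        p = form.baseline * (1.0 + form.effect) ** _exponent(form.name, g)
        if p > 1.0 + 1e-12:
            raise InfeasibleModelError(
                f"infeasible parameters: penetrance {p:.6g} > 1 at genotype "
                f"cell {g} (form={form.name}, baseline={form.baseline}, "
                f"effect={form.effect})"
            )
        values[g] = min(p, 1.0)
    return PenetranceTable(
        order=order,
        mafs=mafs,
        values=values,
        form=form.name,
        params=(form.baseline, form.effect),
    )


def prevalence(table: PenetranceTable) -> float:
    """Population disease probability: sum over cells of P(g) * p(g)."""
    return float(np.sum(table.genotype_probs() * table.as_array()))


def heritability(table: PenetranceTable) -> float:
    """Broad-sense heritability of the binary trait on the observed scale.

    ``sum_g P(g) (p_g - pi)^2 / (pi (1 - pi))`` with pi the prevalence —
    the fraction of phenotypic (Bernoulli) variance explained by genotype.
    """
    pi = prevalence(table)
    if not 0.0 < pi < 1.0:
        raise InfeasibleModelError(
            f"heritability undefined at prevalence {pi}: no phenotypic variance"
        )
    probs = table.genotype_probs()
    pen = table.as_array()
    return float(np.sum(probs * (pen - pi) ** 2) / (pi * (1.0 - pi)))


def _boundary_table(name: str, mafs: tuple[float, ...], effect: float) -> PenetranceTable:
    """Table with the largest cell pinned at penetrance exactly 1."""
    baseline = (1.0 + effect) ** (-_max_exponent(name, len(mafs)))
    return marchini_table(EpistasisForm(name, baseline, effect), mafs)


def solve_penetrance(
    form_name: str,
    mafs: tuple[float, ...] | list[float],
    target_h2: float,
) -> PenetranceTable:
    """Solve for the maximum-prevalence table with the target heritability.

    Along the ``baseline = (1+effect)^(-f_max)`` boundary (largest cell at
    penetrance 1) heritability increases monotonically from 0 with
    ``effect`` while prevalence decreases, so the boundary point hitting
    the target heritability is the prevalence-maximizing feasible table.

    Raises
    ------
    InfeasibleModelError
        If the target heritability exceeds the supremum achievable for
        this form and MAF combination; the message reports that maximum.
    """
    if form_name not in FORMS:
        raise ValueError(f"unknown form {form_name!r}; expected one of {FORMS}")
    if not 0.0 < target_h2 < 1.0:
        raise ValueError(f"target heritability must lie in (0, 1), got {target_h2}")
    mafs = tuple(float(m) for m in mafs)

    def h2_at(effect: float) -> float:
        return heritability(_boundary_table(form_name, mafs, effect))

    # at effect -> 0+ the boundary table tends to all-ones (h2 -> 0);
    # start the bracket just above that degenerate point
    lo, hi = 1e-12, 1.0
    while h2_at(hi) < target_h2:
        hi *= 2.0
        if hi > 1e12:
            # supremum reached numerically; report the ceiling
            raise InfeasibleModelError(
                f"no {form_name} table at mafs={mafs} reaches heritability "
                f"{target_h2}; maximum achievable is about {h2_at(1e12):.6f}"
            )
    effect = brentq(lambda e: h2_at(e) - target_h2, lo, hi, xtol=1e-14, rtol=8.9e-16)
    table = _boundary_table(form_name, mafs, effect)
    achieved = heritability(table)
    if abs(achieved - target_h2) > max(SOLVER_TOL, 1e-6):
        raise InfeasibleModelError(
            f"solver failed to converge: achieved h2 {achieved} vs target {target_h2}"
        )
    return table


# -- serialization ---------------------------------------------------------

def write_table(table: PenetranceTable, path: str | Path) -> None:
    """Write a table as plain text: header lines then one cell per line."""
    path = Path(path)
    lines = [f"#order={table.order}", "#maf=" + ",".join(repr(m) for m in table.mafs)]
    for g in table.genotypes():
        lines.append(",".join(str(x) for x in g) + "\t" + f"{table.values[g]:.12g}")
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> PenetranceTable:
    """Read a table written by :func:`write_table`.

    Raises ``ValueError`` naming the offending line on malformed input,
    wrong cell count, or penetrance outside [0, 1].
    """
    path = Path(path)
    order: int | None = None
    mafs: tuple[float, ...] | None = None
    values: dict[tuple[int, ...], float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#order="):
            order = int(line.split("=", 1)[1])
            continue
        if line.startswith("#maf="):
            mafs = tuple(float(x) for x in line.split("=", 1)[1].split(","))
            continue
        try:
            geno_s, pen_s = line.split("\t")
            genotype = tuple(int(x) for x in geno_s.split(","))
            pen = float(pen_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed table line {raw!r}") from exc
        if any(g not in (0, 1, 2) for g in genotype):
            raise ValueError(f"{path}:{lineno}: genotype codes must be 0/1/2")
        if not 0.0 <= pen <= 1.0:
            raise ValueError(f"{path}:{lineno}: penetrance {pen} outside [0, 1]")
        values[genotype] = pen
    if order is None or mafs is None:
        raise ValueError(f"{path}: missing #order= or #maf= header")
    if len(values) != 3**order:
        raise ValueError(
            f"{path}: expected {3**order} cells for order {order}, got {len(values)}"
        )
    return PenetranceTable(order=order, mafs=mafs, values=values)
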