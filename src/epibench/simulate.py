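"""Synthetic case-control cohorts with mixed linear and epistatic risk.

The generative model assigns each individual a disease probability

    P(Y=1 | x) = alpha * P_lin(Y=1 | x_1..x_k) + (1 - alpha) * p(x_e)

where ``P_lin`` is a logistic model over k linear-effect SNPs, ``p`` is a
penetrance-table lookup over the 2 or 3 epistatic loci, and ``alpha`` in
[0, 1] dials the mixture from purely linear (alpha=1) to purely epistatic
(alpha=0). Genotypes are 0/1/2 minor-allele counts drawn independently per
SNP under Hardy-Weinberg frequencies; the default MAF of 0.5 yields the
0.25 / 0.5 / 0.25 genotype mix. Balanced case-control cohorts are obtained
by rejection sampling to exact 50/50 quotas.

All randomness flows from one root seed through named sub-streams so every
experiment is replayable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .penetrance import (
    PenetranceTable,
    hwe_genotype_freqs,
    prevalence,
    solve_penetrance,
)

__all__ = [
    "GenotypeMatrix",
    "LinearEffectModel",
    "MixedPhenotypeModel",
    "Dataset",
    "rng_for",
    "sample_genotypes",
    "sample_linear_model",
    "linear_prob",
    "mixed_prob",
    "assign_phenotypes",
    "balanced_dataset",
    "alpha_sweep",
    "gametes_experiment",
    "theoretical_auc",
    "write_dataset",
    "read_dataset",
]

#: Default MAF giving the 0.25/0.5/0.25 genotype frequency mix.
DEFAULT_GENOTYPE_MAF = 0.5

_STREAMS = {
    "genotypes": 1,
    "coefficients": 2,
    "labels": 3,
    "splits": 4,
    "training": 5,
    "montecarlo": 6,
}


def rng_for(root_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Named, replayable random sub-stream derived from one root seed."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown stream {stream!r}; expected one of {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(root_seed) % (2**31),
                                spawn_key=(_STREAMS[stream], int(index)))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x SNPs matrix of minor-allele counts in {0, 1, 2}."""

    values: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if v.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must equal column count")
        if v.size and not np.isin(v, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LinearEffectModel:
    """Logistic linear SNP model: logit P = intercept + coefficients . x."""

    intercept: float
    coefficients: np.ndarray
    coefficient_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.coefficient_sd < 0:
            raise ValueError("coefficient_sd must be non-negative")


@dataclass(frozen=True)
class MixedPhenotypeModel:
    """Mixture of a logistic linear part and an epistatic penetrance table.

    ``linear_columns`` and ``epistatic_columns`` index into the genotype
    matrix the model is evaluated against; they must be disjoint.
    """

    alpha: float
    linear: LinearEffectModel
    epistatic: PenetranceTable
    linear_columns: tuple[int, ...]
    epistatic_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if len(self.linear_columns) != len(self.linear.coefficients):
            raise ValueError("linear_columns must match coefficient count")
        if len(self.epistatic_columns) != self.epistatic.order:
            raise ValueError("epistatic_columns must match table order")
        if set(self.linear_columns) & set(self.epistatic_columns):
            raise ValueError("linear and epistatic column sets must be disjoint")


@dataclass(frozen=True)
class Dataset:
    """A genotype matrix with binary phenotype labels and provenance."""

    genotypes: GenotypeMatrix
    labels: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.labels)
        if y.shape != (self.genotypes.n_individuals,):
            raise ValueError("labels length must equal individual count")
        if y.size and not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")


# -- generation ------------------------------------------------------------

def sample_genotypes(
    n: int,
    snp_mafs: np.ndarray | list[float],
    seed: int | np.random.Generator,
    snp_ids: tuple[str, ...] | None = None,
) -> GenotypeMatrix:
    """Draw an n x len(snp_mafs) genotype matrix under Hardy-Weinberg."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = np.asarray(snp_mafs, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "genotypes")
    # per-SNP inverse-CDF draw: cheaper than choice() per column
    u = rng.random((n, mafs.size))
    cum = np.empty((mafs.size, 2))
    for j, m in enumerate(mafs):
        p0, p1, _ = hwe_genotype_freqs(m)
        cum[j] = (p0, p0 + p1)
    values = (u >= cum[:, 0]).astype(np.int8) + (u >= cum[:, 1]).astype(np.int8)
    if snp_ids is None:
        snp_ids = tuple(f"snp{j}" for j in range(mafs.size))
    return GenotypeMatrix(values=values, snp_ids=snp_ids)


def sample_linear_model(
    k: int,
    coefficient_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    intercept: float | None = None,
) -> LinearEffectModel:
    """Sample intercept and k coefficients i.i.d. from N(0, coefficient_sd^2).

    ``coefficient_sd`` is the standard deviation. Pass ``intercept`` to
    override the sampled value.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "coefficients")
    draws = rng.normal(0.0, coefficient_sd, size=k + 1)
    b0 = float(draws[0]) if intercept is None else float(intercept)
    return LinearEffectModel(intercept=b0, coefficients=draws[1:],
                             coefficient_sd=coefficient_sd)


def linear_prob(model: LinearEffectModel, genotype_rows: np.ndarray) -> np.ndarray:
    """Logistic probability of the linear part, numerically stable.

    Accepts a single row (1-D) or a matrix of rows over the linear columns.
    """
    x = np.atleast_2d(np.asarray(genotype_rows, dtype=float))
    if x.shape[1] != len(model.coefficients):
        raise ValueError("row length must match coefficient count")
    logit = model.intercept + x @ model.coefficients
    # stable logistic: exp of a non-positive argument only
    out = np.empty_like(logit)
    pos = logit >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-logit[pos]))
    e = np.exp(logit[~pos])
    out[~pos] = e / (1.0 + e)
    return out if np.asarray(genotype_rows).ndim > 1 else float(out[0])


def mixed_prob(model: MixedPhenotypeModel, genotype_rows: np.ndarray) -> np.ndarray:
    """Disease probability under the mixed linear + epistatic model."""
    x = np.atleast_2d(np.asarray(genotype_rows))
    lin = np.atleast_1d(linear_prob(model.linear, x[:, list(model.linear_columns)]))
    pen_arr = model.epistatic.as_array()
    epi_geno = x[:, list(model.epistatic_columns)].astype(int)
    epi = pen_arr[tuple(epi_geno.T)]
    p = model.alpha * lin + (1.0 - model.alpha) * epi
    return p if np.asarray(genotype_rows).ndim > 1 else float(p[0])


def assign_phenotypes(
    probabilities: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli labels from per-individual probabilities."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "labels")
    return (rng.random(p.shape) < p).astype(np.int8)


def _causal_columns(model: MixedPhenotypeModel) -> list[int]:
    return sorted(set(model.linear_columns) | set(model.epistatic_columns))


def balanced_dataset(
    model: MixedPhenotypeModel,
    n: int,
    noise_snps: int,
    snp_mafs: float | np.ndarray = DEFAULT_GENOTYPE_MAF,
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Rejection-sample a cohort with exactly n/2 cases and n/2 controls.

    Individuals are generated (genotype, mixed probability, Bernoulli
    label) and kept until both class quotas fill. Only the causal columns
    are drawn during rejection; the ``noise_snps`` effect-free SNPs are
    attached to accepted individuals afterwards, which is distributionally
    identical because noise genotypes are independent of the label.
    """
    if n % 2:
        raise ValueError("n must be even for exact 50/50 balance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence(int(seed) % (2**31))
    )
    causal = _causal_columns(model)
    n_causal = len(causal)
    total_snps = n_causal + noise_snps
    mafs = np.broadcast_to(np.asarray(snp_mafs, dtype=float), (total_snps,))
    if sorted(causal) != list(range(n_causal)):
        raise ValueError("causal columns must be the leading columns")

    # expected per-draw acceptance probability per class
    probe = sample_genotypes(4096, mafs[causal], rng)
    p_probe = mixed_prob(model, probe.values)
    exp_case, exp_control = float(np.mean(p_probe)), float(np.mean(1 - p_probe))
    for name, acc in (("case", exp_case), ("control", exp_control)):
        if acc < 1e-4:
            raise ValueError(
                f"infeasible balance: expected {name} acceptance probability "
                f"{acc:.2e} below 1e-4"
            )

    quota = n // 2
    kept_rows: list[np.ndarray] = []
    kept_labels: list[np.ndarray] = []
    need_case, need_control = quota, quota
    while need_case > 0 or need_control > 0:
        remaining = need_case / max(exp_case, 1e-6) + need_control / max(exp_control, 1e-6)
        batch = int(min(max(4096, 1.3 * remaining), 4_000_000))
        g = sample_genotypes(batch, mafs[causal], rng)
        p = mixed_prob(model, g.values)
        y = (rng.random(batch) < p).astype(np.int8)
        for label, need in ((1, need_case), (0, need_control)):
            if need <= 0:
                continue
            idx = np.flatnonzero(y == label)[:need]
            kept_rows.append(g.values[idx])
            kept_labels.append(np.full(idx.size, label, dtype=np.int8))
        need_case = quota - sum(int((l == 1).sum()) for l in kept_labels)
        need_control = quota - sum(int((l == 0).sum()) for l in kept_labels)

    causal_g = np.concatenate(kept_rows)
    labels = np.concatenate(kept_labels)
    order = rng.permutation(n)
    causal_g, labels = causal_g[order], labels[order]

    if noise_snps:
        noise = sample_genotypes(n, mafs[n_causal:], rng)
        values = np.concatenate([causal_g, noise.values], axis=1)
    else:
        values = causal_g
    snp_ids = tuple(f"snp{j}" for j in range(total_snps))
    genotypes = GenotypeMatrix(values=values, snp_ids=snp_ids)
    prov = {
        "design": "balanced_rejection",
        "n": n,
        "alpha": model.alpha,
        "form": model.epistatic.form,
        "epistatic_columns": tuple(model.epistatic_columns),
        "linear_columns": tuple(model.linear_columns),
        "noise_snps": noise_snps,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
    }
    return Dataset(genotypes=genotypes, labels=labels, provenance=prov)


def alpha_sweep(
    base_genotypes: GenotypeMatrix,
    linear: LinearEffectModel,
    table: PenetranceTable,
    alphas: np.ndarray | list[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[Dataset]:
    """One label vector per alpha over a single shared genotype matrix.

    The default grid is 10 evenly spaced values from 1.0 down to 0.0. The
    linear columns are the leading k columns and the epistatic loci the
    next ``table.order`` columns.
    """
    if alphas is None:
        alphas = np.linspace(1.0, 0.0, 10)
    alphas = [float(a) for a in alphas]
    if any(not 0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    k = len(linear.coefficients)
    lin_cols = tuple(range(k))
    epi_cols = tuple(range(k, k + table.order))
    root = seed if isinstance(seed, np.random.Generator) else None
    datasets = []
    for i, a in enumerate(alphas):
        model = MixedPhenotypeModel(
            alpha=a, linear=linear, epistatic=table,
            linear_columns=lin_cols, epistatic_columns=epi_cols,
        )
        p = mixed_prob(model, base_genotypes.values)
        label_rng = root if root is not None else rng_for(int(seed), "labels", i)
        labels = assign_phenotypes(p, label_rng)
        prov = {"design": "alpha_sweep", "alpha": a, "form": table.form,
                "linear_columns": lin_cols, "epistatic_columns": epi_cols,
                "seed": None if root is not None else int(seed)}
        datasets.append(Dataset(genotypes=base_genotypes, labels=labels, provenance=prov))
    return datasets


def gametes_experiment(
    form_name: str,
    target_h2: float = 0.25,
    mafs: tuple[float, float] = (0.25, 0.25),
    replicates: int = 10,
    n: int = 20_000,
    total_snps: int = 1_000,
    seed: int = 0,
) -> list[Dataset]:
    """Balanced pure-epistasis replicates in the GAMETES style.

    Solves the penetrance table once for (form, mafs, heritability), then
    generates ``replicates`` independent balanced cohorts at alpha=0 with
    ``len(mafs)`` causal loci and ``total_snps - len(mafs)`` noise SNPs.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    table = solve_penetrance(form_name, mafs, target_h2)
    order = table.order
    model = MixedPhenotypeModel(
        alpha=0.0,
        linear=LinearEffectModel(intercept=0.0, coefficients=np.empty(0)),
        epistatic=table,
        linear_columns=(),
        epistatic_columns=tuple(range(order)),
    )
    causal_mafs = np.asarray(mafs, dtype=float)
    noise = total_snps - order
    datasets = []
    for r in range(replicates):
        rng = rng_for(seed, "genotypes", index=r)
        snp_mafs = np.concatenate([causal_mafs,
                                   np.full(noise, DEFAULT_GENOTYPE_MAF)])
        ds = balanced_dataset(model, n=n, noise_snps=noise,
                              snp_mafs=snp_mafs, seed=rng)
        ds = replace(ds, provenance={**ds.provenance, "design": "gametes",
                                     "replicate": r, "form": form_name,
                                     "target_h2": target_h2, "seed": int(seed)})
        datasets.append(ds)
    return datasets


# -- theoretical AUC -------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 10**6


def _score_distribution(model: MixedPhenotypeModel) -> tuple[np.ndarray, np.ndarray]:
    """Distinct mixed-probability scores and their genotype probabilities."""
    # at the mixture extremes the score ignores one column set entirely,
    # which keeps exact enumeration feasible for large k at alpha=0
    if model.alpha == 0.0 and model.linear_columns:
        model = replace(model, linear=LinearEffectModel(0.0, np.empty(0)),
                        linear_columns=())
    if model.alpha == 1.0 and model.epistatic_columns:
        # dummy single-locus constant table so enumeration is cheap
        one = PenetranceTable(order=1, mafs=(0.5,),
                              values={(0,): 0.5, (1,): 0.5, (2,): 0.5})
        free = max(max(model.linear_columns, default=-1) + 1, 0)
        model = replace(model, epistatic=one, epistatic_columns=(free,))
    k = len(model.linear_columns)
    order = model.epistatic.order
    if 3 ** (k + order) > EXACT_ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration over 3^{k + order} genotype classes exceeds "
            f"{EXACT_ENUMERATION_LIMIT}; use method='monte_carlo'"
        )
    combos = np.array(list(itertools.product((0, 1, 2), repeat=k + order)),
                      dtype=np.int8)
    # genotype matrix containing only the causal columns, in model order
    cols = list(model.linear_columns) + list(model.epistatic_columns)
    width = max(cols) + 1 if cols else 0
    g = np.zeros((combos.shape[0], width), dtype=np.int8)
    for j, c in enumerate(cols):
        g[:, c] = combos[:, j]
    scores = np.atleast_1d(mixed_prob(model, g))
    # per-combo probability: product of HWE freqs at MAF 0.5 for linear
    # columns is not assumed — linear SNP MAFs default to 0.5
    lin_freqs = np.array(hwe_genotype_freqs(DEFAULT_GENOTYPE_MAF))
    probs = np.ones(combos.shape[0])
    for j in range(k):
        probs *= lin_freqs[combos[:, j]]
    per_locus = [np.array(hwe_genotype_freqs(m)) for m in model.epistatic.mafs]
    for j in range(order):
        probs *= per_locus[j][combos[:, k + j]]
    # collapse equal scores
    uniq, inv = np.unique(np.round(scores, 12), return_inverse=True)
    agg = np.zeros(uniq.size)
    np.add.at(agg, inv, probs)
    return uniq, agg


def theoretical_auc(
    model: MixedPhenotypeModel,
    method: str = "exact",
    mc_draws: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """AUC of the ground-truth disease probability used as the score.

    With labels drawn from Bernoulli(s(g)) and the score s(g) itself, this
    is the ceiling for any trained classifier:

        AUC = sum_{i,j} P(s_i) P(s_j) s_i (1 - s_j) [1(s_i > s_j) + 1/2 1(s_i = s_j)]
              / (pi (1 - pi)),   pi = sum P(s) s.

    ``method='exact'`` enumerates the distinct score classes (requires at
    most 10^6); ``method='monte_carlo'`` estimates the same quantity from
    ``mc_draws`` simulated individuals.
    """
    if method == "exact":
        s, p = _score_distribution(model)
        pi = float(np.sum(p * s))
        if not 0.0 < pi < 1.0:
            return 0.5
        # s sorted ascending from np.unique; use cumulative sums over j < i
        w_control = p * (1.0 - s)
        cum_control = np.concatenate([[0.0], np.cumsum(w_control)])[:-1]
        num = float(np.sum(p * s * cum_control) + 0.5 * np.sum(p * s * w_control))
        return num / (pi * (1.0 - pi))
    if method == "monte_carlo":
        rng = (seed if isinstance(seed, np.random.Generator)
               else rng_for(seed, "montecarlo"))
        cols = list(model.linear_columns) + list(model.epistatic_columns)
        width = max(cols) + 1 if cols else 1
        mafs = np.full(width, DEFAULT_GENOTYPE_MAF)
        for j, c in enumerate(model.epistatic_columns):
            mafs[c] = model.epistatic.mafs[j]
        g = sample_genotypes(mc_draws, mafs, rng)
        scores = np.atleast_1d(mixed_prob(model, g.values))
        labels = (rng.random(mc_draws) < scores).astype(np.int8)
        from sklearn.metrics import roc_auc_score

        if labels.min() == labels.max():
            return 0.5
        return float(roc_auc_score(labels, scores))
    raise ValueError("method must be 'exact' or 'monte_carlo'")


# -- dataset I/O -----------------------------------------------------------

def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """GAMETES-style TSV: SNP-id header plus final ``Class`` column.

    A human-readable provenance sidecar is written next to the data file.
    """
    path = Path(path)
    header = "\t".join(dataset.genotypes.snp_ids + ("Class",))
    body = np.concatenate(
        [dataset.genotypes.values, dataset.labels[:, None]], axis=1
    )
    with path.open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%d", delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".provenance.txt")
    with sidecar.open("w") as fh:
        for key, value in sorted(dataset.provenance.items()):
            fh.write(f"{key}: {value}\n")


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[-1] != "Class":
            raise ValueError(f"{path}: final header column must be 'Class'")
        body = np.loadtxt(fh, dtype=np.int8, delimiter="\t", ndmin=2)
    snp_ids = tuple(header[:-1])
    genotypes = GenotypeMatrix(values=body[:, :-1], snp_ids=snp_ids)
    prov: dict = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.txt")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if ": " in line:
                key, value = line.split(": ", 1)
                prov[key] = value
    return Dataset(genotypes=genotypes, labels=body[:, -1], provenance=prov)
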