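"""Synthetic expression compendia with implanted constant-column biclusters.

The generator emulates the data regime the model assumes: each array has its
own background Normal (mean and spread drawn once per array), and an
implanted bicluster displaces the means of its member columns by a stated
number of that array's background sigmas -- with a random sign per column,
so member genes are coherently up- or down-shifted per condition but the
bicluster is not a trivial all-up block.  Within a member column the member
genes scatter with a small within-bicluster sigma, giving the tight
constant-column structure the model searches for.  Values are missing
completely at random at a configurable rate.

Also here: contamination of seed sets with random genes (the noisy-seed
protocol) and seed/validation splits for cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from probic.matrix import ExpressionMatrix


@dataclass
class ImplantSpec:
    """One implanted bicluster: size, displacement, and tightness.

    ``shift`` is the column-mean displacement in units of that array's
    background sigma; ``noise_sigma`` is the within-bicluster standard
    deviation in expression units.
    """

    n_genes: int
    n_arrays: int
    shift: float = 2.0
    noise_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_arrays < 1:
            raise ValueError("implant needs at least 1 gene and 1 array")
        if self.shift < 0:
            raise ValueError("shift (displacement) must be >= 0")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_arrays: int = 50
    background_mu_range: tuple[float, float] = (-0.5, 0.5)
    background_sigma_range: tuple[float, float] = (0.8, 1.2)
    biclusters: list[ImplantSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.biclusters = [
            b if isinstance(b, ImplantSpec) else ImplantSpec(**b)
            for b in self.biclusters
        ]
        if self.n_genes < 2 or self.n_arrays < 2:
            raise ValueError("need at least 2 genes and 2 arrays")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.background_sigma_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid background_sigma_range")
        for b in self.biclusters:
            if b.n_genes > self.n_genes or b.n_arrays > self.n_arrays:
                raise ValueError("implanted bicluster larger than the matrix")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background_mu_range"] = list(self.background_mu_range)
        d["background_sigma_range"] = list(self.background_sigma_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key in ("background_mu_range", "background_sigma_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Implant:
    gene_ids: list[str]
    array_ids: list[str]
    true_means: dict[str, float]  # array id -> implanted column mean


@dataclass
class GroundTruth:
    background_mu: dict[str, float]
    background_sigma: dict[str, float]
    implants: list[Implant]

    def to_dict(self) -> dict:
        return {
            "background_mu": self.background_mu,
            "background_sigma": self.background_sigma,
            "implants": [asdict(i) for i in self.implants],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def implanted_demo_config(rng_seed: int = 0) -> SimulationConfig:
    """The standard single-implant scenario used throughout the test bench.

    A 200 x 50 compendium with one 20-gene x 10-array bicluster displaced by
    2 background sigmas per member column at within-bicluster sigma 0.25 --
    a clearly expressed module of realistic size, strong enough that a clean
    query should recover it and small enough to run hundreds of repeats.
    """
    return SimulationConfig(
        n_genes=200,
        n_arrays=50,
        biclusters=[ImplantSpec(n_genes=20, n_arrays=10, shift=2.0, noise_sigma=0.25)],
        rng_seed=rng_seed,
    )


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a matrix and its ground truth, fully reproducible from rng_seed.

    Background cells are per-array Normal; implanted member cells are Normal
    around the displaced column mean.  Overlapping implants are allowed; a
    cell claimed twice is owned by the later bicluster (whose mean is the
    one recorded last in the ground truth).
    """
    rng = np.random.default_rng(config.rng_seed)
    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)
    array_ids = np.array([f"A{j:03d}" for j in range(config.n_arrays)], dtype=object)
    mu_lo, mu_hi = config.background_mu_range
    sg_lo, sg_hi = config.background_sigma_range
    mu_a = rng.uniform(mu_lo, mu_hi, size=config.n_arrays)
    sigma_a = rng.uniform(sg_lo, sg_hi, size=config.n_arrays)
    values = rng.normal(mu_a, sigma_a, size=(config.n_genes, config.n_arrays))

    implants: list[Implant] = []
    for spec in config.biclusters:
        g_idx = rng.choice(config.n_genes, size=spec.n_genes, replace=False)
        a_idx = rng.choice(config.n_arrays, size=spec.n_arrays, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.n_arrays)
        true_mean = mu_a[a_idx] + signs * spec.shift * sigma_a[a_idx]
        block = rng.normal(
            true_mean, spec.noise_sigma, size=(spec.n_genes, spec.n_arrays)
        )
        values[np.ix_(g_idx, a_idx)] = block
        implants.append(
            Implant(
                gene_ids=[str(g) for g in gene_ids[np.sort(g_idx)]],
                array_ids=[str(a) for a in array_ids[np.sort(a_idx)]],
                true_means={
                    str(array_ids[a]): float(m)
                    for a, m in sorted(zip(a_idx, true_mean))
                },
            )
        )

    mask = np.ones_like(values, dtype=bool)
    if config.missing_rate > 0.0:
        mask = rng.random(values.shape) >= config.missing_rate
    values = np.where(mask, values, np.nan)
    matrix = ExpressionMatrix(gene_ids, array_ids, values, mask)
    truth = GroundTruth(
        background_mu={str(a): float(m) for a, m in zip(array_ids, mu_a)},
        background_sigma={str(a): float(s) for a, s in zip(array_ids, sigma_a)},
        implants=implants,
    )
    return matrix, truth


def make_noisy_seed(
    true_seeds: Iterable[str],
    all_genes: Iterable[str],
    noise_fraction: float,
    rng_seed: int,
) -> tuple[list[str], list[str]]:
    """Contaminate a seed set with random genes at a target fraction.

    Draws r genes from ``all_genes`` minus the true seeds, without
    replacement, with r chosen so that r / (|true| + r) is as close as
    possible to ``noise_fraction`` (ties toward fewer noise genes).
    Returns (full contaminated seed list, the noise sublist).
    """
    true_list = sorted(set(true_seeds))
    pool = sorted(set(all_genes) - set(true_list))
    if not set(true_seeds) <= set(all_genes):
        raise ValueError("true_seeds must be contained in all_genes")
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must lie in [0, 1)")
    t = len(true_list)
    best_r = 0
    best_err = abs(0.0 - noise_fraction)
    for r in range(0, len(pool) + 1):
        err = abs(r / (t + r) - noise_fraction)
        if err < best_err - 1e-12:
            best_err = err
            best_r = r
    if noise_fraction > 0 and best_r == 0 and len(pool) == 0:
        raise ValueError("not enough non-seed genes to add noise")
    if best_r > len(pool):
        raise ValueError("not enough non-seed genes to reach the noise fraction")
    rng = np.random.default_rng(rng_seed)
    noise = [pool[i] for i in rng.choice(len(pool), size=best_r, replace=False)]
    return true_list + sorted(noise), sorted(noise)


def cv_split(
    regulon_genes: Iterable[str], n_folds: int = 5, rng_seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Seed/validation splits for n-fold cross-validation of a regulon.

    The genes are randomly partitioned into ``n_folds`` near-equal
    validation folds; split i uses fold i for validation and the rest as
    seeds (four fifths seed, one fifth validation at the default 5 folds).
    Regulons below 5 genes are not eligible.
    """
    genes = sorted(set(regulon_genes))
    if len(genes) < 5:
        raise ValueError(
            f"regulon has {len(genes)} genes; cross-validation requires >= 5"
        )
    if n_folds < 2 or n_folds > len(genes):
        raise ValueError("n_folds must lie in [2, number of genes]")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(genes))
    folds = np.array_split(order, n_folds)
    splits = []
    for i in range(n_folds):
        validation = sorted(genes[j] for j in folds[i])
        seeds = sorted(set(genes) - set(validation))
        splits.append((seeds, validation))
    return splits
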