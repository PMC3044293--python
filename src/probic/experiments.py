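"""Reusable experiment drivers: end-to-end runs on synthetic compendia.

These functions wire the generator, the model, and the evaluation module
into the standard experimental protocols: single-query runs, the implanted-
bicluster recovery benchmark, the null (pure background) control, the
noisy-seed robustness protocol, and per-regulon cross-validation.  The CLI
commands are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from probic.config import RunConfig
from probic.evaluation import (
    BiclusterCategory,
    categorize,
    recall_and_enrichment,
)
from probic.matrix import ExpressionMatrix
from probic.model import BiclusterResult, build_prior, estimate_background, run_em
from probic.synthetic import (
    SimulationConfig,
    cv_split,
    implanted_demo_config,
    make_noisy_seed,
    simulate,
)


def fit_seed_set(
    matrix: ExpressionMatrix, seeds: Sequence[str], cfg: RunConfig | None = None
) -> BiclusterResult:
    """Background estimation, prior construction, and EM for one query."""
    cfg = cfg or RunConfig()
    background = estimate_background(
        matrix, trim_fraction=cfg.trim_fraction, sigma_floor=cfg.sigma_floor
    )
    prior = build_prior(
        matrix,
        seeds,
        background,
        f_bcl=cfg.f_bcl,
        kappa0=cfg.kappa0,
        nu0=cfg.nu0,
        log_penalty=cfg.log_penalty,
        p_gene=cfg.p_gene,
    )
    return run_em(matrix, seeds, background, prior, max_iter=cfg.max_iter, tol=cfg.tol)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 1.0


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class RecoveryRun:
    gene_jaccard: float
    array_jaccard: float
    category: BiclusterCategory


def implant_recovery_runs(
    n_repeats: int = 100,
    n_seeds: int = 5,
    rng_seed: int = 0,
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
) -> list[RecoveryRun]:
    """Recovery benchmark: seed with true members, compare to ground truth.

    Each repeat draws a fresh compendium with one implanted bicluster,
    queries it with ``n_seeds`` randomly chosen true members, and records
    the gene and array Jaccard of the result against the implant.
    """
    rng = np.random.default_rng(rng_seed)
    runs = []
    for _ in range(n_repeats):
        s = _spawn(rng)
        cfg = (
            SimulationConfig.from_dict(sim_config.to_dict())
            if sim_config is not None
            else implanted_demo_config()
        )
        cfg.rng_seed = s
        matrix, truth = simulate(cfg)
        implant = truth.implants[0]
        pick = np.random.default_rng(s + 1).choice(
            len(implant.gene_ids), size=n_seeds, replace=False
        )
        seeds = [implant.gene_ids[i] for i in sorted(pick)]
        result = fit_seed_set(matrix, seeds, run_config)
        runs.append(
            RecoveryRun(
                gene_jaccard=jaccard(result.genes, implant.gene_ids),
                array_jaccard=jaccard(result.arrays, implant.array_ids),
                category=categorize(result.genes, seeds, []),
            )
        )
    return runs


def null_control_runs(
    n_repeats: int = 100,
    n_seeds: int = 5,
    rng_seed: int = 0,
    run_config: RunConfig | None = None,
) -> list[BiclusterCategory]:
    """Null control: random queries against a pure-background compendium.

    A sound model should return an empty bicluster or at most the seed
    genes themselves; recruiting additional genes from pure noise is a
    false-positive outcome.
    """
    rng = np.random.default_rng(rng_seed)
    categories = []
    for _ in range(n_repeats):
        s = _spawn(rng)
        matrix, _ = simulate(SimulationConfig(rng_seed=s))
        pick = np.random.default_rng(s + 1).choice(
            matrix.n_genes, size=n_seeds, replace=False
        )
        seeds = [str(matrix.gene_ids[i]) for i in sorted(pick)]
        result = fit_seed_set(matrix, seeds, run_config)
        categories.append(categorize(result.genes, seeds, []))
    return categories


@dataclass
class NoisySeedRun:
    level: float
    category: BiclusterCategory
    true_retention: float  # fraction of true seeds in the result
    noise_retention: float  # fraction of noise seeds in the result (0 if none)
    n_noise: int


def noisy_seed_runs(
    levels: Sequence[float],
    repeats: int = 100,
    n_true_seeds: int = 5,
    rng_seed: int = 0,
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
) -> list[NoisySeedRun]:
    """Noisy-seed protocol: contaminate the query, measure what survives.

    Each repeat simulates a fresh one-implant compendium, takes
    ``n_true_seeds`` true members as the clean query, adds random genes at
    the level, reruns the model, and records seed retention plus the
    outcome category.  Random genes are drawn from outside the implanted
    bicluster so that a retained noise gene is a genuine false positive.
    """
    rng = np.random.default_rng(rng_seed)
    runs = []
    for level in levels:
        for _ in range(repeats):
            s = _spawn(rng)
            cfg = (
                SimulationConfig.from_dict(sim_config.to_dict())
                if sim_config is not None
                else implanted_demo_config()
            )
            cfg.rng_seed = s
            matrix, truth = simulate(cfg)
            implant = truth.implants[0]
            pick = np.random.default_rng(s + 1).choice(
                len(implant.gene_ids), size=n_true_seeds, replace=False
            )
            true_seeds = [implant.gene_ids[i] for i in sorted(pick)]
            pool = (set(map(str, matrix.gene_ids)) - set(implant.gene_ids)) | set(
                true_seeds
            )
            seeds, noise = make_noisy_seed(true_seeds, pool, level, s + 2)
            result = fit_seed_set(matrix, seeds, run_config)
            got = set(result.genes)
            runs.append(
                NoisySeedRun(
                    level=float(level),
                    category=categorize(result.genes, true_seeds, noise),
                    true_retention=len(got & set(true_seeds)) / len(true_seeds),
                    noise_retention=(
                        len(got & set(noise)) / len(noise) if noise else 0.0
                    ),
                    n_noise=len(noise),
                )
            )
    return runs


def randomized_monotonicity_runs(
    n_runs: int = 50, rng_seed: int = 0
) -> list[float]:
    """Worst relative log-posterior increment per run over randomized inputs.

    Each run draws a random compendium (with or without an implant), a
    random seed set (true members, random genes, or a mix), and random
    hyperparameters, then runs EM and returns the minimum of
    ``(J_{t+1} - J_t) / max(1, |J_t|)`` over the trace -- non-negative (up
    to float noise) when the coordinate ascent is exact.
    """
    from probic.model import build_prior, estimate_background
    from probic.synthetic import ImplantSpec

    rng = np.random.default_rng(rng_seed)
    worst: list[float] = []
    attempts = 0
    while len(worst) < n_runs and attempts < 20 * n_runs:
        attempts += 1
        s = _spawn(rng)
        n_genes = int(rng.integers(40, 120))
        n_arrays = int(rng.integers(10, 30))
        implants = []
        if rng.random() < 0.6:
            implants.append(
                ImplantSpec(
                    n_genes=int(rng.integers(5, max(6, n_genes // 4))),
                    n_arrays=int(rng.integers(3, max(4, n_arrays // 2))),
                    shift=float(rng.uniform(0.0, 3.0)),
                    noise_sigma=float(rng.uniform(0.1, 1.0)),
                )
            )
        sim = SimulationConfig(
            n_genes=n_genes,
            n_arrays=n_arrays,
            biclusters=implants,
            missing_rate=float(rng.choice([0.0, 0.1])),
            rng_seed=s,
        )
        matrix, truth = simulate(sim)
        pool = list(map(str, matrix.gene_ids))
        n_seeds = int(rng.integers(3, 9))
        if implants and rng.random() < 0.7:
            members = truth.implants[0].gene_ids
            take = min(n_seeds, len(members))
            seeds = list(rng.choice(members, size=take, replace=False))
            if take < n_seeds:
                extra = sorted(set(pool) - set(members))
                seeds += list(
                    rng.choice(extra, size=n_seeds - take, replace=False)
                )
        else:
            seeds = list(rng.choice(pool, size=n_seeds, replace=False))
        background = estimate_background(matrix)
        try:
            prior = build_prior(
                matrix,
                sorted(set(seeds)),
                background,
                f_bcl=float(rng.uniform(0.3, 1.0)),
                kappa0=float(10.0 ** rng.uniform(0.0, 4.0)),
                nu0=float(10.0 ** rng.uniform(-0.5, 2.0)),
                log_penalty=float(rng.uniform(0.0, 2.0)),
                p_gene=float(10.0 ** rng.uniform(-3.0, -0.3)),
            )
        except ValueError:
            # all seed values missing on some array: not a runnable query
            continue
        result = run_em(matrix, sorted(set(seeds)), background, prior)
        t = np.asarray(result.log_posterior_trace)
        if t.size < 2:
            worst.append(0.0)
        else:
            worst.append(float(np.min(np.diff(t) / np.maximum(1.0, np.abs(t[:-1])))))
    return worst


def category_counts(
    runs: Iterable[NoisySeedRun],
) -> dict[float, dict[BiclusterCategory, int]]:
    counts: dict[float, dict[BiclusterCategory, int]] = {}
    for run in runs:
        level = counts.setdefault(run.level, {})
        level[run.category] = level.get(run.category, 0) + 1
    return counts


def crossval_regulon(
    matrix: ExpressionMatrix,
    regulon_genes: Sequence[str],
    cfg: RunConfig | None = None,
    n_folds: int = 5,
) -> tuple[float, float]:
    """Mean recall and mean validation-enrichment across CV folds."""
    cfg = cfg or RunConfig()
    splits = cv_split(regulon_genes, n_folds=n_folds, rng_seed=cfg.rng_seed)
    recalls, enrichments = [], []
    for seeds, validation in splits:
        result = fit_seed_set(matrix, seeds, cfg)
        r, e = recall_and_enrichment(result.genes, seeds, validation)
        recalls.append(r)
        enrichments.append(e)
    return float(np.mean(recalls)), float(np.mean(enrichments))
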