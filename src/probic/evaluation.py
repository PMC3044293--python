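"""Bicluster quality statistics, outcome categories, and enrichment tests.

Expression quality of a gene set over a condition set is summarized by two
numbers: STD-within, the spread of member genes around the per-array mean
profile, and STD-across, the uncentered spread of that mean profile over the
selected arrays.  A good constant-column bicluster is tight within (small
STD-within) and strongly displaced across conditions (large STD-across);
their ratio condenses this into one score.

A result is categorized against the true seed genes and any random genes
that were mixed into the query, following the eight mutually exclusive
outcomes used in noisy-seed experiments (empty, seed-only variants, noise
variants, recovery-with-additional variants, drift-away).

Enrichment of the recruited genes against annotation sets uses the one-sided
upper mid-P of the hypergeometric distribution, which counts half the
probability of the observed overlap and thereby undoes the conservativeness
of the discrete tail test.  Seed genes are excluded before testing, so
significance reflects the *additional* genes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

from probic.matrix import ExpressionMatrix


@dataclass
class QualityScores:
    std_within: float
    std_across: float

    @property
    def ratio(self) -> float:
        """STD-across / STD-within; undefined (inf/nan) when within is 0."""
        if self.std_within == 0.0:
            return float("inf") if self.std_across > 0 else float("nan")
        return self.std_across / self.std_within


class BiclusterCategory(str, Enum):
    EMPTY = "empty"
    ONLY_FULL_SEED_SET = "only_full_seed_set"
    ONLY_PART_OF_SEED_SET = "only_part_of_seed_set"
    ONLY_RANDOM_SEED = "only_random_seed"
    RANDOM_SEED_AND_ADDITIONAL = "random_seed_and_additional"
    FULL_SEED_SET_AND_ADDITIONAL = "full_seed_set_and_additional"
    PART_OF_SEED_SET_AND_ADDITIONAL = "part_of_seed_set_and_additional"
    DRIFT_AWAY = "drift_away"


#: Categories in which every true seed gene was retained.
FULL_RECOVERY_CATEGORIES = frozenset(
    {
        BiclusterCategory.ONLY_FULL_SEED_SET,
        BiclusterCategory.FULL_SEED_SET_AND_ADDITIONAL,
    }
)


@dataclass
class EnrichmentResult:
    annotation_id: str
    overlap: int
    midp: float
    significant: bool


def _selected_values(
    matrix: ExpressionMatrix, genes: Iterable[str], arrays: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    gi = matrix.gene_index(list(genes))
    ai = matrix.array_index(list(arrays))
    sub = matrix.values[np.ix_(gi, ai)]
    msk = matrix.mask[np.ix_(gi, ai)]
    return np.where(msk, sub, np.nan), msk


def std_within(
    matrix: ExpressionMatrix, genes: Iterable[str], arrays: Iterable[str]
) -> float:
    """Within-condition spread: sqrt( (1/(G C)) sum_j sum_i (x_ij - xbar_j)^2 ).

    xbar_j is the mean of the selected genes on array j; G and C are the
    selected gene and array counts.  Missing values drop out of both the
    column means and the sum (with G scaled per column accordingly).
    """
    gene_list, array_list = list(genes), list(arrays)
    if len(gene_list) < 2:
        raise ValueError("std_within needs at least 2 genes")
    if len(array_list) < 1:
        raise ValueError("std_within needs at least 1 array")
    sub, msk = _selected_values(matrix, gene_list, array_list)
    counts = msk.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("an array has no present values for the selected genes")
    col_mean = np.nansum(sub, axis=0) / counts
    dev = np.where(msk, (sub - col_mean) ** 2, 0.0)
    return float(np.sqrt(dev.sum() / counts.sum()))


def std_across(
    matrix: ExpressionMatrix, genes: Iterable[str], arrays: Iterable[str]
) -> float:
    """Uncentered spread of the mean profile: sqrt( (1/C) sum_j xbar_j^2 ).

    For a seed set C is all compendium arrays; for a bicluster, the selected
    arrays.  Uncentered (second moment about zero) because displacement from
    the log-ratio origin is the signal of interest.
    """
    gene_list, array_list = list(genes), list(arrays)
    if len(gene_list) < 1:
        raise ValueError("std_across needs at least 1 gene")
    if len(array_list) < 1:
        raise ValueError("std_across needs at least 1 array")
    sub, msk = _selected_values(matrix, gene_list, array_list)
    counts = msk.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("an array has no present values for the selected genes")
    col_mean = np.nansum(sub, axis=0) / counts
    return float(np.sqrt(np.mean(col_mean**2)))


def quality_scores(
    matrix: ExpressionMatrix, genes: Iterable[str], arrays: Iterable[str]
) -> QualityScores:
    gene_list, array_list = list(genes), list(arrays)
    return QualityScores(
        std_within=std_within(matrix, gene_list, array_list),
        std_across=std_across(matrix, gene_list, array_list),
    )


def categorize(
    result_genes: Iterable[str],
    true_seeds: Iterable[str],
    noise_seeds: Iterable[str] = (),
) -> BiclusterCategory:
    """Classify a result against the true seeds and injected noise seeds.

    Exactly one of eight outcomes, evaluated in precedence order: empty
    first; then results with no genes beyond the (true or noise) seeds;
    then results with additional genes, split by whether the full seed set,
    part of it, or only noise seeds survive; a non-empty result containing
    neither true nor noise seeds has drifted away.
    """
    result = set(result_genes)
    true_set = set(true_seeds)
    noise_set = set(noise_seeds)
    if true_set & noise_set:
        raise ValueError("true_seeds and noise_seeds must be disjoint")
    if not result:
        return BiclusterCategory.EMPTY
    kept_true = result & true_set
    kept_noise = result & noise_set
    additional = result - true_set - noise_set
    if not additional:
        if not kept_true:
            return BiclusterCategory.ONLY_RANDOM_SEED
        if kept_true == true_set:
            return BiclusterCategory.ONLY_FULL_SEED_SET
        return BiclusterCategory.ONLY_PART_OF_SEED_SET
    if kept_true == true_set and true_set:
        return BiclusterCategory.FULL_SEED_SET_AND_ADDITIONAL
    if kept_true:
        return BiclusterCategory.PART_OF_SEED_SET_AND_ADDITIONAL
    if kept_noise:
        return BiclusterCategory.RANDOM_SEED_AND_ADDITIONAL
    return BiclusterCategory.DRIFT_AWAY


def hypergeom_midp(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper mid-P: 0.5 P(X = k) + P(X > k), X ~ Hypergeom(N, K, n).

    k is the observed overlap, K the annotation size, n the drawn (bicluster)
    size, N the universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible counts: K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}, N={N}")
    dist = hypergeom(N, K, n)
    return float(0.5 * dist.pmf(k) + dist.sf(k))


def enrich(
    bicluster_genes: Iterable[str],
    seed_genes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Mid-P hypergeometric enrichment of the recruited (non-seed) genes.

    Seed genes are removed from the bicluster, the annotation sets, and the
    universe before testing, so the result measures whether the *additional*
    genes share annotations.  ``significant`` applies the plain ``alpha``
    level per annotation; ``bh_correct=True`` switches to a
    Benjamini-Hochberg threshold across the tested annotations.
    Returns an empty list when nothing is left after seed exclusion.
    """
    seeds = set(seed_genes)
    universe_set = set(universe) - seeds
    tested = set(bicluster_genes) - seeds
    if not tested <= universe_set:
        raise ValueError("bicluster genes missing from the universe")
    if not tested:
        return []
    results = []
    for ann_id, members in annotations.items():
        ann = set(members) - seeds
        if not ann <= universe_set:
            raise ValueError(f"annotation {ann_id!r} not contained in the universe")
        k = len(tested & ann)
        p = hypergeom_midp(k, len(ann), len(tested), len(universe_set))
        results.append(
            EnrichmentResult(
                annotation_id=ann_id, overlap=k, midp=p, significant=p <= alpha
            )
        )
    results.sort(key=lambda r: (r.midp, r.annotation_id))
    if bh_correct and results:
        m = len(results)
        significant_rank = 0
        for i, r in enumerate(results, start=1):
            if r.midp <= alpha * i / m:
                significant_rank = i
        for i, r in enumerate(results, start=1):
            r.significant = i <= significant_rank
    return results


def recall_and_enrichment(
    result_genes: Iterable[str],
    seed_genes: Iterable[str],
    validation_genes: Iterable[str],
) -> tuple[float, float]:
    """Cross-validation read-outs for one fold.

    recall = fraction of validation genes retrieved in the result;
    enrichment = fraction of the result made up of validation genes (0 for
    an empty result).  Seed and validation sets must be disjoint.
    """
    result = set(result_genes)
    seeds = set(seed_genes)
    validation = set(validation_genes)
    if not validation:
        raise ValueError("validation set is empty")
    if seeds & validation:
        raise ValueError("seed and validation sets must be disjoint")
    hits = len(result & validation)
    recall = hits / len(validation)
    enrichment = hits / len(result) if result else 0.0
    return recall, enrichment
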