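"""Mutual-information co-expression inference with a null-calibrated cutoff.

Expression profiles are discretized into equal-frequency bins and pairwise
dependence is measured by the plug-in mutual information

    I(x, y) = S(x) + S(y) - S(x, y)     (entropies in nats),

where S is the plug-in entropy of the binned profile.  Because the target
significance level (p < 1e-15) lies far below the resolution of any
feasible permutation null, the cutoff is obtained by fitting an exponential
right tail to the permutation null of MI,

    ln P(MI >= m) = a + b * m,   b < 0,

and solving for the MI value at the target tail probability.  Co-expression
edges are inferred bipartitely: every seed gene against every other gene in
the expression matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactome import COEXPRESSION, ScoredEdge
from .variants import SeedGeneSet

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """The null-tail fit did not yield a decreasing survival function."""


@dataclass(frozen=True)
class DiscretizedProfile:
    """Equal-frequency bin labels of one gene's expression profile."""

    gene: str
    bins: np.ndarray
    n_bins: int


@dataclass(frozen=True)
class MIEstimate:
    """Plug-in mutual information of one gene pair, with its entropy terms."""

    gene_a: str
    gene_b: str
    mi: float
    entropy_a: float
    entropy_b: float
    joint_entropy: float


@dataclass(frozen=True)
class NullCalibration:
    """Permutation-null summary and fitted exponential tail.

    ``mi_threshold`` is the MI value whose extrapolated tail probability
    equals ``p_target``; ``extrapolated`` records whether ``p_target`` lies
    below the empirical resolution 1 / n_permutations.
    """

    n_permutations: int
    null_mi: np.ndarray
    intercept: float
    slope: float
    p_target: float
    mi_threshold: float
    tail_fraction: float
    rng_seed: int
    extrapolated: bool


def default_n_bins(n_samples: int) -> int:
    """sqrt-rule bin count: floor(sqrt(n)), at least 2 (15 at n = 240)."""
    return max(2, int(math.isqrt(n_samples)))


def discretize(values, n_bins: int, gene: str = "") -> DiscretizedProfile:
    """Equal-frequency (quantile) binning on ranks.

    Ties are broken by stable original sample order; with no ties the bin
    occupancies differ by at most one.  A constant vector collapses to a
    single occupied bin (zero entropy) with a warning.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = v.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {n}")
    if np.all(v == v[0]):
        logger.warning("constant profile %r: single bin, zero entropy", gene)
        return DiscretizedProfile(gene, np.zeros(n, dtype=np.int64), n_bins)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    bins = (ranks * n_bins) // n
    return DiscretizedProfile(gene, bins, n_bins)


def _entropy_from_counts(counts: np.ndarray) -> float:
    # summing in sorted-count order makes the float result canonical, so
    # mi(a, b) == mi(b, a) holds bitwise (transposed tables share counts)
    p = np.sort(counts[counts > 0]) / counts.sum()
    return float(-(p * np.log(p)).sum())


def entropy(profile: DiscretizedProfile) -> float:
    """Plug-in entropy -sum p ln p over occupied bins, in nats."""
    return _entropy_from_counts(np.bincount(profile.bins, minlength=profile.n_bins))


def mutual_information(a: DiscretizedProfile, b: DiscretizedProfile) -> MIEstimate:
    """MI from the 2-D bin contingency table; symmetric, clamped at zero."""
    if a.bins.size != b.bins.size:
        raise ValueError(
            f"profile length mismatch: {a.bins.size} vs {b.bins.size}"
        )
    joint = np.bincount(a.bins * b.n_bins + b.bins, minlength=a.n_bins * b.n_bins)
    joint = joint.reshape(a.n_bins, b.n_bins)
    s_a = _entropy_from_counts(joint.sum(axis=1))
    s_b = _entropy_from_counts(joint.sum(axis=0))
    s_ab = _entropy_from_counts(joint.ravel())
    mi = s_a + s_b - s_ab
    if mi < 0:
        mi = 0.0
    return MIEstimate(a.gene, b.gene, mi, s_a, s_b, s_ab)


def fit_survival_tail(
    null_values: np.ndarray, tail_fraction: float
) -> tuple[float, float]:
    """Least-squares fit of ln P(MI >= m) = a + b*m over the top tail.

    The empirical survival at the i-th largest of n values is taken as i/n.
    Returns (a, b); raises :class:`CalibrationError` if b >= 0.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    values = np.sort(np.asarray(null_values, dtype=float))[::-1]
    n = values.size
    k = max(3, int(round(tail_fraction * n)))
    m = values[:k]
    if np.ptp(m) == 0:
        raise CalibrationError(
            "degenerate null: the upper tail is constant; increase "
            "n_permutations or tail_fraction"
        )
    log_surv = np.log(np.arange(1, k + 1) / n)
    slope, intercept = np.polyfit(m, log_surv, 1)
    if slope >= 0:
        raise CalibrationError(
            "fitted survival slope is non-negative; increase n_permutations "
            "or tail_fraction"
        )
    return float(intercept), float(slope)


def threshold_from_null(
    null_values: np.ndarray, p_target: float, tail_fraction: float
) -> tuple[float, float, float]:
    """Fit the exponential tail and solve for the MI cutoff at p_target."""
    if not 0 < p_target < 1:
        raise ValueError("p_target must be in (0, 1)")
    intercept, slope = fit_survival_tail(null_values, tail_fraction)
    threshold = (math.log(p_target) - intercept) / slope
    return intercept, slope, threshold


def calibrate_null(
    expr: pd.DataFrame,
    n_bins: int | None = None,
    n_permutations: int = 100_000,
    p_target: float = 1e-15,
    tail_fraction: float = 0.1,
    rng_seed: int = 0,
) -> NullCalibration:
    """Build the permutation null of MI and calibrate the significance cutoff.

    Each null draw pairs two distinct, randomly chosen genes and permutes
    one profile independently, destroying any dependence while keeping the
    marginal bin occupancies.  The cutoff at ``p_target`` comes from the
    fitted exponential tail; extrapolation below the empirical resolution
    1/n_permutations is explicit and logged.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least two genes to calibrate")
    n_samples = expr.shape[1]
    if n_bins is None:
        n_bins = default_n_bins(n_samples)
    rng = np.random.default_rng(rng_seed)
    labels = np.stack(
        [discretize(expr.iloc[i].to_numpy(), n_bins).bins for i in range(expr.shape[0])]
    )
    n_genes = labels.shape[0]
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        i, j = rng.choice(n_genes, size=2, replace=False)
        perm = rng.permutation(labels[j])
        joint = np.bincount(labels[i] * n_bins + perm, minlength=n_bins * n_bins)
        s_a = _entropy_from_counts(np.bincount(labels[i], minlength=n_bins))
        s_b = _entropy_from_counts(np.bincount(perm, minlength=n_bins))
        null[t] = max(0.0, s_a + s_b - _entropy_from_counts(joint))
    intercept, slope, threshold = threshold_from_null(null, p_target, tail_fraction)
    extrapolated = p_target < 1.0 / n_permutations
    if extrapolated:
        logger.info(
            "p_target %.3g below permutation resolution %.3g: threshold %.4f "
            "obtained by exponential-tail extrapolation",
            p_target,
            1.0 / n_permutations,
            threshold,
        )
    return NullCalibration(
        n_permutations=n_permutations,
        null_mi=np.sort(null),
        intercept=intercept,
        slope=slope,
        p_target=p_target,
        mi_threshold=threshold,
        tail_fraction=tail_fraction,
        rng_seed=rng_seed,
        extrapolated=extrapolated,
    )


def infer_coexpression(
    expr: pd.DataFrame,
    seeds: SeedGeneSet,
    calib: NullCalibration,
    n_bins: int | None = None,
) -> list[ScoredEdge]:
    """Emit co-expression edges between seeds and all other expressed genes.

    Only (seed, other) pairs are tested — the inference is bipartite.  An
    edge is emitted when MI exceeds the calibrated threshold; its score is
    1 - exp(-MI), a monotone rescaling of MI into (0, 1].
    """
    if n_bins is None:
        n_bins = default_n_bins(expr.shape[1])
    present = [g for g in sorted(seeds.genes) if g in expr.index]
    missing = sorted(seeds.genes - set(present))
    if missing:
        logger.warning("seeds absent from expression matrix, skipped: %s", missing)
    if not present:
        raise ValueError("no seed gene is present in the expression matrix")
    profiles = {
        g: discretize(expr.loc[g].to_numpy(), n_bins, gene=g) for g in expr.index
    }
    edges: list[ScoredEdge] = []
    tested: set[tuple[str, str]] = set()
    for seed in present:
        for other in expr.index:
            if other == seed:
                continue
            pair = (seed, other) if seed < other else (other, seed)
            if pair in tested:
                continue
            tested.add(pair)
            est = mutual_information(profiles[seed], profiles[other])
            if est.mi > calib.mi_threshold:
                edges.append(
                    ScoredEdge(
                        seed,
                        other,
                        score=1.0 - math.exp(-est.mi),
                        source="coexpression",
                        kind=COEXPRESSION,
                    )
                )
    return edges
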