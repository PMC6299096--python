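"""Correlation and fate-concordance statistics on related-cell pairs.

Sister and cousin pairs are unordered, so the Pearson correlation is
computed on the *symmetrized* pair set — each pair contributes both
orderings — which makes the estimate invariant to how pairs were listed.
Inference (t-test p-value, Fisher-z confidence interval) uses the number
of unordered pairs as the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lineage import Fate, LineageForest, PairObservation, Relation, extract_pairs

__all__ = [
    "CorrelationEstimate",
    "ConcordanceResult",
    "symmetrized_pairs",
    "pearson_with_inference",
    "fate_concordance",
    "randomization_null",
    "distance_stratified_concordance",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationEstimate:
    rho: float
    n_pairs: int
    p_value: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class ConcordanceResult:
    fraction_same_fate: float
    expected_independent: float
    chi2_stat: float
    chi2_p: float
    n_pairs: int


def symmetrized_pairs(pairs) -> list[tuple[float, float]]:
    """Emit each unordered pair (a, b) as both (a, b) and (b, a)."""
    out = []
    for p in pairs:
        t1, t2 = (p.t1, p.t2) if isinstance(p, PairObservation) else (p[0], p[1])
        out.append((t1, t2))
        out.append((t2, t1))
    return out


def pearson_with_inference(pairs, symmetrize: bool = True) -> CorrelationEstimate:
    """Pearson r with t-test p-value and 95% Fisher-z confidence interval.

    With ``symmetrize`` (the default for unordered relations) r is computed
    on the doubled set; n for inference remains the unordered pair count.
    """
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    data = symmetrized_pairs(pairs) if symmetrize else [
        (p.t1, p.t2) if isinstance(p, PairObservation) else (p[0], p[1]) for p in pairs
    ]
    x = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    if np.std(x) < 1e-14 or np.std(y) < 1e-14:
        raise InsufficientDataError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    if n >= 4 and abs(r) < 1.0:
        zr = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (-1.0, 1.0)
    return CorrelationEstimate(rho=r, n_pairs=n, p_value=p, ci95=ci)


def _died(f: Fate) -> bool:
    return f is Fate.DIED


def fate_concordance(pairs) -> ConcordanceResult:
    """Fraction of pairs sharing a fate vs the independence expectation.

    Fate is binarized as died vs survived-to-horizon (divided or censored).
    The independence expectation is ``p^2 + (1-p)^2`` with p the marginal
    death fraction among pair members; the chi-square test (1 df) compares
    observed concordant/discordant counts to that expectation.
    """
    n = len(pairs)
    if n == 0:
        raise InsufficientDataError("no pairs")
    same = sum(1 for p in pairs if _died(p.e1) == _died(p.e2))
    deaths = sum(_died(p.e1) + _died(p.e2) for p in pairs)
    p_die = deaths / (2.0 * n)
    expected = p_die**2 + (1.0 - p_die) ** 2
    obs = np.array([same, n - same], dtype=float)
    exp = np.array([expected * n, (1.0 - expected) * n])
    if exp.min() <= 0:
        chi2, pval = 0.0, 1.0
    else:
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        pval = float(stats.chi2.sf(chi2, df=1))
    return ConcordanceResult(
        fraction_same_fate=same / n,
        expected_independent=expected,
        chi2_stat=chi2,
        chi2_p=pval,
        n_pairs=n,
    )


def randomization_null(values1, values2, statistic, n_perm: int = 10_000, seed: int = 0):
    """Permutation null for a pair statistic by random re-pairing.

    Re-pairs the two member lists at random ``n_perm`` times, evaluates
    ``statistic(x, y)`` on each random pairing, and returns
    ``(null_values, two_sided_p)`` with the add-one empirical p-value
    ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise InsufficientDataError("need two equal-length lists of pair members")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = float(statistic(x, y))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(x, rng.permutation(y))
    p = (1.0 + int(np.sum(np.abs(null) >= abs(obs)))) / (n_perm + 1.0)
    return null, float(p)


def distance_stratified_concordance(forest: LineageForest, bin_edges_um):
    """Spatial controls for fate concordance.

    Returns ``(per_bin, mean_distances)`` where ``per_bin`` maps each
    distance bin (lo, hi) to the ConcordanceResult of *unrelated* pairs
    whose centroid separation falls in it, and ``mean_distances`` maps each
    relation class to (mean, sd, n) of pair separations.  Raises if the
    forest carries no positions.
    """
    if not any(c.position is not None for c in forest.cells.values()):
        raise InsufficientDataError("forest has no cell positions")

    def dist(p: PairObservation) -> float | None:
        a = forest.cells[p.id1].position
        b = forest.cells[p.id2].position
        if a is None or b is None:
            return None
        return float(np.hypot(a[0] - b[0], a[1] - b[1]))

    mean_distances = {}
    for rel in [Relation.SISTER, Relation.COUSIN, Relation.SECOND_COUSIN,
                Relation.THIRD_COUSIN, Relation.UNRELATED]:
        ds = [d for d in (dist(p) for p in extract_pairs(forest, rel)) if d is not None]
        if ds:
            mean_distances[rel] = (float(np.mean(ds)), float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0, len(ds))

    unrelated = extract_pairs(forest, Relation.UNRELATED)
    edges = list(bin_edges_um)
    per_bin = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [p for p in unrelated
               if (d := dist(p)) is not None and lo <= d < hi]
        if sel:
            per_bin[(lo, hi)] = fate_concordance(sel)
    return per_bin, mean_distances
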