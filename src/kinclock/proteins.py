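"""Protein production/degradation models of division control.

The alternative, non-oscillatory mechanism: a protein X (or the ratio of
two proteins X/Y) is produced at constant rate ``k_prod`` and degraded at
first-order rate ``k_deg`` inside every cell.  At division both daughters
inherit the mother's terminal level, and the inherited level sets the
location of the daughters' division clock — a higher inherited level means
a longer expected inter-mitotic time.  Whether a protein retains memory of
its level across one lifetime is governed by the dimensionless parameter
``k_deg * lifetime``: >> 1 is the *mixing* regime (memory lost), << 1
*non-mixing* (memory retained).

The birth-death chemistry is an immigration-death Markov jump process whose
transition law is known in closed form:

    X(t) | X(0)=x0  ~  Binomial(x0, e^(-k_deg t)) + Poisson(m (1 - e^(-k_deg t)))

with stationary distribution Poisson(m), m = k_prod / k_deg.  The lineage
simulator samples terminal levels from this exact law; ``gillespie_trajectory``
provides the full event-resolved path for trajectory-level statistics, and
the two routes are cross-checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .emg import EMGParams
from .lineage import CellRecord, Fate, LineageForest, Relation
from .simulator import (
    MetricSpec,
    DEFAULT_METRICS,
    PRE_IMT_LATENT,
    RunawayPopulationError,
    _latent_times,
)

__all__ = [
    "ProteinModelSpec",
    "gillespie_trajectory",
    "transition_sample",
    "autocorrelation_regime",
    "simulate_protein_forest",
    "protein_replicates",
    "calibrate_slope",
    "falsification_experiment",
    "MIXING_SPEC",
    "NONMIXING_SPEC",
]


@dataclass(frozen=True)
class ProteinModelSpec:
    """One- or two-protein inheritance model.

    ``slope`` maps the standardized inherited level (or standardized
    log-ratio for two proteins) to the division-clock location:
    ``mu_div = base.mu + slope * w``; monotone increasing, so more protein
    means slower division.
    """

    k_prod: float
    k_deg: float
    base: EMGParams
    slope: float = 0.0
    n_proteins: int = 1
    x0: float | None = None  # founder level; default stationary mean

    def __post_init__(self) -> None:
        if self.k_prod < 0 or self.k_deg < 0:
            raise ValueError("rates must be >= 0")
        if self.n_proteins not in (1, 2):
            raise ValueError("n_proteins must be 1 or 2")
        if self.slope < 0:
            raise ValueError("slope must be >= 0 (level increases IMT)")

    @property
    def stationary_mean(self) -> float:
        if self.k_deg == 0:
            raise ValueError("no stationary state with k_deg = 0")
        return self.k_prod / self.k_deg


def gillespie_trajectory(k_prod: float, k_deg: float, x0: int, duration: float,
                         rng) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic simulation of births (k_prod) and deaths (k_deg*x).

    Returns event times (starting at 0) and the piecewise-constant molecule
    counts after each event.
    """
    rng = np.random.default_rng(rng)
    t, x = 0.0, int(x0)
    times, counts = [0.0], [x]
    while True:
        a_tot = k_prod + k_deg * x
        if a_tot <= 0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t > duration:
            break
        if rng.uniform() * a_tot < k_prod:
            x += 1
        else:
            x -= 1
        times.append(t)
        counts.append(x)
    return np.asarray(times), np.asarray(counts)


def transition_sample(x0, k_prod: float, k_deg: float, dt, rng) -> np.ndarray:
    """Exact endpoint draw X(dt) | X(0)=x0 of the immigration-death process.

    Surviving initial molecules are Binomial(x0, e^(-k_deg dt)); newly made
    ones Poisson(m (1 - e^(-k_deg dt))).  Statistically identical to running
    the event-resolved simulation and reading the endpoint.
    """
    rng = np.random.default_rng(rng)
    x0 = np.asarray(x0, dtype=np.int64)
    dt = np.asarray(dt, dtype=float)
    if k_deg == 0:
        return x0 + rng.poisson(k_prod * dt, size=x0.shape)
    p = np.exp(-k_deg * dt)
    m = k_prod / k_deg
    return rng.binomial(x0, np.broadcast_to(p, x0.shape)) + rng.poisson(
        np.broadcast_to(m * (1.0 - p), x0.shape)
    )


def autocorrelation_regime(spec: ProteinModelSpec, lifetime: float,
                           n_mc: int = 4000, seed: int = 0):
    """Monte-Carlo corr(X(0), X(lifetime)) at stationarity, plus the label.

    Theory for the immigration-death process gives exp(-k_deg * lifetime);
    the empirical value classifies the protein as MIXING (< 0.2),
    NON_MIXING (> 0.8) or INTERMEDIATE.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.poisson(spec.stationary_mean, size=n_mc)
    xt = transition_sample(x0, spec.k_prod, spec.k_deg, lifetime, rng)
    r = float(np.corrcoef(x0, xt)[0, 1])
    label = "MIXING" if r < 0.2 else ("NON_MIXING" if r > 0.8 else "INTERMEDIATE")
    return r, label


#: floor of the division-clock location, hours.  A cell cycle has a
#: physiological minimum duration; without the floor a persistently
#: low-protein lineage in the non-mixing regime acquires a near-zero
#: division time and the population runs away.  The slow-division side of
#: the mapping is left open.
_MU_FLOOR_H = 4.0


def _standardized_level(x, spec: ProteinModelSpec, y=None):
    """Inherited-level covariate w: standardized count (or log-ratio)."""
    m = spec.stationary_mean
    if spec.n_proteins == 1:
        return (np.asarray(x, float) - m) / np.sqrt(m)
    lx = np.log(np.maximum(np.asarray(x, float), 0.5))
    ly = np.log(np.maximum(np.asarray(y, float), 0.5))
    return (lx - ly) / np.sqrt(2.0 / m)


def simulate_protein_forest(spec: ProteinModelSpec, n_founders: int,
                            t_total: float, seed: int = 0,
                            founder_birth_spread: float = 0.0,
                            cap: int = 100_000) -> LineageForest:
    """Branching population where inherited protein level gates division.

    Founders start at a stationary draw; each cell's division clock has
    location ``base.mu + slope * w(inherited level)``, the cell's protein
    evolves over its lifetime by the exact transition law, and both
    daughters inherit the terminal level identically.  No death channel
    (the regime these models address is drug-free growth).
    """
    rng = np.random.default_rng(seed)
    n0 = n_founders
    ids = [f"f{i}" for i in range(n0)]
    mothers: list[str | None] = [None] * n0
    births = (
        np.sort(rng.uniform(0.0, founder_birth_spread, n0))
        if founder_birth_spread > 0
        else np.zeros(n0)
    )
    if spec.x0 is not None:
        x = np.full(n0, int(spec.x0), dtype=np.int64)
    else:
        x = rng.poisson(spec.stationary_mean, size=n0).astype(np.int64)
    y = rng.poisson(spec.stationary_mean, size=n0).astype(np.int64) if spec.n_proteins == 2 else None

    cells: dict[str, CellRecord] = {}
    total = 0
    while ids:
        n = len(ids)
        total += n
        if total > cap:
            raise RunawayPopulationError(f"population exceeded cap of {cap}")
        w = _standardized_level(x, spec, y)
        mu = np.maximum(spec.base.mu + spec.slope * w, _MU_FLOOR_H)
        u = rng.uniform(size=n)
        lifetimes = _latent_times(u, spec.base, mu)
        end = births + lifetimes
        censored = end > t_total
        end = np.where(censored, t_total, end)
        dt = end - births
        # protein level at the end of each cell's life (exact transition law)
        xe = transition_sample(x, spec.k_prod, spec.k_deg, dt, rng)
        ye = transition_sample(y, spec.k_prod, spec.k_deg, dt, rng) if y is not None else None

        new_ids, new_mothers, nb, nx, ny = [], [], [], [], []
        for i in range(n):
            f = Fate.CENSORED if censored[i] else Fate.DIVIDED
            cells[ids[i]] = CellRecord(ids[i], mothers[i], float(births[i]),
                                       float(end[i]), f)
            if not censored[i]:
                for tag in "ab":
                    new_ids.append(ids[i] + tag)
                    new_mothers.append(ids[i])
                    nb.append(end[i])
                    nx.append(xe[i])
                    if ye is not None:
                        ny.append(ye[i])
        if not new_ids:
            break
        ids, mothers = new_ids, new_mothers
        births = np.array(nb)
        x = np.array(nx, dtype=np.int64)
        y = np.array(ny, dtype=np.int64) if ye is not None else None

    forest = LineageForest(cells=cells, T_d=None, T_end=t_total)
    return forest.with_generations()


def protein_replicates(spec: ProteinModelSpec, n_runs: int, n_founders: int = 24,
                       t_total: float = 50.0, seed: int = 0,
                       metrics=DEFAULT_METRICS):
    """Per-run lineage correlations for a protein model (IMT channel)."""
    rows = []
    for i in range(n_runs):
        forest = simulate_protein_forest(spec, n_founders, t_total,
                                         seed=seed + i,
                                         founder_birth_spread=16.0)
        rows.append({"run": i} | {m.name: m.compute(forest) for m in metrics})
    per_run = pd.DataFrame(rows).set_index("run")
    return per_run, per_run.quantile([0.25, 0.5, 0.75])


def calibrate_slope(spec: ProteinModelSpec, target_r: float = 0.73,
                    n_runs: int = 8, seed: int = 0,
                    slope_grid=(2.0, 3.0, 4.0, 5.0, 5.5, 6.0, 6.5, 7.0, 8.0),
                    tol: float = 0.05):
    """Set the level->IMT slope so sisters correlate near ``target_r``.

    Shared inheritance makes the sister correlation roughly
    slope^2 / (slope^2 + var_base), but growth selection (fast lineages
    contribute disproportionately many pairs) erodes the between-lineage
    variance at large slopes, so r is not monotone in the slope.  The
    calibration therefore evaluates a bounded grid and keeps the slope
    whose median sister correlation over ``n_runs`` runs is closest to the
    target; success means within ``tol``.
    """
    metric = MetricSpec("sister_imt", Relation.SISTER, Fate.DIVIDED)
    best_s, best_r = None, np.nan
    for s in slope_grid:
        cand = replace(spec, slope=float(s))
        per_run, _ = protein_replicates(cand, n_runs, seed=seed, metrics=(metric,))
        r = float(per_run["sister_imt"].median())
        if best_s is None or abs(r - target_r) < abs(best_r - target_r):
            best_s, best_r = s, r
    return replace(spec, slope=float(best_s)), best_r, abs(best_r - target_r) <= tol


#: mixing regime: memory parameter k_deg * lifetime ~ 8 over a 16 h lifetime
MIXING_SPEC = ProteinModelSpec(k_prod=25.0, k_deg=0.5, base=PRE_IMT_LATENT)
#: non-mixing regime: k_deg * lifetime ~ 0.16, memory ~ 0.85
NONMIXING_SPEC = ProteinModelSpec(k_prod=0.5, k_deg=0.01, base=PRE_IMT_LATENT)


def falsification_experiment(regimes=None, n_runs: int = 30, seed: int = 0,
                             target_r: float = 0.73, n_proteins: int = 1):
    """Can inherited-protein models produce the cousin-mother inequality?

    Each regime is calibrated so the median sister IMT correlation matches
    the observed value, then ``n_runs`` replicate forests are summarized.
    Returns a DataFrame with per-regime medians and the flag
    ``inequality``: whether the median cousin r exceeds the median
    mother-daughter r by more than a 0.1 noise margin (the observed data
    shows an excess of ~0.37; both medians hover near zero in the mixing
    regime, so a margin-free comparison would flag sampling noise).
    """
    if regimes is None:
        regimes = {
            "mixing": replace(MIXING_SPEC, base=PRE_IMT_LATENT,
                              n_proteins=n_proteins),
            "non_mixing": replace(NONMIXING_SPEC, base=PRE_IMT_LATENT,
                                  n_proteins=n_proteins),
        }
    rows = []
    for name, spec in regimes.items():
        cal, r_cal, ok = calibrate_slope(spec, target_r=target_r, seed=seed)
        per_run, q = protein_replicates(cal, n_runs, seed=seed + 1000)
        med = q.loc[0.5]
        rows.append(
            {
                "regime": name,
                "memory": float(np.exp(-spec.k_deg * spec.base.mean)),
                "slope": cal.slope,
                "calibrated": ok,
                "sister_r": med["sister_imt"],
                "md_r": med["md_imt"],
                "cousin_r": med["cousin_imt"],
                "inequality": bool(med["cousin_imt"] > med["md_imt"] + 0.1),
            }
        )
    return pd.DataFrame(rows)
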