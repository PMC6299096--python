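"""Figure-level experiment drivers: data analysis, inference, simulations.

Each function reproduces one analysis of the two-epoch lineage-tracking
study end to end: descriptive lineage correlations and fate concordance,
copula competing-risks inference of the hidden fate-time distributions,
the birth-death validation loop, the no-gating null, and the circadian
gating suite (24 h gating, period scan, gate combinations, phase-offset
scan).  All entry points are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .emg import EMGParams, emg_fit_mle, shrink_to_sd
from .inference import (
    CompetingRisksModel,
    FitResult,
    fit_model,
    inferred_underlying,
)
from .lineage import (
    Epoch,
    Fate,
    LineageForest,
    PairObservation,
    Relation,
    epoch_of,
    extract_pairs,
)
from .pairstats import (
    InsufficientDataError,
    distance_stratified_concordance,
    fate_concordance,
    pearson_with_inference,
)
from .simulator import (
    AT_METRICS,
    DEFAULT_METRICS,
    DRUG_DELAY_H,
    DRUG_TIME_H,
    POST_AT_LATENT,
    POST_IMT_LATENT,
    POST_WINDOW_H,
    PRE_IMT_LATENT,
    ClockSpec,
    EpochModel,
    MetricSpec,
    SimulationSpec,
    calibrate_amplitude,
    period_scan,
    phase_offset_scan,
    run_replicates,
    simulate_forest,
)

__all__ = [
    "sister_pairset",
    "fit_epoch",
    "profile_delay",
    "run_data_analysis",
    "run_bias_demo",
    "run_null_model",
    "pre_gating_spec",
    "post_gating_spec",
    "run_gating_suite",
]


# --- epoch datasets for the likelihood ------------------------------------


def sister_pairset(forest: LineageForest, epoch: str, delay: float = 0.0,
                   censor_horizon: float | None = None):
    """Sister pairs + singletons of one drug epoch, ready for fitting.

    ``epoch`` is "pre" or "post"; the effective boundary is
    ``T_d + delay``.  Pre-epoch cells whose fate falls after the boundary
    are right-censored at the boundary for the pre fit.  Post-epoch cells
    are all cells whose fate (or censoring) falls after the boundary, with
    lifetimes measured from birth; cells alive at the horizon
    ``min(T_end, T_d + 72 h)`` are censored there.  A cell whose sister is
    not part of the same epoch contributes a univariate singleton term.
    """
    if forest.T_d is None:
        raise ValueError("forest has no drug-administration time")
    switch = forest.T_d + delay
    horizon = forest.T_end
    if censor_horizon is not None:
        horizon = min(horizon, censor_horizon)

    def member(c):
        """(lifetime, fate, entry_age) of a cell in the epoch, or None.

        Entry ages encode delayed entry: a founder already alive when
        imaging starts enters the pre epoch at age -birth_time; a cell
        born before the boundary whose fate falls after it enters the
        post epoch at its age at the boundary.
        """
        if epoch == "pre":
            if c.birth_time >= switch:
                return None
            entry = max(0.0, -c.birth_time) if c.mother_id is None else 0.0
            if c.end_time <= switch:
                if c.fate is Fate.CENSORED:  # censored before the boundary
                    return (c.lifetime, Fate.CENSORED, entry)
                return (c.lifetime, c.fate, entry)
            return (switch - c.birth_time, Fate.CENSORED, entry)
        if epoch == "post":
            if c.end_time <= switch:
                return None
            entry = max(0.0, switch - c.birth_time)
            if c.fate is Fate.CENSORED or c.end_time > horizon:
                return (min(c.end_time, horizon) - c.birth_time, Fate.CENSORED, entry)
            return (c.lifetime, c.fate, entry)
        raise ValueError(f"unknown epoch {epoch!r}")

    done: set[str] = set()
    pairs: list[PairObservation] = []
    singles: list[tuple[float, Fate]] = []
    for cid in sorted(forest.cells):
        if cid in done:
            continue
        c = forest.cells[cid]
        m = member(c)
        if m is None:
            done.add(cid)
            continue
        sister = None
        if c.mother_id is not None:
            sibs = [s for s in forest.daughters(c.mother_id) if s != cid]
            if sibs:
                sister = sibs[0]
        if sister is not None and sister not in done:
            sm = member(forest.cells[sister])
            if sm is not None:
                pairs.append(PairObservation(m[0], sm[0], m[1], sm[1],
                                             Relation.SISTER, None, cid, sister,
                                             entry1=m[2], entry2=sm[2]))
                done.update((cid, sister))
                continue
        singles.append(m)
        done.add(cid)
    return pairs, singles


def fit_epoch(
    forest: LineageForest,
    epoch: str,
    delay: float = 0.0,
    with_death: bool | None = None,
    init: CompetingRisksModel | None = None,
    fixed_params: dict | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Copula competing-risks fit of one epoch of a lineage forest.

    ``with_death`` defaults to False for the pre epoch (negligible death
    before the drug) and True for the post epoch.  The censor horizon is
    ``min(T_end, T_d + 72 h)``.
    """
    if with_death is None:
        with_death = epoch == "post"
    horizon = forest.T_d + POST_WINDOW_H if epoch == "post" else None
    pairs, singles = sister_pairset(forest, epoch, delay=delay,
                                    censor_horizon=horizon)
    if init is None:
        tdiv = np.array(
            [t for pp in pairs for t, e in ((pp.t1, pp.e1), (pp.t2, pp.e2))
             if e is Fate.DIVIDED]
            + [s[0] for s in singles if s[1] is Fate.DIVIDED]
        )
        mean0 = float(np.mean(tdiv)) if tdiv.size else 20.0
        sd0 = float(np.std(tdiv, ddof=1)) if tdiv.size > 2 else 5.0
        theta_div = EMGParams.from_moments(max(mean0, 2.0), max(sd0, 0.5), 0.5)
        theta_die = None
        if with_death:
            obs_die = [
                t for pp in pairs for t, e in ((pp.t1, pp.e1), (pp.t2, pp.e2))
                if e is Fate.DIED
            ] + [s[0] for s in singles if s[1] is Fate.DIED]
            tdie = np.array(obs_die)
            mean1 = float(np.mean(tdie)) if tdie.size else 24.0
            sd1 = float(np.std(tdie, ddof=1)) if tdie.size > 2 else 8.0
            theta_die = EMGParams.from_moments(max(mean1, 2.0), max(sd1, 0.5), 0.5)
        init = CompetingRisksModel(theta_div=theta_div, theta_die=theta_die,
                                   z=0.4, delay=delay, censor_horizon=horizon)
    return fit_model(pairs, singles, init=init, fixed_params=fixed_params,
                     n_restarts=n_restarts, seed=seed)


def profile_delay(forest: LineageForest, delays=None, epoch: str = "post",
                  seed: int = 0, n_restarts: int = 2):
    """Profile the drug-effect delay over a grid (default 0-12 h, 1 h step).

    Returns ``(best_fit, table)`` where the table lists the maximized
    log-likelihood per candidate delay.
    """
    if delays is None:
        delays = np.arange(0.0, 13.0, 1.0)
    rows, best = [], None
    for d in delays:
        fit = fit_epoch(forest, epoch, delay=float(d), seed=seed,
                        n_restarts=n_restarts)
        rows.append({"delay": float(d), "loglik": fit.loglik,
                     "converged": fit.converged})
        if best is None or fit.loglik > best[1].loglik:
            best = (float(d), fit)
    return best[1], pd.DataFrame(rows)


# --- descriptive statistics (lineage correlations, concordance) ------------


def _corr(pairs, symmetrize=True):
    try:
        e = pearson_with_inference(pairs, symmetrize=symmetrize)
        return {"rho": e.rho, "n_pairs": e.n_pairs, "p_value": e.p_value,
                "ci95": list(e.ci95)}
    except InsufficientDataError:
        return {"rho": None, "n_pairs": len(pairs), "p_value": None,
                "ci95": None}


def run_data_analysis(forest: LineageForest, distance_bins=None) -> dict:
    """All descriptive statistics of a two-epoch lineage experiment.

    Pre-drug IMT correlations (sister / mother-daughter / cousin), death
    time correlations (sister / cousin, all dying cells), event counts and
    moments of the three observed distributions (pre IMT, straddle IMT,
    death times), sister fate concordance among drug-exposed pairs, and —
    when positions are available — the distance-stratified concordance
    controls.
    """
    T_d = forest.T_d
    out: dict = {"n_cells": len(forest)}

    pre_sister = extract_pairs(forest, Relation.SISTER, Epoch.PRE, Fate.DIVIDED)
    pre_md = extract_pairs(forest, Relation.MOTHER_DAUGHTER, Epoch.PRE, Fate.DIVIDED)
    pre_cousin = extract_pairs(forest, Relation.COUSIN, Epoch.PRE, Fate.DIVIDED)
    at_sister = extract_pairs(forest, Relation.SISTER, None, Fate.DIED)
    at_cousin = extract_pairs(forest, Relation.COUSIN, None, Fate.DIED)
    out["correlations"] = {
        "pre_imt_sister": _corr(pre_sister),
        "pre_imt_mother_daughter": _corr(pre_md, symmetrize=False),
        "pre_imt_cousin": _corr(pre_cousin),
        "at_sister": _corr(at_sister),
        "at_cousin": _corr(at_cousin),
    }

    def stats_of(values):
        v = np.asarray(values)
        if v.size == 0:
            return {"n": 0, "mean": None, "sd": None}
        return {"n": int(v.size), "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else None}

    cells = forest.cells.values()
    pre_imt = [c.lifetime for c in cells
               if c.fate is Fate.DIVIDED and epoch_of(c, T_d) is Epoch.PRE]
    straddle_imt = [c.lifetime for c in cells
                    if c.fate is Fate.DIVIDED and epoch_of(c, T_d) is Epoch.STRADDLE]
    at_times = [c.lifetime for c in cells if c.fate is Fate.DIED]
    out["distributions"] = {
        "pre_imt": stats_of(pre_imt),
        "straddle_imt": stats_of(straddle_imt),
        "at": stats_of(at_times),
    }

    # sister fate concordance among pairs exposed to the drug
    exposed = [p for p in extract_pairs(forest, Relation.SISTER)
               if forest.cells[p.id1].end_time > T_d
               and forest.cells[p.id2].end_time > T_d]
    if exposed:
        cc = fate_concordance(exposed)
        out["fate_concordance"] = {
            "fraction_same_fate": cc.fraction_same_fate,
            "expected_independent": cc.expected_independent,
            "chi2_stat": cc.chi2_stat,
            "chi2_p": cc.chi2_p,
            "n_pairs": cc.n_pairs,
        }

    if any(c.position is not None for c in cells):
        bins = distance_bins if distance_bins is not None else [0, 50, 100, 200, 400, 1e9]
        per_bin, mean_d = distance_stratified_concordance(forest, bins)
        out["distance"] = {
            "per_bin": {f"{lo:g}-{hi:g}": {
                "fraction_same_fate": r.fraction_same_fate,
                "n_pairs": r.n_pairs,
            } for (lo, hi), r in per_bin.items()},
            "mean_by_relation": {rel.value: {"mean": m, "sd": s, "n": n}
                                 for rel, (m, s, n) in mean_d.items()},
        }
    return out


# --- Fig.3-style validation loop ------------------------------------------


def run_bias_demo(
    latent_div: EMGParams,
    latent_die: EMGParams,
    data_forest: LineageForest,
    seed: int = 0,
    n_founders: int = 300,
    alpha: float = 0.01,
) -> dict:
    """Birth-death validation of inferred latent distributions.

    Simulates the drug window with ``(latent_div, latent_die)`` as inputs
    (no gating, no sister coupling) and compares the simulated *observed*
    division/death-time histograms to the data's observed histograms by
    two-sample KS tests.  Also runs the negative control in which the
    observed distributions themselves are (incorrectly) used as latent
    inputs — competition biases them a second time, so the control should
    be rejected.
    """
    T_d = data_forest.T_d
    switch = T_d + DRUG_DELAY_H
    data_imt = np.array([c.lifetime for c in data_forest.cells.values()
                         if c.fate is Fate.DIVIDED and c.end_time > switch])
    data_at = np.array([c.lifetime for c in data_forest.cells.values()
                        if c.fate is Fate.DIED and c.end_time > switch])

    def observed(div, die, sd_offset):
        spec = SimulationSpec(
            n_founders=n_founders, t_total=POST_WINDOW_H + 20.0,
            pre_model=EpochModel(div=div, die=die),
            founder_birth_spread=16.0, seed=seed + sd_offset)
        f = simulate_forest(spec)
        sim_imt = np.array([c.lifetime for c in f.cells.values() if c.fate is Fate.DIVIDED])
        sim_at = np.array([c.lifetime for c in f.cells.values() if c.fate is Fate.DIED])
        return sim_imt, sim_at

    sim_imt, sim_at = observed(latent_div, latent_die, 0)
    ks_imt = sstats.ks_2samp(sim_imt, data_imt)
    ks_at = sstats.ks_2samp(sim_at, data_at)

    # negative control: plain EMG fits of the observed histograms as inputs
    obs_div_fit = emg_fit_mle(data_imt, seed=seed)
    obs_die_fit = emg_fit_mle(data_at, seed=seed)
    ctl_imt_s, ctl_at_s = observed(obs_div_fit.params, obs_die_fit.params, 1)
    ks_ctl_imt = sstats.ks_2samp(ctl_imt_s, data_imt)
    ks_ctl_at = sstats.ks_2samp(ctl_at_s, data_at)

    return {
        "latent_inputs": {
            "imt": {"stat": float(ks_imt.statistic), "p": float(ks_imt.pvalue),
                    "rejected": bool(ks_imt.pvalue < alpha),
                    "sim_mean": float(np.mean(sim_imt)), "n_sim": int(sim_imt.size)},
            "at": {"stat": float(ks_at.statistic), "p": float(ks_at.pvalue),
                   "rejected": bool(ks_at.pvalue < alpha),
                   "sim_mean": float(np.mean(sim_at)), "n_sim": int(sim_at.size)},
        },
        "observed_as_inputs_control": {
            "imt": {"stat": float(ks_ctl_imt.statistic), "p": float(ks_ctl_imt.pvalue),
                    "rejected": bool(ks_ctl_imt.pvalue < alpha)},
            "at": {"stat": float(ks_ctl_at.statistic), "p": float(ks_ctl_at.pvalue),
                   "rejected": bool(ks_ctl_at.pvalue < alpha)},
        },
        "n_data": {"imt": int(data_imt.size), "at": int(data_at.size)},
    }


# --- Fig.5c no-gating null -------------------------------------------------


def run_null_model(mu_die_grid=(18.0, 22.0, 26.0, 30.0, 34.0), n_runs: int = 25,
                   seed: int = 0) -> pd.DataFrame:
    """Stochastic fate competition alone, across death-clock locations.

    Simulates the untreated experiment with the death channel enabled at
    varying ``mu_die`` (no oscillator, no sister coupling) and summarizes
    the lineage correlations and death counts — demonstrating that
    competition by itself produces near-zero correlations.
    """
    rows = []
    die_shape = EMGParams.from_moments(20.0, 6.0, 0.5)
    for mu_die in mu_die_grid:
        die = EMGParams(mu=float(mu_die) - 1.0 / die_shape.lam,
                        sigma=die_shape.sigma, lam=die_shape.lam)
        spec = SimulationSpec(
            n_founders=24, t_total=DRUG_TIME_H, T_d=DRUG_TIME_H,
            pre_model=EpochModel(div=PRE_IMT_LATENT, die=die),
            founder_birth_spread=16.0, seed=seed)
        per_run, q = run_replicates(spec, n_runs, metrics=DEFAULT_METRICS)
        deaths = []
        for i in range(n_runs):
            f = simulate_forest(replace(spec, seed=seed + i))
            deaths.append(sum(1 for c in f.cells.values() if c.fate is Fate.DIED))
        row = {"mu_die": float(mu_die), "mean_deaths": float(np.mean(deaths))}
        for m in DEFAULT_METRICS:
            row[f"{m.name}_median"] = q.loc[0.5, m.name]
        rows.append(row)
    return pd.DataFrame(rows)


# --- circadian gating suite ------------------------------------------------

#: mother->daughter clock-phase jitter of the standard gating configuration
#: (radians per division); see docs/methods.md for the calibration.
GATING_PHASE_JITTER = 0.5


def pre_gating_spec(seed: int = 0, n_founders: int = 24,
                    period_T: float = 24.0) -> SimulationSpec:
    """Untreated experiment gated by the oscillator (amplitude uncalibrated)."""
    return SimulationSpec(
        n_founders=n_founders, t_total=DRUG_TIME_H, T_d=DRUG_TIME_H,
        pre_model=EpochModel(div=PRE_IMT_LATENT, die=None),
        clock=ClockSpec(period_T=period_T, phase_noise_sd=GATING_PHASE_JITTER),
        founder_birth_spread=16.0, seed=seed)


def post_gating_spec(seed: int = 0, n_founders: int = 18, A_div: float = 2.98,
                     gate_death: bool = True) -> SimulationSpec:
    """Two-epoch drug experiment with oscillator gating of the post clocks.

    The post-drug division gate runs at the same between-lineage variance
    share as the calibrated pre-drug gate (scaled by the sd ratio of the
    latent IMT distributions); its channel noise is shrunk accordingly.
    The death-gate amplitude starts at 0 and is calibrated by
    :func:`run_gating_suite` when ``gate_death``.
    """
    a_div_post = A_div * POST_IMT_LATENT.sd / PRE_IMT_LATENT.sd
    div_m = shrink_to_sd(
        POST_IMT_LATENT,
        max(np.sqrt(max(POST_IMT_LATENT.sd**2 - 0.5 * a_div_post**2, 0.0)),
            0.2 * POST_IMT_LATENT.sd),
    )
    return SimulationSpec(
        n_founders=n_founders, t_total=DRUG_TIME_H + POST_WINDOW_H,
        T_d=DRUG_TIME_H, delay=DRUG_DELAY_H,
        pre_model=EpochModel(div=PRE_IMT_LATENT, die=None),
        post_model=EpochModel(div=div_m, die=POST_AT_LATENT),
        clock=ClockSpec(period_T=24.0, A_div=A_div,
                        phase_noise_sd=GATING_PHASE_JITTER,
                        A_div_post=a_div_post,
                        A_die_post=None if not gate_death else 0.0),
        founder_birth_spread=16.0, seed=seed)


STRADDLE_SISTER_IMT = MetricSpec("sister_imt_straddle", Relation.SISTER,
                                 Fate.DIVIDED, Epoch.STRADDLE)


def run_gating_suite(seed: int = 0, n_runs: int = 25, calib_runs: int = 10,
                     scan_periods=(3.5, 12.0, 14.0, 18.5, 24.0, 36.0, 48.0),
                     dphi_values=(0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi),
                     at_ci=(0.48, 0.78)) -> dict:
    """The full oscillator-gating experiment battery.

    1. Pre-drug 24 h gating, amplitude calibrated to the sister IMT target,
       summarized over ``n_runs`` (cousin-mother inequality check).
    2. Period scan with per-period re-calibration.
    3. Post-drug runs: no gating / cell-cycle-only / both gates, with the
       death gate calibrated to the sister death-time target; each reports
       whether the sister AT correlation falls inside the data CI.
    4. Phase-offset scan of the death gate (straddle sister IMT metric).
    5. Sister fate concordance of the two-epoch generative model.
    """
    out: dict = {}

    # 1. pre-drug 24 h gating
    pre = pre_gating_spec(seed=seed)
    pre_cal, pre_r, pre_ok = calibrate_amplitude(pre, 0.73, which="div",
                                                 n_runs=calib_runs)
    per_run, q = run_replicates(pre_cal, n_runs, metrics=DEFAULT_METRICS)
    out["pre_24h"] = {
        "A_div": pre_cal.clock.A_div,
        "calibrated": pre_ok,
        "calibration_r": pre_r,
        "medians": {m.name: float(q.loc[0.5, m.name]) for m in DEFAULT_METRICS},
        "quartiles": q.to_dict(),
        "inequality": bool(q.loc[0.5, "cousin_imt"] > q.loc[0.5, "md_imt"]),
    }

    # 2. period scan
    out["period_scan"] = period_scan(pre, periods_h=scan_periods, n_runs=n_runs,
                                     calib_runs=calib_runs)

    # 3. post-drug gate combinations
    post = post_gating_spec(seed=seed, A_div=pre_cal.clock.A_div)
    both, at_r, at_ok = calibrate_amplitude(post, 0.64, which="die_post",
                                            n_runs=calib_runs)
    no_gate = replace(post, clock=None,
                      post_model=EpochModel(div=POST_IMT_LATENT, die=POST_AT_LATENT))
    cc_only = replace(both, clock=replace(both.clock, A_die_post=0.0),
                      post_model=replace(both.post_model, die=POST_AT_LATENT))
    post_metrics = (STRADDLE_SISTER_IMT,) + AT_METRICS
    gates = {}
    for name, s in (("no_gating", no_gate), ("cell_cycle_only", cc_only),
                    ("both_gates", both)):
        _, qq = run_replicates(s, n_runs, metrics=post_metrics)
        med = {m.name: float(qq.loc[0.5, m.name]) for m in post_metrics}
        gates[name] = med | {
            "at_sister_in_ci": bool(at_ci[0] <= med["sister_at"] <= at_ci[1]),
        }
    gates["both_gates"]["A_die_post"] = both.clock.A_die_post
    gates["both_gates"]["calibrated"] = at_ok
    out["post_gates"] = gates

    # 4. phase-offset scan (death gate shifted out of phase)
    out["phase_scan"] = phase_offset_scan(both, dphi_values, n_runs=n_runs,
                                          metric=STRADDLE_SISTER_IMT)

    # 5. sister fate concordance of the generative two-epoch model
    from .simulator import cisplatin_spec

    conc = []
    for i in range(n_runs):
        f = simulate_forest(cisplatin_spec(seed=seed + 9000 + i))
        exposed = [p for p in extract_pairs(f, Relation.SISTER)
                   if f.cells[p.id1].end_time > f.T_d
                   and f.cells[p.id2].end_time > f.T_d]
        cc = fate_concordance(exposed)
        conc.append((cc.fraction_same_fate, cc.expected_independent))
    conc = np.array(conc)
    out["fate_concordance"] = {
        "fraction_same_fate": float(np.median(conc[:, 0])),
        "expected_independent": float(np.median(conc[:, 1])),
    }
    return out
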