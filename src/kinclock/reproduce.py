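"""End-to-end reproduction batteries for the emulated two-epoch study.

Each function regenerates its inputs from the synthetic-experiment
generator (or from closed-form oracles), runs the relevant part of the
package, and returns plain dictionaries of the measured quantities.  They
are consumed by the validation test-suite and by ``scripts/acceptance.py``,
and are all deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import integrate, stats as sstats

from .emg import EMGParams, emg_hazard, emg_pdf, emg_survival
from .experiments import (
    STRADDLE_SISTER_IMT,
    fit_epoch,
    post_gating_spec,
    pre_gating_spec,
    run_bias_demo,
    run_null_model,
)
from .inference import (
    CompetingRisksModel,
    fit_model,
    gaussian_copula_density,
    inferred_underlying,
    sample_pairs_from_model,
)
from .inference import _pairs_loglik
from .lineage import Epoch, Fate, Relation, epoch_of, extract_pairs
from .pairstats import fate_concordance, pearson_with_inference
from .proteins import falsification_experiment, gillespie_trajectory
from .simulator import (
    AT_METRICS,
    DRUG_DELAY_H,
    POST_AT_LATENT,
    POST_IMT_LATENT,
    calibrate_amplitude,
    cisplatin_spec,
    phase_offset_scan,
    pre_only_spec,
    run_replicates,
    simulate_forest,
)

__all__ = [
    "data_statistics",
    "inference_reproduction",
    "parameter_recovery",
    "oracle_checks",
    "validation_loop",
    "correlation_structure",
    "fate_concordance_check",
]


def _median(values):
    v = [x for x in values if x is not None and np.isfinite(x)]
    return float(np.median(v)) if v else float("nan")


def data_statistics(seed: int = 0, n_replicates: int = 12) -> dict:
    """Descriptive statistics of the emulated experiment.

    Correlations and distribution moments are medians over
    ``n_replicates`` independently generated datasets of the study's size,
    so they measure the generator/pipeline property rather than one draw.
    """
    per = {k: [] for k in ("pre_sister", "pre_md", "pre_cousin", "at_sister",
                           "at_cousin", "pre_imt_mean", "straddle_mean",
                           "straddle_sd", "n_pre_imt", "n_straddle", "n_at",
                           "n_pre_sister_pairs", "n_at_sister_pairs")}
    for i in range(n_replicates):
        pre = simulate_forest(pre_only_spec(seed=seed + 10 * i))
        cis = simulate_forest(cisplatin_spec(seed=seed + 10 * i + 1))

        def corr(forest, rel, epoch, fate, symmetrize=True):
            pairs = extract_pairs(forest, rel, epoch, fate)
            if len(pairs) < 3:
                return None, len(pairs)
            return pearson_with_inference(pairs, symmetrize=symmetrize).rho, len(pairs)

        r, n = corr(pre, Relation.SISTER, Epoch.PRE, Fate.DIVIDED)
        per["pre_sister"].append(r)
        per["n_pre_sister_pairs"].append(n)
        per["pre_md"].append(corr(pre, Relation.MOTHER_DAUGHTER, Epoch.PRE,
                                  Fate.DIVIDED, symmetrize=False)[0])
        per["pre_cousin"].append(corr(pre, Relation.COUSIN, Epoch.PRE, Fate.DIVIDED)[0])
        r, n = corr(cis, Relation.SISTER, None, Fate.DIED)
        per["at_sister"].append(r)
        per["n_at_sister_pairs"].append(n)
        per["at_cousin"].append(corr(cis, Relation.COUSIN, None, Fate.DIED)[0])

        pre_imt = [c.lifetime for c in pre.cells.values() if c.fate is Fate.DIVIDED]
        straddle = [c.lifetime for c in cis.cells.values()
                    if c.fate is Fate.DIVIDED and epoch_of(c, cis.T_d) is Epoch.STRADDLE]
        at = [c.lifetime for c in cis.cells.values() if c.fate is Fate.DIED]
        per["pre_imt_mean"].append(float(np.mean(pre_imt)))
        per["straddle_mean"].append(float(np.mean(straddle)))
        per["straddle_sd"].append(float(np.std(straddle, ddof=1)))
        per["n_pre_imt"].append(len(pre_imt))
        per["n_straddle"].append(len(straddle))
        per["n_at"].append(len(at))
    return {k: _median(v) for k, v in per.items()}


def inference_reproduction(seed: int = 0, big_founders: int = 300) -> dict:
    """Copula competing-risks inference on the emulated datasets.

    Pre-drug: fitted sister coupling vs the directly computed Pearson r on
    the same (study-sized) dataset.  Post-drug: latent IMT moments
    recovered from a larger synthetic cohort, so the check reflects the
    estimator rather than single-replicate sampling noise.
    """
    pre = simulate_forest(pre_only_spec(seed=seed))
    direct = pearson_with_inference(
        extract_pairs(pre, Relation.SISTER, Epoch.PRE, Fate.DIVIDED)).rho
    pre_fit = fit_epoch(pre, "pre", seed=seed, n_restarts=2)

    cis = simulate_forest(replace(cisplatin_spec(seed=seed), n_founders=big_founders))
    post_fit = fit_epoch(cis, "post", delay=DRUG_DELAY_H, seed=seed, n_restarts=2)
    _, _, summary = inferred_underlying(post_fit)
    return {
        "pre_direct_r": float(direct),
        "pre_fitted_z": float(pre_fit.model.z),
        "pre_fitted_imt_mean": float(pre_fit.model.theta_div.mean),
        "post_latent_imt_mean": float(summary["imt"][0]),
        "post_latent_imt_sd": float(summary["imt"][1]),
        "post_latent_at_mean": float(summary["at"][0]),
        "post_latent_at_sd": float(summary["at"][1]),
        "post_fitted_z": float(post_fit.model.z),
        "generating_post_imt_mean": POST_IMT_LATENT.mean,
        "generating_post_imt_sd": POST_IMT_LATENT.sd,
        "n_post_pairs": post_fit.n_pairs,
        "converged": bool(pre_fit.converged and post_fit.converged),
    }


def parameter_recovery(seed: int = 0, n_datasets: int = 50, n_pairs: int = 200) -> dict:
    """Recovery of (theta_div, theta_die, z) from synthetic sister pairs."""
    true = CompetingRisksModel(
        theta_div=EMGParams(17.0, 5.0, 1 / 12.0),
        theta_die=EMGParams(20.0, 7.0, 1 / 9.0),
        z=0.6, censor_horizon=72.0)

    def moment_init(pairs):
        tdiv = np.array([t for p in pairs for t, e in ((p.t1, p.e1), (p.t2, p.e2))
                         if e is Fate.DIVIDED])
        tdie = np.array([t for p in pairs for t, e in ((p.t1, p.e1), (p.t2, p.e2))
                         if e is Fate.DIED])
        return CompetingRisksModel(
            theta_div=EMGParams.from_moments(tdiv.mean(), max(tdiv.std(), 1.0), 0.5),
            theta_die=EMGParams.from_moments(tdie.mean(), max(tdie.std(), 1.0), 0.5),
            z=0.4, censor_horizon=72.0)

    z_err, mean_err = [], []
    for i in range(n_datasets):
        rng = np.random.default_rng(seed + 1000 + i)
        pairs = sample_pairs_from_model(true, n_pairs, rng, censor_horizon=72.0)
        fit = fit_model(pairs, [], init=moment_init(pairs), n_restarts=2, seed=seed)
        z_err.append(abs(fit.model.z - true.z))
        mean_err.append(abs(fit.model.theta_div.mean - true.theta_div.mean)
                        / true.theta_div.mean)
    return {
        "median_abs_z_error": float(np.median(z_err)),
        "median_latent_mean_rel_error": float(np.median(mean_err)),
        "n_datasets": n_datasets,
        "n_pairs": n_pairs,
    }


def oracle_checks(seed: int = 0) -> dict:
    """Numerical agreement with independent closed-form/quadrature oracles."""
    p = EMGParams(10.0, 2.0, 0.25)

    def convolved(t):
        f = lambda s: sstats.norm.pdf(s, p.mu, p.sigma) * p.lam * np.exp(-p.lam * (t - s))
        val, _ = integrate.quad(f, p.mu - 10 * p.sigma, t, limit=400)
        return val

    pdf_err = max(abs(float(emg_pdf(t, p)) - convolved(t)) for t in (6.0, 12.0, 20.0, 35.0))

    surv_err = 0.0
    for t in (5.0, 10.0, 18.0, 25.0):
        ih, _ = integrate.quad(lambda s: emg_hazard(s, p), 0.0, t, limit=300)
        surv_err = max(surv_err, abs(np.exp(-ih)
                                     - float(emg_survival(t, p) / emg_survival(0.0, p))))

    cop_val, _ = integrate.dblquad(
        lambda u, v: gaussian_copula_density(u, v, 0.6), 0, 1, 0, 1, epsabs=1e-9)
    cop_err = abs(cop_val - 1.0)

    model = CompetingRisksModel(theta_div=p, theta_die=EMGParams(12.0, 3.0, 0.3), z=0.55)
    t = np.linspace(0.0, 120.0, 900)
    T1, T2 = np.meshgrid(t, t)
    zeros = np.zeros(T1.size)
    tot = 0.0
    for e1 in (0, 1):
        for e2 in (0, 1):
            ll = _pairs_loglik(T1.ravel(), T2.ravel(), np.full(T1.size, e1),
                               np.full(T1.size, e2), model, zeros, zeros)
            tot += np.trapezoid(np.trapezoid(np.exp(ll).reshape(T1.shape), t, axis=1), t)
    pair_err = abs(tot - 1.0)

    ends = [gillespie_trajectory(25.0, 0.5, 50, 30.0, np.random.default_rng(seed + s))[1][-1]
            for s in range(300)]
    m = 25.0 / 0.5
    gil_rel = abs(float(np.mean(ends)) - m) / m
    gil_3se = 3 * np.sqrt(m / 300) / m

    return {
        "emg_pdf_vs_convolution_max_abs_err": float(pdf_err),
        "survival_vs_exp_integrated_hazard_max_abs_err": float(surv_err),
        "copula_density_integral_abs_err": float(cop_err),
        "pair_likelihood_normalization_abs_err": float(pair_err),
        "gillespie_stationary_mean_rel_err": float(gil_rel),
        "gillespie_rel_3se": float(gil_3se),
    }


def validation_loop(seed: int = 0) -> dict:
    """Fit the drug epoch, then simulate with the inferred latents."""
    forest = simulate_forest(cisplatin_spec(seed=seed))
    fit = fit_epoch(forest, "post", delay=DRUG_DELAY_H, seed=seed)
    demo = run_bias_demo(fit.model.theta_div, fit.model.theta_die, forest, seed=seed)
    demo["fitted_latent_imt_mean"] = float(fit.model.theta_div.mean)
    return demo


def correlation_structure(seed: int = 0, n_runs: int = 25, pre_runs: int = 100) -> dict:
    """The oscillator-gating battery (pre-drug, periods, gates, phase scan,
    protein falsification, competition-only null)."""
    out: dict = {}

    pre = pre_gating_spec(seed=seed)
    pre_cal, pre_r, pre_ok = calibrate_amplitude(pre, 0.73, which="div", n_runs=10)
    _, q = run_replicates(pre_cal, pre_runs)
    out["pre_24h"] = {
        "A_div": float(pre_cal.clock.A_div),
        "calibration_r": float(pre_r),
        "calibrated": bool(pre_ok),
        "sister_median": float(q.loc[0.5, "sister_imt"]),
        "md_median": float(q.loc[0.5, "md_imt"]),
        "cousin_median": float(q.loc[0.5, "cousin_imt"]),
    }

    periods = {}
    for T in (3.5, 18.5):
        s = replace(pre, clock=replace(pre.clock, period_T=T))
        cal, r, ok = calibrate_amplitude(s, 0.73, which="div", n_runs=10)
        _, qq = run_replicates(cal, n_runs)
        periods[str(T)] = {
            "calibration_r": float(r), "calibrated": bool(ok),
            "sister_median": float(qq.loc[0.5, "sister_imt"]),
            "md_median": float(qq.loc[0.5, "md_imt"]),
            "cousin_median": float(qq.loc[0.5, "cousin_imt"]),
        }
    out["periods"] = periods

    post = post_gating_spec(seed=seed, A_div=pre_cal.clock.A_div)
    both, at_r, at_ok = calibrate_amplitude(post, 0.64, which="die_post", n_runs=10)
    cc_only = replace(both, clock=replace(both.clock, A_die_post=0.0),
                      post_model=replace(both.post_model, die=POST_AT_LATENT))
    post_metrics = (STRADDLE_SISTER_IMT,) + AT_METRICS
    gates = {}
    for name, s in (("cell_cycle_only", cc_only), ("both_gates", both)):
        _, qq = run_replicates(s, n_runs, metrics=post_metrics)
        gates[name] = {m.name: float(qq.loc[0.5, m.name]) for m in post_metrics}
    gates["both_gates"]["calibrated"] = bool(at_ok)
    out["post_gates"] = gates

    scan = phase_offset_scan(both, (0.0, np.pi / 2, np.pi), n_runs=n_runs,
                             metric=STRADDLE_SISTER_IMT)
    out["phase_scan"] = {f"{row.delta_phi:.3f}": float(row.median_r)
                         for row in scan.itertuples()}

    out["proteins"] = falsification_experiment(n_runs=n_runs, seed=seed).to_dict("records")

    null = run_null_model(n_runs=n_runs, seed=seed)
    out["null_model_max_abs_median_r"] = float(
        null[[c for c in null.columns if c.endswith("_median")]].abs().max().max())
    return out


def fate_concordance_check(seed: int = 0, n_runs: int = 25) -> dict:
    """Sister same-fate fraction of the generative two-epoch model."""
    frac, exp = [], []
    for i in range(n_runs):
        f = simulate_forest(cisplatin_spec(seed=seed + 9000 + i))
        exposed = [p for p in extract_pairs(f, Relation.SISTER)
                   if f.cells[p.id1].end_time > f.T_d
                   and f.cells[p.id2].end_time > f.T_d]
        cc = fate_concordance(exposed)
        frac.append(cc.fraction_same_fate)
        exp.append(cc.expected_independent)
    return {
        "fraction_same_fate": float(np.median(frac)),
        "expected_independent": float(np.median(exp)),
        "n_runs": n_runs,
    }
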