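"""Copula competing-risks inference of latent fate-time distributions.

A cell carries two latent clocks: a division clock and a death clock, each
EMG-distributed; only the earlier of the two latent times is observed, so
the histograms of observed inter-mitotic times (IMT) and apoptosis times
(AT) are biased toward short times whenever the latent distributions
overlap.  Sister cells are strongly correlated, so pairs are modeled
jointly: the bivariate density of a concordant sister pair is

    f(t1, t2) = c_z(F(t1), F(t2)) * S(t1) h_e1(t1) * S(t2) h_e2(t2)

where S = S_div * S_die is the overall survival of a cell, F = 1 - S,
h_k is the cause-specific hazard (division or death), and c_z is the
Gaussian-copula density with correlation z — z plays the role of the
sister-sister Pearson correlation.  Right-censored members contribute
conditional-copula survival terms, untracked-sister singletons contribute
univariate terms, and a scalar delay shifts the effective drug-epoch
boundary.  Maximizing the product of these terms over all pairs recovers
the *latent* (pre-competition) IMT and AT distributions — the hidden
heterogeneity that the raw histograms mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .emg import EMGParams, emg_log_survival, emg_logpdf
from .lineage import Fate, PairObservation

__all__ = [
    "CompetingRisksModel",
    "FitResult",
    "gaussian_copula_density",
    "gaussian_copula_cdf",
    "conditional_copula_survival",
    "overall_survival",
    "overall_log_survival",
    "cause_log_density",
    "pair_loglikelihood",
    "dataset_loglik",
    "sample_pairs_from_model",
    "fit_model",
    "inferred_underlying",
]

_UEPS = 1e-12


@dataclass(frozen=True)
class CompetingRisksModel:
    """Latent two-clock model with sister coupling.

    ``theta_die=None`` disables the death channel (appropriate before drug
    treatment where death is negligible).  ``censor_horizon`` is the age at
    which survivors are administratively censored; ``delay`` is the lag
    between drug administration and the realization of its effect, used
    upstream when classifying events into epochs.
    """

    theta_div: EMGParams
    theta_die: EMGParams | None = None
    z: float = 0.0
    delay: float = 0.0
    censor_horizon: float | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.z < 1.0):
            raise ValueError(f"|z| must be < 1, got {self.z}")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class FitResult:
    model: CompetingRisksModel
    loglik: float
    se: dict[str, float]
    converged: bool
    n_pairs: int
    n_singletons: int
    free_names: tuple[str, ...] = ()


def gaussian_copula_density(u1, u2, z: float):
    """Density of the Gaussian copula with correlation z; c == 1 at z = 0."""
    if not (-1.0 < z < 1.0):
        raise ValueError(f"|z| must be < 1, got {z}")
    return np.exp(_log_copula_density(np.asarray(u1, float), np.asarray(u2, float), z))


def _log_copula_density(u1, u2, z: float):
    x = stats.norm.ppf(np.clip(u1, _UEPS, 1 - _UEPS))
    y = stats.norm.ppf(np.clip(u2, _UEPS, 1 - _UEPS))
    om = 1.0 - z * z
    return -0.5 * np.log(om) - (z * z * (x * x + y * y) - 2.0 * z * x * y) / (2.0 * om)


def _bvn_cdf(x, y, rho: float):
    """Standard bivariate-normal CDF P(X<=x, Y<=y) via Owen's T function.

    Vectorized and accurate to ~1e-14; exact zeros are nudged by 1e-12 to
    avoid the removable singularity in the Owen decomposition.
    """
    if abs(rho) >= 1.0 - 1e-12:
        s = np.sign(rho) if rho != 0 else 1.0
        if s > 0:
            return stats.norm.cdf(np.minimum(x, y))
        return np.clip(stats.norm.cdf(x) + stats.norm.cdf(y) - 1.0, 0.0, None)
    x = np.where(np.abs(x) < 1e-12, 1e-12, np.asarray(x, float))
    y = np.where(np.abs(y) < 1e-12, 1e-12, np.asarray(y, float))
    rr = np.sqrt(1.0 - rho * rho)
    a1 = (y / x - rho) / rr
    a2 = (x / y - rho) / rr
    beta = np.where(x * y < 0, 0.5, 0.0)
    return (
        0.5 * (stats.norm.cdf(x) + stats.norm.cdf(y))
        - special.owens_t(x, a1)
        - special.owens_t(y, a2)
        - beta
    )


def gaussian_copula_cdf(u1, u2, z: float):
    """C(u1, u2; z): bivariate-normal CDF evaluated at the normal scores."""
    scalar = np.ndim(u1) == 0 and np.ndim(u2) == 0
    u1 = np.clip(np.asarray(u1, float), _UEPS, 1 - _UEPS)
    u2 = np.clip(np.asarray(u2, float), _UEPS, 1 - _UEPS)
    out = _bvn_cdf(stats.norm.ppf(u1), stats.norm.ppf(u2), z)
    return float(out) if scalar else out


def conditional_copula_survival(u_obs, u_cens, z: float):
    """P(U2 > u_cens | U1 = u_obs) = 1 - dC/du1: sister survives past censoring."""
    x = stats.norm.ppf(np.clip(u_obs, _UEPS, 1 - _UEPS))
    y = stats.norm.ppf(np.clip(u_cens, _UEPS, 1 - _UEPS))
    return stats.norm.sf((y - z * x) / np.sqrt(1.0 - z * z))


def overall_log_survival(t, model: CompetingRisksModel):
    ls = emg_log_survival(t, model.theta_div)
    if model.theta_die is not None:
        ls = ls + emg_log_survival(t, model.theta_die)
    return ls


def overall_survival(t, model: CompetingRisksModel):
    """S(t) = S_div(t) * S_die(t): latent clocks independent within a cell."""
    return np.exp(overall_log_survival(t, model))


def cause_log_density(t, model: CompetingRisksModel, cause: Fate):
    """log of the observed (sub-)density S(t) h_cause(t) at age t."""
    if cause is Fate.DIVIDED:
        out = emg_logpdf(t, model.theta_div)
        if model.theta_die is not None:
            out = out + emg_log_survival(t, model.theta_die)
        return out
    if cause is Fate.DIED:
        if model.theta_die is None:
            raise ValueError("death channel is disabled in this model")
        return emg_logpdf(t, model.theta_die) + emg_log_survival(t, model.theta_div)
    raise ValueError(f"no observed density for fate {cause}")


def _overall_cdf(t, model: CompetingRisksModel):
    return -np.expm1(overall_log_survival(t, model))


def pair_loglikelihood(pair: PairObservation, model: CompetingRisksModel) -> float:
    """Log joint density / probability of one sister pair under the model.

    Non-zero ``entry`` ages (delayed entry: the cell is only observed under
    this regime from that age onward) condition each margin on survival
    past its entry age.
    """
    if pair.t1 < 0 or pair.t2 < 0:
        raise ValueError("negative lifetime")
    return float(
        _pairs_loglik(
            np.array([pair.t1]),
            np.array([pair.t2]),
            np.array([_code(pair.e1)]),
            np.array([_code(pair.e2)]),
            model,
            np.array([pair.entry1]),
            np.array([pair.entry2]),
        )[0]
    )


_CODE = {Fate.DIVIDED: 0, Fate.DIED: 1, Fate.CENSORED: 2}


def _code(f: Fate) -> int:
    return _CODE[f]


def _pairs_loglik(t1, t2, e1, e2, model: CompetingRisksModel,
                  a1=None, a2=None) -> np.ndarray:
    z = model.z
    lS_a1 = 0.0 if a1 is None else overall_log_survival(a1, model)
    lS_a2 = 0.0 if a2 is None else overall_log_survival(a2, model)
    # conditional (left-truncated) margins: u = 1 - S(t)/S(entry)
    F1 = -np.expm1(overall_log_survival(t1, model) - lS_a1)
    F2 = -np.expm1(overall_log_survival(t2, model) - lS_a2)
    ll = np.zeros(t1.shape)

    both_obs = (e1 < 2) & (e2 < 2)
    one_cens = (e1 < 2) ^ (e2 < 2)
    both_cens = (e1 == 2) & (e2 == 2)

    def obs_logf(t, e, lS_a):
        out = np.empty(t.shape)
        for code, cause in ((0, Fate.DIVIDED), (1, Fate.DIED)):
            m = e == code
            if m.any():
                out[m] = cause_log_density(t[m], model, cause)
        return out - lS_a

    lSa1 = np.broadcast_to(np.asarray(lS_a1, float), t1.shape)
    lSa2 = np.broadcast_to(np.asarray(lS_a2, float), t2.shape)
    if both_obs.any():
        m = both_obs
        ll[m] = (
            _log_copula_density(F1[m], F2[m], z)
            + obs_logf(t1[m], e1[m], lSa1[m])
            + obs_logf(t2[m], e2[m], lSa2[m])
        )
    if one_cens.any():
        m = one_cens
        first_obs = e1[m] < 2
        t_obs = np.where(first_obs, t1[m], t2[m])
        e_obs = np.where(first_obs, e1[m], e2[m])
        u_obs = np.where(first_obs, F1[m], F2[m])
        u_cen = np.where(first_obs, F2[m], F1[m])
        lS_obs = np.where(first_obs, lSa1[m], lSa2[m])
        with np.errstate(divide="ignore"):
            ll[m] = obs_logf(t_obs, e_obs, lS_obs) + np.log(
                np.clip(conditional_copula_survival(u_obs, u_cen, z), 1e-300, None)
            )
    if both_cens.any():
        m = both_cens
        surv = 1.0 - F1[m] - F2[m] + np.atleast_1d(gaussian_copula_cdf(F1[m], F2[m], z))
        ll[m] = np.log(np.clip(surv, 1e-300, None))
    return ll


def dataset_loglik(pairs, singletons, model: CompetingRisksModel) -> float:
    """Total log-likelihood: sum over sister pairs plus singleton terms.

    ``singletons`` is a sequence of ``(lifetime, Fate)`` or
    ``(lifetime, Fate, entry_age)`` for cells whose sister was not tracked;
    observed singletons contribute ``log(S h_e)``, censored singletons
    ``log S``, each divided by ``S(entry)`` under delayed entry.
    """
    if not pairs and not singletons:
        raise ValueError("empty dataset")
    total = 0.0
    if pairs:
        t1 = np.array([p.t1 for p in pairs])
        t2 = np.array([p.t2 for p in pairs])
        e1 = np.array([_code(p.e1) for p in pairs])
        e2 = np.array([_code(p.e2) for p in pairs])
        a1 = np.array([p.entry1 for p in pairs])
        a2 = np.array([p.entry2 for p in pairs])
        total += float(np.sum(_pairs_loglik(t1, t2, e1, e2, model, a1, a2)))
    if singletons:
        ts = np.array([s[0] for s in singletons])
        es = np.array([_code(s[1]) for s in singletons])
        aa = np.array([(s[2] if len(s) > 2 else 0.0) for s in singletons])
        total -= float(np.sum(overall_log_survival(aa, model)))
        for code, cause in ((0, Fate.DIVIDED), (1, Fate.DIED)):
            m = es == code
            if m.any():
                total += float(np.sum(cause_log_density(ts[m], model, cause)))
        m = es == 2
        if m.any():
            total += float(np.sum(overall_log_survival(ts[m], model)))
    return total


def _invert_overall_cdf(v: np.ndarray, model: CompetingRisksModel) -> np.ndarray:
    """Vectorized inversion of the overall CDF F = 1 - S_div*S_die."""
    target = np.log1p(-np.asarray(v, dtype=float))  # log S at the solution
    sd = model.theta_div.sd + (model.theta_die.sd if model.theta_die else 0.0)
    lo = np.full(target.shape, min(model.theta_div.mu,
                                   model.theta_die.mu if model.theta_die else np.inf) - 12 * sd)
    hi = np.full(target.shape, max(model.theta_div.mean,
                                   model.theta_die.mean if model.theta_die else -np.inf) + 40 * sd)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        high_mask = overall_log_survival(mid, model) > target  # S too big -> move right
        lo = np.where(high_mask, mid, lo)
        hi = np.where(high_mask, hi, mid)
    return 0.5 * (lo + hi)


def sample_pairs_from_model(model: CompetingRisksModel, n: int, rng,
                            censor_horizon: float | None = None):
    """Draw sister pairs exactly from the fitted pair density.

    Overall event times come from the Gaussian copula on the overall CDF;
    the cause (division vs death) is then assigned with probability
    proportional to the cause-specific hazard at the drawn time, which
    reproduces the pair likelihood exactly.  Times past ``censor_horizon``
    are right-censored there.
    """
    rng = np.random.default_rng(rng)
    g = rng.standard_normal((n, 2))
    g2 = model.z * g[:, 0] + np.sqrt(1.0 - model.z**2) * g[:, 1]
    v = np.column_stack([stats.norm.cdf(g[:, 0]), stats.norm.cdf(g2)])
    v = np.clip(v, _UEPS, 1 - _UEPS)
    # lifetimes are non-negative: the copula couples the conditional
    # (truncated-at-zero) margins, matching the likelihood's convention
    F0 = float(_overall_cdf(np.asarray(0.0), model))
    v = F0 + v * (1.0 - F0)
    t = np.column_stack([_invert_overall_cdf(v[:, 0], model),
                         _invert_overall_cdf(v[:, 1], model)])
    if model.theta_die is not None:
        log_hdiv = emg_logpdf(t, model.theta_div) - emg_log_survival(t, model.theta_div)
        log_hdie = emg_logpdf(t, model.theta_die) - emg_log_survival(t, model.theta_die)
        p_div = 1.0 / (1.0 + np.exp(log_hdie - log_hdiv))
        causes = np.where(rng.uniform(size=(n, 2)) < p_div, 0, 1)
    else:
        causes = np.zeros((n, 2), dtype=int)
    pairs = []
    inv = {0: Fate.DIVIDED, 1: Fate.DIED}
    for i in range(n):
        tt, ee = [], []
        for j in (0, 1):
            if censor_horizon is not None and t[i, j] > censor_horizon:
                tt.append(censor_horizon)
                ee.append(Fate.CENSORED)
            else:
                tt.append(float(t[i, j]))
                ee.append(inv[int(causes[i, j])])
        pairs.append(PairObservation(tt[0], tt[1], ee[0], ee[1], None))
    return pairs


# --- fitting ---------------------------------------------------------------

_PARAM_NAMES = ("mu_div", "sigma_div", "lam_div", "mu_die", "sigma_die", "lam_die", "z")


def _model_to_vec(model: CompetingRisksModel) -> dict[str, float]:
    d = {
        "mu_div": model.theta_div.mu,
        "sigma_div": model.theta_div.sigma,
        "lam_div": model.theta_div.lam,
        "z": model.z,
    }
    if model.theta_die is not None:
        d |= {
            "mu_die": model.theta_die.mu,
            "sigma_die": model.theta_die.sigma,
            "lam_die": model.theta_die.lam,
        }
    return d


def _transform(name: str, value: float) -> float:
    if name.startswith(("sigma", "lam")):
        return float(np.log(value))
    if name == "z":
        return float(np.arctanh(value))
    return float(value)


def _untransform(name: str, value: float) -> float:
    if name.startswith(("sigma", "lam")):
        return float(np.exp(value))
    if name == "z":
        return float(np.tanh(value))
    return float(value)


def _build_model(vals: dict[str, float], template: CompetingRisksModel) -> CompetingRisksModel:
    theta_div = EMGParams(vals["mu_div"], vals["sigma_div"], vals["lam_div"])
    theta_die = None
    if template.theta_die is not None:
        theta_die = EMGParams(vals["mu_die"], vals["sigma_die"], vals["lam_die"])
    return CompetingRisksModel(
        theta_div=theta_div,
        theta_die=theta_die,
        z=np.clip(vals["z"], -1 + 1e-10, 1 - 1e-10),
        delay=template.delay,
        censor_horizon=template.censor_horizon,
    )


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f(x) + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def fit_model(
    pairs,
    singletons,
    init: CompetingRisksModel,
    fixed_params: dict[str, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of the copula competing-risks model.

    Optimizes on an unconstrained scale (log sigma, log lam, atanh z) with
    Nelder-Mead from ``n_restarts`` jittered starts around ``init``.
    Standard errors come from the inverse of a central-finite-difference
    Hessian of the negative log-likelihood, delta-method transformed back
    to the natural scale; a singular Hessian yields NaN SEs with the fit
    still returned.
    """
    fixed = dict(fixed_params or {})
    base = _model_to_vec(init)
    free_names = [n for n in _PARAM_NAMES if n in base and n not in fixed]
    if not free_names:
        raise ValueError("no free parameters")

    def unpack(eta: np.ndarray) -> dict[str, float]:
        vals = {n: _untransform(n, v) for n, v in zip(free_names, eta)}
        for n in base:
            if n in fixed:
                vals[n] = fixed[n]
            elif n not in vals:
                vals[n] = base[n]
        return vals

    def nll(eta: np.ndarray) -> float:
        try:
            model = _build_model(unpack(eta), init)
            val = -dataset_loglik(pairs, singletons, model)
        except (ValueError, FloatingPointError):
            return 1e300
        return val if np.isfinite(val) else 1e300

    eta0 = np.array([_transform(n, base[n]) for n in free_names])
    rng = np.random.default_rng(seed)
    starts = [eta0] + [eta0 + rng.normal(0, 0.25, eta0.size) for _ in range(n_restarts - 1)]

    best_eta, best_val, ok = None, np.inf, False
    for s0 in starts:
        res = optimize.minimize(
            nll, s0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000},
        )
        if res.fun < best_val:
            best_eta, best_val, ok = res.x, float(res.fun), bool(res.success)

    model = _build_model(unpack(best_eta), init)
    se: dict[str, float] = {}
    try:
        H = _fd_hessian(nll, best_eta)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        for i, n in enumerate(free_names):
            if diag[i] <= 0:
                se[n] = float("nan")
                continue
            se_eta = float(np.sqrt(diag[i]))
            # delta method: d(natural)/d(transformed) at the optimum
            if n.startswith(("sigma", "lam")):
                jac = _untransform(n, best_eta[i])
            elif n == "z":
                jac = 1.0 - np.tanh(best_eta[i]) ** 2
            else:
                jac = 1.0
            se[n] = se_eta * abs(jac)
    except np.linalg.LinAlgError:
        se = {n: float("nan") for n in free_names}

    return FitResult(
        model=model,
        loglik=-best_val,
        se=se,
        converged=ok,
        n_pairs=len(pairs),
        n_singletons=len(singletons) if singletons else 0,
        free_names=tuple(free_names),
    )


def inferred_underlying(fit: FitResult):
    """Latent (pre-competition) IMT/AT distributions and their moments.

    Returns ``(theta_div, theta_die, summary)`` where summary maps channel
    name to (mean, sd) computed from the EMG closed forms; this is the
    hidden-heterogeneity readout.  Refuses an unconverged fit.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing latent readout")
    m = fit.model
    summary = {"imt": (m.theta_div.mean, m.theta_div.sd)}
    if m.theta_die is not None:
        summary["at"] = (m.theta_die.mean, m.theta_die.sd)
    return m.theta_div, m.theta_die, summary
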