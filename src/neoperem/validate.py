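"""Model validation: nonparametric bootstrap, normalized prediction
distribution errors (NPDE), and goodness-of-fit diagnostics.

The bootstrap resamples subjects with replacement and refits the model to
each replicate; parameter percentiles across converged replicates quantify
estimation uncertainty.  NPDE simulates the dataset many times under the
model, decorrelates each subject's observation vector with the simulated
mean and covariance, rank-transforms the observed data within the
simulated distribution, and maps the ranks through the inverse normal:
under a correct model the NPDE are standard normal.  Goodness-of-fit
reports population predictions (random effects at zero), individual
predictions (empirical-Bayes random effects) and conditional weighted
residuals (CWRES) from the first-order-conditional linearization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import (
    FitResult,
    ModelStructure,
    TDMDataset,
    _Engine,
    _warm_x0,
    final_structure,
    fit,
    resample_subjects,
)
from .popmodel import PopulationParameters

__all__ = ["BootstrapResult", "NpdeResult", "bootstrap", "npde", "gof"]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile summary of refits on subject-resampled replicates."""

    summary: pd.DataFrame          # param, original, median, lo, hi
    n_replicates: int
    n_converged: int
    converged_flags: list
    replicate_params: pd.DataFrame

    @property
    def failure_rate(self) -> float:
        return 1.0 - self.n_converged / max(self.n_replicates, 1)


def bootstrap(
    data: TDMDataset,
    structure: ModelStructure | None = None,
    n: int = 1000,
    seed: int = 0,
    original: FitResult | None = None,
    ci: float = 95.0,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, summarize.

    Replicate fits start from the original estimates (standard practice;
    replicates are perturbations of the original data).  Non-converged
    replicates are recorded and excluded from the percentiles.
    """
    if structure is None:
        structure = final_structure()
    if original is None:
        original = fit(data, structure=structure, seed=seed)
    if not original.converged:
        raise RuntimeError("original fit did not converge; bootstrap aborted")

    rng = np.random.default_rng(seed)
    n_subj = data.n_subjects
    rows, flags = [], []
    for _b in range(n):
        idx = rng.integers(0, n_subj, n_subj)
        rep = resample_subjects(data, idx)
        rfit = fit(rep, structure=structure, x0=original.x, n_restarts=0,
                   compute_rse=False)
        flags.append(rfit.converged)
        if rfit.converged:
            rows.append(rfit.params)
    reps = pd.DataFrame(rows)
    lo_q, hi_q = (100 - ci) / 200.0, 1 - (100 - ci) / 200.0
    summary = pd.DataFrame(
        {
            "param": list(original.params),
            "original": [original.params[k] for k in original.params],
            "median": [reps[k].median() if len(reps) else np.nan for k in original.params],
            "lo": [reps[k].quantile(lo_q) if len(reps) else np.nan for k in original.params],
            "hi": [reps[k].quantile(hi_q) if len(reps) else np.nan for k in original.params],
        }
    )
    return BootstrapResult(
        summary=summary, n_replicates=n, n_converged=int(np.sum(flags)),
        converged_flags=flags, replicate_params=reps,
    )


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------

@dataclass
class NpdeResult:
    """Per-observation NPDE with location/scale tests.

    ``npde`` is aligned with the observation rows of the dataset (dose rows
    excluded).  ``p_mean`` is a one-sample t-test of mean 0; ``p_variance``
    a chi-square test of variance 1.
    """

    npde: np.ndarray
    mean: float
    se_mean: float
    variance: float
    se_variance: float
    p_mean: float
    p_variance: float
    n_obs: int
    n_sim: int
    flags: list = field(default_factory=list)


def _simulate_subject(engine: _Engine, x, s, n_sim, rng, sigma):
    """Simulate n_sim observation vectors for subject s under the model."""
    o0, o1 = engine.subj_off[s], engine.subj_off[s + 1]
    cl0, v0 = engine._typical_cl_v(x)
    idx = np.arange(o0, o1)
    w1 = math.exp(x[-3])
    w2 = math.exp(x[-2])
    eta1 = rng.normal(0.0, math.sqrt(w1), n_sim)
    eta2 = rng.normal(0.0, math.sqrt(w2), n_sim)
    pm = (engine.p_obs >= o0) & (engine.p_obs < o1)
    loc = engine.p_obs[pm] - o0
    t1, t2, rt = engine.p_tau1[pm], engine.p_tau2[pm], engine.p_rate[pm]
    out = np.empty((n_sim, o1 - o0))
    for k in range(n_sim):
        cl = cl0[idx] * math.exp(eta1[k])
        ke = cl / (v0[idx] * math.exp(eta2[k]))
        f = np.zeros(o1 - o0)
        np.add.at(f, loc, (rt / cl[loc]) * (-np.expm1(-ke[loc] * t1)) * np.exp(-ke[loc] * t2))
        # proportional residual error, redrawn to keep concentrations positive
        y = f * (1.0 + sigma * rng.standard_normal(o1 - o0))
        for _ in range(100):
            neg = y <= 0
            if not neg.any():
                break
            y[neg] = f[neg] * (1.0 + sigma * rng.standard_normal(int(neg.sum())))
        out[k] = y
    return out


def npde(
    data: TDMDataset,
    pop: PopulationParameters,
    n_sim: int = 500,
    seed: int = 0,
) -> NpdeResult:
    """Normalized prediction distribution errors under the final model.

    The dataset is simulated ``n_sim`` times; per subject, observed and
    simulated vectors are decorrelated with the simulated mean and
    covariance (Cholesky), the observed decorrelated values are
    rank-transformed within the simulated ones, and ranks are mapped
    through the inverse standard normal.
    """
    if n_sim < 50:
        raise ValueError("n_sim < 50 gives too coarse a rank resolution")
    engine = _Engine(data, final_structure(bw_ref=pop.bw_ref))
    from .estimate import _pop_to_x

    x = _pop_to_x(engine, pop)
    sigma = math.sqrt(pop.sigma2_prop)
    # one stream per subject, keyed by the subject's rank among sorted ids:
    # the result does not depend on row or subject order in the file
    rank = {sid: k for k, sid in enumerate(sorted(engine.ids, key=str))}

    flags = []
    npde_engine_order = np.empty(engine.n_obs)
    for s in range(engine.n_subj):
        o0, o1 = engine.subj_off[s], engine.subj_off[s + 1]
        rng = np.random.default_rng(np.random.SeedSequence([seed, rank[engine.ids[s]]]))
        sims = _simulate_subject(engine, x, s, n_sim, rng, sigma)
        y = engine.y[o0:o1]
        m = sims.mean(axis=0)
        if o1 - o0 == 1:
            sd = sims.std(axis=0, ddof=1)
            ystar = (y - m) / np.maximum(sd, 1e-12)
            sstar = (sims - m) / np.maximum(sd, 1e-12)
        else:
            C = np.cov(sims.T) + 1e-10 * np.eye(o1 - o0)
            try:
                L = np.linalg.cholesky(C)
                ystar = np.linalg.solve(L, y - m)
                sstar = np.linalg.solve(L, (sims - m).T).T
            except np.linalg.LinAlgError:
                flags.append(f"subject {engine.ids[s]}: singular simulated covariance")
                sd = sims.std(axis=0, ddof=1)
                ystar = (y - m) / np.maximum(sd, 1e-12)
                sstar = (sims - m) / np.maximum(sd, 1e-12)
        counts = (sstar < ystar[None, :]).sum(axis=0)
        pde = counts / n_sim
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        npde_engine_order[o0:o1] = stats.norm.ppf(pde)

    # back to the dataset's observation-row order
    vals = np.empty_like(npde_engine_order)
    vals[engine.obs_order] = npde_engine_order

    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if n > 1 else float("nan")
    if n > 1:
        se_mean = math.sqrt(var / n)
        se_var = var * math.sqrt(2.0 / (n - 1))
        t = mean / se_mean
        p_mean = 2.0 * stats.t.sf(abs(t), n - 1)
        chi = (n - 1) * var
        p_var = 2.0 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1))
        p_var = min(p_var, 1.0)
    else:
        flags.append("single observation: tests degenerate")
        se_mean = se_var = p_mean = p_var = float("nan")
    return NpdeResult(
        npde=vals, mean=mean, se_mean=se_mean, variance=var, se_variance=se_var,
        p_mean=p_mean, p_variance=p_var, n_obs=n, n_sim=n_sim, flags=flags,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def gof(data: TDMDataset, fit_result: FitResult) -> pd.DataFrame:
    """Diagnostic table: PRED, IPRED and CWRES per observation.

    PRED evaluates the model at zero random effects, IPRED at the
    empirical-Bayes estimates.  CWRES decorrelates the first-order-
    conditional residual y - (f(eta_hat) - G eta_hat) with the
    model-implied covariance G Omega G' + diag(sigma2 f(eta_hat)^2); a
    singular per-subject covariance falls back to standardized residuals
    and is flagged in the ``fallback`` column.
    """
    if not fit_result.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    engine = _Engine(data, fit_result.structure)
    x = fit_result.x
    eta = fit_result.etas
    pred = engine.predictions(x, eta=None)
    f_ind, G = engine.pred_and_jacobian(x, eta)
    params = fit_result.params
    w1, w2, s2 = params["omega2_cl"], params["omega2_v"], params["sigma2_prop"]
    omega = np.diag([w1, w2])

    cwres = np.empty(engine.n_obs)
    fallback = np.zeros(engine.n_obs, dtype=bool)
    for s in range(engine.n_subj):
        o0, o1 = engine.subj_off[s], engine.subj_off[s + 1]
        Gs = G[o0:o1]
        fs = f_ind[o0:o1]
        y = engine.y[o0:o1]
        resid = y - (fs - Gs @ eta[s])
        V = Gs @ omega @ Gs.T + np.diag(s2 * np.maximum(fs, 1e-6) ** 2)
        try:
            L = np.linalg.cholesky(V)
            cwres[o0:o1] = np.linalg.solve(L, resid)
        except np.linalg.LinAlgError:
            sd = np.sqrt(np.maximum(np.diag(V), 1e-12))
            cwres[o0:o1] = resid / sd
            fallback[o0:o1] = True

    obs = data.df[(data.df["EVID"] == 0) & (data.df["MDV"] == 0)].reset_index(drop=True)
    inv = np.empty(engine.n_obs, dtype=int)
    inv[engine.obs_order] = np.arange(engine.n_obs)
    table = pd.DataFrame(
        {
            "ID": obs["ID"],
            "TIME": obs["TIME"],
            "DV": obs["DV"],
            "PRED": pred[inv],
            "IPRED": f_ind[inv],
            "CWRES": cwres[inv],
            "fallback": fallback[inv],
        }
    )
    return table
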