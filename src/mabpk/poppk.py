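"""Nonlinear mixed-effects estimation of the population PK model by SAEM.

The hierarchical model: individual structural parameters (CL, Vc, Q, Vp) are
log-normal around population values with a freely estimated 4x4 covariance of
the log random effects; absorption rate ka and bioavailability F carry fixed
effects only (no between-subject variability, mirroring the limited SC data
that motivates that restriction).  Residual error on each observed
concentration is combined: variance = sigma_add^2 + (sigma_prop * c_pred)^2.

Estimation is Stochastic Approximation EM with a random-walk Metropolis
E-step on the individual log parameters, an exploration phase (step size 1,
with simulated-annealing floors on the variance components) followed by a
smoothing phase with step size k^-0.7.  Empirical-Bayes individual estimates
are the modes of the conditional posterior (MAP) given the population fit.
Standard errors come from a stochastic approximation of the Fisher
information (per-subject conditional scores, Fisher identity); they are
approximate for the off-diagonal random-effect structure and labelled as
such.  Marginal log-likelihood is computed on demand by importance sampling
around the individual conditional modes.

Within SAEM the no-variability parameters ka and F are given a small fixed
auxiliary random-effect SD (``aux_sd``) so the MCMC kernel can move them; only
their population means are reported.  This is the standard device for fixed
effects without random effects in SAEM implementations.

Subjects are processed in a canonical order (sorted by id), so permuting the
input leaves every estimate bit-identical for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_ndtr, logit, logsumexp
from sklearn.base import BaseEstimator

from .errors import ConfigError, EstimationError
from .pk_model import StructuralParams
from .trial_data import TrialDataset

__all__ = [
    "PopPKParams",
    "PopPKFit",
    "IndividualParams",
    "SAEMFitter",
    "SAEMConfig",
    "fit_saem",
    "eb_estimates",
    "residual_sd",
    "reference_poppk",
    "importance_loglik",
]

_PARAM_NAMES = ("CL", "Vc", "Q", "Vp")
_LOG2PI = float(np.log(2.0 * np.pi))


def residual_sd(c_pred, sigma_add: float, sigma_prop: float):
    """Residual standard deviation at predicted concentration(s) ``c_pred``.

    The error variance is the sum of a constant additive term and a term
    proportional to the predicted concentration:
    var = sigma_add^2 + (sigma_prop * c_pred)^2.
    """
    c = np.asarray(c_pred, dtype=float)
    if np.any(c < 0):
        raise ValueError("predicted concentrations must be non-negative")
    out = np.sqrt(sigma_add**2 + (sigma_prop * c) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class PopPKParams:
    """Population parameters: fixed effects, random-effect covariance, error model."""

    fixed: StructuralParams
    omega: np.ndarray  # 4x4 covariance of log (CL, Vc, Q, Vp)
    sigma_add: float  # µg/mL
    sigma_prop: float  # fraction

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (4, 4):
            raise ConfigError("omega must be 4x4 over (CL, Vc, Q, Vp)")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ConfigError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(self.omega)) < -1e-10:
            raise ConfigError("omega must be positive semi-definite")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ConfigError("error SDs must be non-negative")
        if self.sigma_add == 0 and self.sigma_prop == 0:
            raise ConfigError("additive and proportional error cannot both be zero")

    def mu_log(self) -> np.ndarray:
        """Population means on the internal scale (log CL..Vp, log ka, logit F)."""
        f = self.fixed
        return np.array(
            [np.log(f.CL), np.log(f.Vc), np.log(f.Q), np.log(f.Vp), np.log(f.ka), logit(f.F)]
        )


def reference_poppk(cl_vc_corr: float = 0.3) -> PopPKParams:
    """Published cross-protocol base-model estimates for VRC07-523LS.

    Fixed effects F=0.47, ka=0.34/day, CL=0.12 L/day, Vc=3.88 L, Q=0.30 L/day,
    Vp=3.60 L; random-effect SDs 0.29/0.40/0.57/0.24 for CL/Vc/Q/Vp; combined
    residual error sigma_add=0.13 µg/mL, sigma_prop=0.14.  The random-effect
    correlations were modelled but not published; the generator default is a
    modest positive CL-Vc correlation (0.3), configurable here.
    """
    sds = np.array([0.29, 0.40, 0.57, 0.24])
    corr = np.eye(4)
    corr[0, 1] = corr[1, 0] = cl_vc_corr
    omega = np.outer(sds, sds) * corr
    return PopPKParams(
        fixed=StructuralParams(CL=0.12, Vc=3.88, Q=0.30, Vp=3.60, F=0.47, ka=0.34),
        omega=omega,
        sigma_add=0.13,
        sigma_prop=0.14,
    )


@dataclass
class IndividualParams:
    """Empirical-Bayes (MAP) structural parameters of one subject, natural scale.

    ka and F are held at their population values (they carry no random
    effects), so they are not part of this record.
    """

    subject_id: str
    CL: float
    Vc: float
    Q: float
    Vp: float

    def __post_init__(self) -> None:
        if min(self.CL, self.Vc, self.Q, self.Vp) <= 0:
            raise ValueError(f"subject {self.subject_id}: parameters must be positive")

    def structural(self, pop: PopPKParams) -> StructuralParams:
        return StructuralParams(self.CL, self.Vc, self.Q, self.Vp,
                                F=pop.fixed.F, ka=pop.fixed.ka)


@dataclass
class PopPKFit:
    """Result of a population fit: estimates, uncertainty, trace, reproducibility."""

    estimate: PopPKParams
    rse: dict[str, float]
    loglik: Optional[float]
    trace: pd.DataFrame
    seed: int
    ids: list[str] = field(default_factory=list)
    eta_mean: Optional[np.ndarray] = None  # (n, 4) conditional mean random effects
    cond_samples: Optional[np.ndarray] = None  # (S, n, 4) conditional draws
    covariate_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        """Fit report with estimate, Wald 95% CI and %RSE per parameter."""
        est = self.estimate
        rows = []
        values = {
            "F": est.fixed.F, "ka": est.fixed.ka, "CL": est.fixed.CL, "Vc": est.fixed.Vc,
            "Q": est.fixed.Q, "Vp": est.fixed.Vp,
            "omega_CL": np.sqrt(est.omega[0, 0]), "omega_Vc": np.sqrt(est.omega[1, 1]),
            "omega_Q": np.sqrt(est.omega[2, 2]), "omega_Vp": np.sqrt(est.omega[3, 3]),
            "sigma_add": est.sigma_add, "sigma_prop": est.sigma_prop,
        }
        for p, beta in self.covariate_coefficients.items():
            for cov, val in beta.items():
                values[f"beta_{p}_{cov}"] = val
        for name, val in values.items():
            rse = self.rse.get(name, np.nan)
            se = abs(val) * rse / 100.0 if np.isfinite(rse) else np.nan
            # Wald interval on the estimation (log) scale for positive parameters
            if val > 0 and np.isfinite(se):
                lo, hi = val * np.exp(-1.96 * rse / 100.0), val * np.exp(1.96 * rse / 100.0)
            elif np.isfinite(se):
                lo, hi = val - 1.96 * se, val + 1.96 * se
            else:
                lo = hi = np.nan
            rows.append(dict(parameter=name, estimate=val, ci_lo=lo, ci_hi=hi, rse_pct=rse,
                             ci_kind="wald"))
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# packed data representation

class _Packed:
    """Array view of a TrialDataset for vectorised likelihood evaluation."""

    def __init__(self, data: TrialDataset, blq: str):
        if blq not in ("discard", "censored"):
            raise ConfigError("blq policy must be 'discard' or 'censored'")
        ids = sorted({s.id for s in data.subjects})
        self.ids = ids
        self.n = len(ids)
        index = {sid: i for i, sid in enumerate(ids)}

        obs = [o for o in data.observations if not (blq == "discard" and o.blq)]
        # canonical order: estimates become invariant to input row permutation
        obs.sort(key=lambda o: (o.subject_id, o.time, o.conc))
        self.t = np.array([o.time for o in obs])
        self.y = np.array([o.conc for o in obs])
        self.sub = np.array([index[o.subject_id] for o in obs], dtype=np.int64)
        self.is_blq = np.array([o.blq for o in obs], dtype=bool)
        self.lloq = np.array([o.lloq for o in obs])
        self.m = len(obs)
        self.n_obs_per_subject = np.bincount(self.sub, minlength=self.n)

        per = {i: [] for i in range(self.n)}
        for d in data.doses:
            per[index[d.subject_id]].append(d)
        dmax = max(len(v) for v in per.values())
        self.d_time = np.zeros((self.n, dmax))
        self.d_amt = np.zeros((self.n, dmax))
        self.d_sc = np.zeros((self.n, dmax), dtype=bool)
        self.d_mask = np.zeros((self.n, dmax), dtype=bool)
        for i, dose_list in per.items():
            for j, d in enumerate(sorted(dose_list, key=lambda x: x.time)):
                self.d_time[i, j] = d.time
                self.d_amt[i, j] = d.amount
                self.d_sc[i, j] = d.route == "SC"
                self.d_mask[i, j] = True
        self.has_sc = self.d_sc.any(axis=1)

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Predicted concentration for every observation.

        ``phi``: (n, 6) internal-scale parameters per subject
        (log CL, log Vc, log Q, log Vp, log ka, logit F).
        """
        CL = np.exp(phi[:, 0]); Vc = np.exp(phi[:, 1])
        Q = np.exp(phi[:, 2]); Vp = np.exp(phi[:, 3])
        ka = np.exp(phi[:, 4]); F = expit(phi[:, 5])
        k10 = CL / Vc; k12 = Q / Vc; k21 = Q / Vp
        s = k10 + k12 + k21
        root = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        a = 0.5 * (s + root)
        b = 0.5 * (s - root)
        denom = np.maximum(a - b, 1e-12)
        # IV coefficients (amount scale, divided by Vc at the end)
        iv_a = (a - k21) / denom
        iv_b = (k21 - b) / denom
        # SC coefficients, ka nudged off the alpha/beta poles
        scale = np.maximum(np.maximum(a, b), ka)
        near = np.minimum(np.abs(ka - a), np.abs(ka - b)) < 1e-10 * scale
        ka = np.where(near, ka * (1.0 + 1e-7), ka)
        sc_a = ka * (k21 - a) / ((ka - a) * (b - a))
        sc_b = ka * (k21 - b) / ((ka - b) * (a - b))
        sc_k = ka * (k21 - ka) / ((a - ka) * (b - ka))

        sub = self.sub
        c = np.zeros(self.m)
        for d in range(self.d_time.shape[1]):
            td = self.d_time[sub, d]
            tau = self.t - td
            active = self.d_mask[sub, d] & (tau >= 0)
            if not np.any(active):
                continue
            tau = tau[active]
            si = sub[active]
            amt = self.d_amt[si, d]
            ea = np.exp(-a[si] * tau)
            eb = np.exp(-b[si] * tau)
            iv_part = iv_a[si] * ea + iv_b[si] * eb
            sc_part = F[si] * (sc_a[si] * ea + sc_b[si] * eb + sc_k[si] * np.exp(-ka[si] * tau))
            contrib = amt / Vc[si] * np.where(self.d_sc[si, d], sc_part, iv_part)
            c[active] += contrib
        return c

    def obs_loglik(self, c: np.ndarray, sigma_add: float, sigma_prop: float) -> np.ndarray:
        """Per-observation log-likelihood (censored rows use the normal CDF)."""
        v = sigma_add**2 + (sigma_prop * c) ** 2
        v = np.maximum(v, 1e-12)
        ll = -0.5 * (_LOG2PI + np.log(v) + (self.y - c) ** 2 / v)
        if np.any(self.is_blq):
            sd = np.sqrt(v)
            ll = np.where(self.is_blq, log_ndtr((self.lloq - c) / sd), ll)
        return ll

    def subject_loglik(self, phi: np.ndarray, sigma_add: float, sigma_prop: float) -> np.ndarray:
        c = self.predict(phi)
        return np.bincount(self.sub, weights=self.obs_loglik(c, sigma_add, sigma_prop),
                           minlength=self.n)


def _nearest_psd(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    sym = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < floor:
        warnings.warn("random-effect covariance update was not positive definite; "
                      "projected to the nearest PSD matrix")
        vals = np.maximum(vals, floor)
        sym = (vecs * vals) @ vecs.T
    return sym


def _two_stage_init(packed: _Packed) -> PopPKParams:
    """Naive two-stage initial values: per-subject non-compartmental summaries
    pooled by medians.  Crude but inside SAEM's basin of attraction."""
    vcs, cls_iv, auc_dn_iv, auc_dn_sc = [], [], [], []
    for i in range(packed.n):
        sel = packed.sub == i
        if sel.sum() < 3 or packed.d_mask[i].sum() != 1:
            continue
        t = packed.t[sel]; y = np.maximum(packed.y[sel], 1e-6)
        order = np.argsort(t); t, y = t[order], y[order]
        amt = packed.d_amt[i, 0]
        # terminal slope from the last three points
        A = np.vstack([np.ones(3), t[-3:]]).T
        coef, *_ = np.linalg.lstsq(A, np.log(y[-3:]), rcond=None)
        lam = max(-coef[1], 1e-3)
        auc = np.trapezoid(y, t) + y[-1] / lam
        if packed.has_sc[i]:
            auc_dn_sc.append(auc / amt)
        else:
            vcs.append(amt / y[0])
            cls_iv.append(amt / auc)
            auc_dn_iv.append(auc / amt)
    cl0 = float(np.median(cls_iv)) if cls_iv else 0.2
    vc0 = float(np.median(vcs)) if vcs else 5.0
    f0 = 0.5
    if auc_dn_iv and auc_dn_sc:
        f0 = float(np.clip(np.median(auc_dn_sc) / np.median(auc_dn_iv), 0.05, 0.95))
    omega = np.diag(np.full(4, 0.3**2))
    return PopPKParams(
        fixed=StructuralParams(CL=cl0, Vc=vc0, Q=cl0, Vp=vc0, F=f0, ka=0.3),
        omega=omega, sigma_add=0.5, sigma_prop=0.25,
    )


class SAEMFitter(BaseEstimator):
    """SAEM estimator for the two-compartment population model.

    Parameters
    ----------
    n_chains, n_explore, n_smooth, n_kernel
        Number of parallel MCMC chains, exploration iterations (step size 1),
        smoothing iterations (step size k^-0.7) and Metropolis sweeps per
        iteration.  Defaults converge comfortably at cohort sizes around 150.
    seed
        Required; all randomness flows from it.
    blq
        "discard" drops below-LLoQ records (default; the fine assay's LLoQ is
        orders of magnitude below typical levels), "censored" uses the normal
        CDF (M3) likelihood contribution.
    anneal
        Exploration-phase floor factor on the variance-component updates
        (simulated annealing, prevents premature variance collapse).
    covariate_design
        Optional mapping parameter name -> (n, k) design matrix (rows in
        sorted-subject-id order) extending the fixed effects with covariate
        coefficients; used by the covariate-model module.
    aux_sd
        Fixed auxiliary SD for the no-variability parameters ka and F inside
        the MCMC kernel.
    """

    def __init__(self, n_chains: int = 3, n_explore: int = 400, n_smooth: int = 200,
                 n_kernel: int = 2, seed: Optional[int] = None, blq: str = "discard",
                 anneal: float = 0.95, init: Optional[PopPKParams] = None,
                 covariate_design: Optional[dict] = None, compute_rse: bool = True,
                 aux_sd: float = 0.10):
        self.n_chains = n_chains
        self.n_explore = n_explore
        self.n_smooth = n_smooth
        self.n_kernel = n_kernel
        self.seed = seed
        self.blq = blq
        self.anneal = anneal
        self.init = init
        self.covariate_design = covariate_design
        self.compute_rse = compute_rse
        self.aux_sd = aux_sd

    # -- internals --------------------------------------------------------

    def _mu_matrix(self, theta0: np.ndarray, betas: dict[str, np.ndarray],
                   packed: _Packed) -> np.ndarray:
        mu = np.tile(theta0, (packed.n, 1))
        for j, name in enumerate(_PARAM_NAMES):
            design = (self.covariate_design or {}).get(name)
            if design is not None and betas.get(name) is not None:
                mu[:, j] += np.asarray(design, dtype=float) @ betas[name]
        return mu

    def fit(self, data: TrialDataset, y=None) -> "SAEMFitter":
        if self.seed is None:
            raise ConfigError("SAEMFitter requires an explicit seed for reproducibility")
        packed = _Packed(data, self.blq)
        enough = np.sum(packed.n_obs_per_subject >= 2)
        if packed.n < 2 or enough < 2:
            raise ConfigError("need at least 2 subjects with at least 2 observations each")
        rng = np.random.default_rng(self.seed)
        init = self.init if self.init is not None else _two_stage_init(packed)

        theta0 = init.mu_log()  # length 6
        betas = {
            name: np.zeros(np.asarray(d).shape[1])
            for name, d in (self.covariate_design or {}).items()
        }
        omega = _nearest_psd(init.omega.copy(), floor=1e-4)  # keep invertible
        sig = np.array([max(init.sigma_add, 1e-3), max(init.sigma_prop, 1e-3)])
        aux2 = self.aux_sd**2

        C, n, m = self.n_chains, packed.n, packed.m
        mu = self._mu_matrix(theta0, betas, packed)
        phi = np.tile(mu, (C, 1, 1))  # (C, n, 6)
        steps = np.full(6, 0.4)
        acc_smooth = np.full(6, 0.3)

        s_phi = np.zeros((n, 6))
        s_outer = np.zeros((4, 4))
        s_r2 = np.zeros(m)
        s_c2 = np.zeros(m)
        gauss = ~packed.is_blq

        trace_rows = []
        K1, K2 = self.n_explore, self.n_smooth
        score_window = min(100, K2)
        score_sum = None
        score_count = 0
        cond_sum = np.zeros((n, 4))
        cond_count = 0
        cond_samples = []

        def sigma_objective(x: np.ndarray) -> float:
            s1, s2 = np.exp(x)
            v = s1**2 + s2**2 * s_c2[gauss]
            return float(np.sum(np.log(v) + s_r2[gauss] / v))

        for k in range(K1 + K2):
            exploring = k < K1
            gamma = 1.0 if exploring else (k - K1 + 1) ** -0.7
            omega_inv = np.linalg.inv(omega)

            # E-step: Metropolis-within-Gibbs sweeps, vectorised across subjects
            stat_phi = np.zeros((n, 6))
            stat_outer = np.zeros((4, 4))
            stat_r2 = np.zeros(m)
            stat_c2 = np.zeros(m)
            acc_iter = np.zeros(6)
            for c_idx in range(C):
                ph = phi[c_idx]
                ll = packed.subject_loglik(ph, sig[0], sig[1])
                eta4 = ph[:, :4] - mu[:, :4]
                lp = -0.5 * np.einsum("ij,jk,ik->i", eta4, omega_inv, eta4)
                lp -= 0.5 * ((ph[:, 4] - mu[:, 4]) ** 2 + (ph[:, 5] - mu[:, 5]) ** 2) / aux2
                for _ in range(self.n_kernel):
                    for j in range(6):
                        prop = ph.copy()
                        prop[:, j] = ph[:, j] + steps[j] * rng.standard_normal(n)
                        ll_p = packed.subject_loglik(prop, sig[0], sig[1])
                        eta4p = prop[:, :4] - mu[:, :4]
                        lp_p = -0.5 * np.einsum("ij,jk,ik->i", eta4p, omega_inv, eta4p)
                        lp_p -= 0.5 * ((prop[:, 4] - mu[:, 4]) ** 2
                                       + (prop[:, 5] - mu[:, 5]) ** 2) / aux2
                        accept = np.log(rng.random(n)) < (ll_p + lp_p) - (ll + lp)
                        ph[accept] = prop[accept]
                        ll = np.where(accept, ll_p, ll)
                        lp = np.where(accept, lp_p, lp)
                        acc_iter[j] += accept.mean()
                phi[c_idx] = ph
                stat_phi += ph
                e4 = ph[:, :4] - mu[:, :4]
                stat_outer += e4.T @ e4 / n
                pred = packed.predict(ph)
                stat_r2 += (packed.y - pred) ** 2
                stat_c2 += pred**2
            stat_phi /= C
            stat_outer /= C
            stat_r2 /= C
            stat_c2 /= C
            acc_iter /= C * self.n_kernel

            # proposal adaptation (exploration only)
            acc_smooth = 0.9 * acc_smooth + 0.1 * acc_iter
            if exploring:
                steps *= np.exp(0.2 * (acc_smooth - 0.3))
                steps = np.clip(steps, 1e-3, 2.0)

            # stochastic-approximation smoothing
            s_phi += gamma * (stat_phi - s_phi)
            s_outer += gamma * (stat_outer - s_outer)
            s_r2 += gamma * (stat_r2 - s_r2)
            s_c2 += gamma * (stat_c2 - s_c2)

            # M-step: fixed effects (+ covariate coefficients)
            for j in range(6):
                name = _PARAM_NAMES[j] if j < 4 else None
                design = (self.covariate_design or {}).get(name) if name else None
                if design is not None:
                    X = np.column_stack([np.ones(n), np.asarray(design, dtype=float)])
                    coef, *_ = np.linalg.lstsq(X, s_phi[:, j], rcond=None)
                    theta0[j] = coef[0]
                    betas[name] = coef[1:]
                else:
                    theta0[j] = s_phi[:, j].mean()
            mu = self._mu_matrix(theta0, betas, packed)

            # M-step: omega with annealing floor during exploration
            omega_hat = 0.5 * (s_outer + s_outer.T)
            if exploring:
                d_hat = np.maximum(np.diag(omega_hat), 1e-8)
                d_floor = np.maximum(d_hat, self.anneal * np.diag(omega))
                scale = np.sqrt(d_floor / d_hat)
                omega_hat = omega_hat * np.outer(scale, scale)
            omega = _nearest_psd(omega_hat, floor=1e-8)

            # M-step: residual error by direct 2-parameter maximisation
            res = minimize(sigma_objective, np.log(np.maximum(sig, 1e-8)),
                           method="Nelder-Mead",
                           options=dict(maxiter=60, xatol=1e-4, fatol=1e-6))
            sig_hat = np.exp(res.x)
            if exploring:
                sig_hat = np.sqrt(np.maximum(sig_hat**2, self.anneal * sig**2))
            sig = np.maximum(sig_hat, 1e-8)

            if not (np.all(np.isfinite(theta0)) and np.all(np.isfinite(omega))
                    and np.all(np.isfinite(sig))):
                raise EstimationError(
                    f"SAEM diverged at iteration {k}; trace:\n{pd.DataFrame(trace_rows)}"
                )

            trace_rows.append(dict(
                iteration=k, phase="explore" if exploring else "smooth",
                CL=float(np.exp(theta0[0])), Vc=float(np.exp(theta0[1])),
                Q=float(np.exp(theta0[2])), Vp=float(np.exp(theta0[3])),
                ka=float(np.exp(theta0[4])), F=float(expit(theta0[5])),
                omega_CL=float(np.sqrt(omega[0, 0])), omega_Vc=float(np.sqrt(omega[1, 1])),
                omega_Q=float(np.sqrt(omega[2, 2])), omega_Vp=float(np.sqrt(omega[3, 3])),
                sigma_add=float(sig[0]), sigma_prop=float(sig[1]),
            ))

            # conditional summaries and Fisher-score accumulation near the end
            if k >= K1 + K2 - score_window:
                eta4_all = phi[:, :, :4] - mu[None, :, :4]
                cond_sum += eta4_all.mean(axis=0)
                cond_count += 1
                if cond_count % 5 == 0:
                    cond_samples.append(phi[0, :, :4] - mu[:, :4])
                if self.compute_rse:
                    sc = self._score_matrix(packed, phi, mu, omega, sig, betas, aux2)
                    score_sum = sc if score_sum is None else score_sum + sc
                    score_count += 1

        self.ids_ = packed.ids
        self.theta0_ = theta0
        self.betas_ = betas
        self.params_ = PopPKParams(
            fixed=StructuralParams(
                CL=float(np.exp(theta0[0])), Vc=float(np.exp(theta0[1])),
                Q=float(np.exp(theta0[2])), Vp=float(np.exp(theta0[3])),
                F=float(expit(theta0[5])), ka=float(np.exp(theta0[4])),
            ),
            omega=omega, sigma_add=float(sig[0]), sigma_prop=float(sig[1]),
        )
        self.trace_ = pd.DataFrame(trace_rows)
        self.eta_mean_ = cond_sum / max(cond_count, 1)
        self.cond_samples_ = np.array(cond_samples) if cond_samples else None
        self.rse_ = {}
        if self.compute_rse and score_count:
            self.rse_ = self._rse_from_scores(score_sum / score_count, betas)
        self._packed = packed
        return self

    # -- uncertainty ------------------------------------------------------

    def _score_names(self, betas: dict[str, np.ndarray]) -> list[str]:
        names = list(_PARAM_NAMES)
        for p, b in betas.items():
            names += [f"beta_{p}_{i}" for i in range(len(b))]
        names += ["ka", "F", "omega_CL", "omega_Vc", "omega_Q", "omega_Vp",
                  "sigma_add", "sigma_prop"]
        return names

    def _score_matrix(self, packed, phi, mu, omega, sig, betas, aux2) -> np.ndarray:
        """Per-subject conditional score vectors (Fisher identity), chain-averaged."""
        n = packed.n
        P = len(self._score_names(betas))
        out = np.zeros((n, P))
        omega_inv = np.linalg.inv(omega)
        omega_d = np.sqrt(np.diag(omega))
        for c_idx in range(phi.shape[0]):
            ph = phi[c_idx]
            eta4 = ph[:, :4] - mu[:, :4]
            G = eta4 @ omega_inv  # d l / d mu
            col = 0
            out[:, col:col + 4] += G
            col += 4
            for p_name, b in betas.items():
                j = _PARAM_NAMES.index(p_name)
                design = np.asarray(self.covariate_design[p_name], dtype=float)
                out[:, col:col + len(b)] += G[:, [j]] * design
                col += len(b)
            out[:, col] += (ph[:, 4] - mu[:, 4]) / aux2  # ka (log scale)
            out[:, col + 1] += (ph[:, 5] - mu[:, 5]) / aux2  # F (logit scale)
            col += 2
            # omega SDs: marginal-normal approximation
            out[:, col:col + 4] += (eta4**2 - omega_d[None, :] ** 2) / omega_d[None, :] ** 3
            col += 4
            pred = packed.predict(ph)
            v = np.maximum(sig[0] ** 2 + (sig[1] * pred) ** 2, 1e-12)
            common = np.where(~packed.is_blq, (packed.y - pred) ** 2 / v**2 - 1.0 / v, 0.0)
            out[:, col] += np.bincount(packed.sub, weights=sig[0] * common, minlength=n)
            out[:, col + 1] += np.bincount(packed.sub, weights=sig[1] * pred**2 * common,
                                           minlength=n)
        return out / phi.shape[0]

    def _rse_from_scores(self, scores: np.ndarray, betas) -> dict[str, float]:
        names = self._score_names(betas)
        fim = scores.T @ scores
        cov = np.linalg.pinv(fim)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        est = self.params_
        rse = {}
        for name, s in zip(names, se):
            if name in ("CL", "Vc", "Q", "Vp", "ka"):
                rse[name] = 100.0 * s  # SE on log scale ~ CV of natural parameter
            elif name == "F":
                rse[name] = 100.0 * s * (1.0 - est.fixed.F)  # delta method, logit scale
            elif name.startswith("omega_"):
                idx = ["omega_CL", "omega_Vc", "omega_Q", "omega_Vp"].index(name)
                rse[name] = 100.0 * s / np.sqrt(est.omega[idx, idx])
            elif name == "sigma_add":
                rse[name] = 100.0 * s / est.sigma_add
            elif name == "sigma_prop":
                rse[name] = 100.0 * s / est.sigma_prop
            else:  # covariate coefficient: RSE relative to its own magnitude
                p, i = name.rsplit("_", 1)
                val = self.betas_[p.replace("beta_", "")][int(i)]
                rse[name] = 100.0 * s / abs(val) if val != 0 else np.inf
        return rse

    def to_fit(self, covariate_names: Optional[dict[str, list[str]]] = None) -> PopPKFit:
        coefs = {}
        for p, b in self.betas_.items():
            names = (covariate_names or {}).get(p, [str(i) for i in range(len(b))])
            coefs[p] = {nm: float(v) for nm, v in zip(names, b)}
        return PopPKFit(
            estimate=self.params_, rse=self.rse_, loglik=getattr(self, "loglik_", None),
            trace=self.trace_, seed=self.seed, ids=list(self.ids_),
            eta_mean=self.eta_mean_, cond_samples=self.cond_samples_,
            covariate_coefficients=coefs,
        )


@dataclass
class SAEMConfig:
    """Convenience bundle of SAEM settings (mirrors SAEMFitter arguments)."""

    n_chains: int = 3
    n_explore: int = 400
    n_smooth: int = 200
    n_kernel: int = 2
    seed: int = 0
    blq: str = "discard"
    compute_rse: bool = True


def fit_saem(data: TrialDataset, init: Optional[PopPKParams] = None,
             config: Optional[SAEMConfig] = None) -> PopPKFit:
    """Fit the base population model by SAEM; see :class:`SAEMFitter`."""
    cfg = config or SAEMConfig()
    fitter = SAEMFitter(
        n_chains=cfg.n_chains, n_explore=cfg.n_explore, n_smooth=cfg.n_smooth,
        n_kernel=cfg.n_kernel, seed=cfg.seed, blq=cfg.blq, init=init,
        compute_rse=cfg.compute_rse,
    ).fit(data)
    return fitter.to_fit()


# --------------------------------------------------------------------------
# empirical Bayes and marginal likelihood

def _subject_arrays(packed: _Packed, i: int):
    sel = packed.sub == i
    doses = []
    for j in range(packed.d_time.shape[1]):
        if packed.d_mask[i, j]:
            doses.append((packed.d_time[i, j], packed.d_amt[i, j],
                          "SC" if packed.d_sc[i, j] else "IV"))
    return packed.t[sel], packed.y[sel], packed.is_blq[sel], packed.lloq[sel], doses


def _subject_negll(eta4: np.ndarray, mu6: np.ndarray, omega_inv: np.ndarray,
                   t, y, blq, lloq, doses, pop: PopPKParams) -> float:
    """Negative conditional log-posterior (up to the prior normalising constant)."""
    from .pk_model import superpose

    phi = mu6.copy()
    phi[:4] += eta4
    p = StructuralParams(
        CL=float(np.exp(phi[0])), Vc=float(np.exp(phi[1])), Q=float(np.exp(phi[2])),
        Vp=float(np.exp(phi[3])), F=float(expit(phi[5])), ka=float(np.exp(phi[4])),
    )
    c = np.atleast_1d(superpose(p, doses, t)) if len(t) else np.zeros(0)
    v = np.maximum(pop.sigma_add**2 + (pop.sigma_prop * c) ** 2, 1e-12)
    ll = -0.5 * (_LOG2PI + np.log(v) + (y - c) ** 2 / v)
    if np.any(blq):
        ll = np.where(blq, log_ndtr((lloq - c) / np.sqrt(v)), ll)
    prior = -0.5 * float(eta4 @ omega_inv @ eta4)
    return -(float(ll.sum()) + prior)


def eb_estimates(fit: PopPKFit, data: TrialDataset, blq: str = "discard"
                 ) -> list[IndividualParams]:
    """Empirical-Bayes (MAP) individual parameters given a population fit.

    Per subject, the mode of the conditional posterior of the 4 log random
    effects is found by quasi-Newton maximisation of log-prior +
    log-likelihood; ka and F are held at the population values.  A subject
    with no observations shrinks fully to the population values.  Results are
    returned in the dataset's subject order.
    """
    pop = fit.estimate
    packed = _Packed(data, blq)
    omega_inv = np.linalg.inv(pop.omega)
    mu6 = pop.mu_log()
    warm = {sid: eta for sid, eta in zip(fit.ids or [], fit.eta_mean if fit.eta_mean is not None
                                         else [])}
    by_id: dict[str, IndividualParams] = {}
    for i, sid in enumerate(packed.ids):
        t, y, isblq, lloq, doses = _subject_arrays(packed, i)
        if len(t) == 0:
            eta = np.zeros(4)
        else:
            x0 = np.asarray(warm.get(sid, np.zeros(4)), dtype=float)
            res = minimize(
                _subject_negll, x0, args=(mu6, omega_inv, t, y, isblq, lloq, doses, pop),
                method="L-BFGS-B", options=dict(maxiter=200),
            )
            if not res.success and not np.all(np.isfinite(res.x)):
                warnings.warn(f"EB optimisation failed for subject {sid}; "
                              "falling back to the conditional mean estimate")
                eta = x0
            else:
                eta = res.x
        theta = np.exp(mu6[:4] + eta)
        by_id[sid] = IndividualParams(sid, *map(float, theta))
    order = [s.id for s in data.subjects]
    return [by_id[sid] for sid in order]


def importance_loglik(fit: PopPKFit, data: TrialDataset, seed: int = 0,
                      n_is: int = 300, blq: str = "discard",
                      covariate_design: Optional[dict] = None,
                      covariate_betas: Optional[dict] = None) -> float:
    """Marginal log-likelihood by importance sampling around the conditional modes.

    Per subject the proposal is a scaled Gaussian at the MAP of the 4 log
    random effects with covariance from a finite-difference Hessian.  The
    small auxiliary ka/F variances used inside SAEM integrate out exactly
    (their prior is shared between any two models compared), so only the 4
    structural random effects are integrated.
    """
    pop = fit.estimate
    packed = _Packed(data, blq)
    omega_inv = np.linalg.inv(pop.omega)
    _sign, logdet = np.linalg.slogdet(pop.omega)
    log_prior_const = -0.5 * (4 * _LOG2PI + logdet)
    mu6_base = pop.mu_log()
    rng = np.random.default_rng(seed)
    total = 0.0
    for i, sid in enumerate(packed.ids):
        t, y, isblq, lloq, doses = _subject_arrays(packed, i)
        mu6 = mu6_base.copy()
        if covariate_design and covariate_betas:
            for j, name in enumerate(_PARAM_NAMES):
                if name in covariate_design and name in covariate_betas:
                    mu6[j] += float(np.asarray(covariate_design[name], dtype=float)[i]
                                    @ np.asarray(covariate_betas[name], dtype=float))
        if len(t) == 0:
            continue  # marginal contribution of a subject with no data is 1
        args = (mu6, omega_inv, t, y, isblq, lloq, doses, pop)
        res = minimize(_subject_negll, np.zeros(4), args=args, method="L-BFGS-B",
                       options=dict(maxiter=200))
        eta_map = res.x
        # central-difference Hessian of the negative log posterior
        h = 1e-3
        H = np.zeros((4, 4))
        f0 = _subject_negll(eta_map, *args)
        for a in range(4):
            for b in range(a, 4):
                ea, eb = np.eye(4)[a] * h, np.eye(4)[b] * h
                fpp = _subject_negll(eta_map + ea + eb, *args)
                fpm = _subject_negll(eta_map + ea - eb, *args)
                fmp = _subject_negll(eta_map - ea + eb, *args)
                fmm = _subject_negll(eta_map - ea - eb, *args)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        vals, vecs = np.linalg.eigh(0.5 * (H + H.T))
        vals = np.maximum(vals, 1e-4)
        cov = (vecs / vals) @ vecs.T * 1.3**2  # inflated Laplace proposal
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_is, 4))
        draws = eta_map[None, :] + z @ L.T
        log_q = (-0.5 * np.sum(z**2, axis=1) - np.sum(np.log(np.diag(L)))
                 - 2.0 * _LOG2PI)
        log_joint = np.array([-(_subject_negll(d, *args)) for d in draws]) + log_prior_const
        total += float(logsumexp(log_joint - log_q) - np.log(n_is))
    return total
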