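"""Covariate-adjusted population model and stepwise covariate search.

Approach 2 of the analysis: the population means of the structural parameters
are extended with covariate effects — continuous covariates (weight,
creatinine clearance, age) enter as power models on the log scale centred at
the cohort median, binary covariates (sex, coadministration) as exponentiated
indicator effects.  Model building approximates the COSSAC strategy:
correlations between the conditional random-effect samples of the base fit
and the unused covariates screen candidate (parameter, covariate) pairs for a
forward step; included effects are pruned by likelihood-ratio tests.  The
exact commercial algorithm is proprietary; this documented approximation
(correlation screening at p_in, LRT pruning at p_out) follows its published
outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EstimationError
from .poppk import (
    PopPKFit,
    PopPKParams,
    SAEMConfig,
    SAEMFitter,
    importance_loglik,
)
from .trial_data import TrialDataset

__all__ = ["CovariateModelSpec", "fit_covariate_model", "stepwise_search",
           "build_design", "DEFAULT_CANDIDATES"]

_PK_PARAMS = ("CL", "Vc", "Q", "Vp")

#: Candidate covariates considered by the search (matching Approach 2).
DEFAULT_CANDIDATES = ("coadministration", "weight", "crcl", "age", "sex")


@dataclass
class CovariateModelSpec:
    """Mapping parameter -> covariates entering its population mean.

    Continuous covariates contribute ``beta * log(x / median(x))`` to the log
    parameter (a power model); ``sex`` (female=1) and ``coadministration``
    (combination=1) contribute ``beta * indicator``.
    """

    effects: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, covs in self.effects.items():
            if p not in _PK_PARAMS:
                raise ConfigError(f"unknown PK parameter {p!r}")
            if len(set(covs)) != len(covs):
                raise ConfigError(f"covariate repeated on parameter {p!r}")

    def pairs(self) -> list[tuple[str, str]]:
        return [(p, c) for p, covs in self.effects.items() for c in covs]

    def with_pair(self, param: str, cov: str) -> "CovariateModelSpec":
        eff = {p: list(c) for p, c in self.effects.items()}
        eff.setdefault(param, []).append(cov)
        return CovariateModelSpec(eff)

    def without_pair(self, param: str, cov: str) -> "CovariateModelSpec":
        eff = {p: [c for c in covs if c != cov] for p, covs in self.effects.items()}
        return CovariateModelSpec({p: c for p, c in eff.items() if c})


def _covariate_column(data: TrialDataset, name: str, ids: Sequence[str]) -> np.ndarray:
    subj = data.subject_map()
    if name == "coadministration":
        return np.array([1.0 if subj[s].group == "combination" else 0.0 for s in ids])
    if name == "sex":
        return np.array([1.0 if subj[s].sex == "female" else 0.0 for s in ids])
    if name == "weight":
        x = np.array([subj[s].weight for s in ids])
    elif name == "crcl":
        x = np.array([subj[s].crcl for s in ids])
    elif name == "age":
        x = np.array([subj[s].age for s in ids])
    else:
        raise ConfigError(f"unknown covariate {name!r}")
    return np.log(x / np.median(x))


def build_design(data: TrialDataset, spec: CovariateModelSpec
                 ) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Per-parameter design matrices in sorted-subject-id order."""
    ids = sorted(s.id for s in data.subjects)
    design, names = {}, {}
    for p, covs in spec.effects.items():
        cols = [_covariate_column(data, c, ids) for c in covs]
        X = np.column_stack(cols)
        for (i, a), (j, b) in [((i, a), (j, b)) for i, a in enumerate(covs)
                               for j, b in enumerate(covs) if i < j]:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > 0.95:
                raise ConfigError(f"covariates {a!r} and {b!r} on {p!r} are collinear "
                                  f"(|r|={abs(r):.3f})")
        design[p] = X
        names[p] = list(covs)
    return design, names


def fit_covariate_model(data: TrialDataset, spec: CovariateModelSpec,
                        init: Optional[PopPKParams] = None,
                        config: Optional[SAEMConfig] = None) -> PopPKFit:
    """Fit the covariate-adjusted population model with the same SAEM engine.

    An empty spec reduces exactly to the base model (identical draws for the
    same seed).  Returns a fit whose ``covariate_coefficients`` carry the
    estimated effect sizes on the log-parameter scale.
    """
    cfg = config or SAEMConfig()
    design, names = build_design(data, spec)
    fitter = SAEMFitter(
        n_chains=cfg.n_chains, n_explore=cfg.n_explore, n_smooth=cfg.n_smooth,
        n_kernel=cfg.n_kernel, seed=cfg.seed, blq=cfg.blq, init=init,
        covariate_design=design or None, compute_rse=cfg.compute_rse,
    ).fit(data)
    return fitter.to_fit(covariate_names=names)


@dataclass
class SearchConfig:
    p_in: float = 0.01
    p_out: float = 0.05
    max_iter: int = 6
    n_is: int = 200  # importance-sampling draws for the LRT log-likelihoods
    saem: SAEMConfig = field(default_factory=SAEMConfig)


def _screen_pvalues(fit: PopPKFit, data: TrialDataset,
                    candidates: Sequence[str],
                    current: CovariateModelSpec) -> list[tuple[float, str, str]]:
    """Correlation tests between conditional random-effect means and covariates."""
    ids = fit.ids
    eta = fit.eta_mean
    if eta is None:
        raise EstimationError("base fit carries no conditional random-effect summaries")
    used = set(current.pairs())
    out = []
    for j, p in enumerate(_PK_PARAMS):
        for c in candidates:
            if (p, c) in used:
                continue
            x = _covariate_column(data, c, ids)
            if np.std(x) < 1e-12:
                continue
            r, pval = stats.pearsonr(eta[:, j], x)
            out.append((float(pval), p, c))
    return sorted(out)


def _loglik(fit: PopPKFit, data: TrialDataset, spec: CovariateModelSpec,
            cfg: SearchConfig) -> float:
    design, _ = build_design(data, spec)
    betas = {p: np.array([fit.covariate_coefficients[p][c] for c in spec.effects[p]])
             for p in spec.effects}
    return importance_loglik(fit, data, seed=cfg.saem.seed, n_is=cfg.n_is,
                             blq=cfg.saem.blq, covariate_design=design or None,
                             covariate_betas=betas or None)


def stepwise_search(data: TrialDataset, candidates: Sequence[str] = DEFAULT_CANDIDATES,
                    config: Optional[SearchConfig] = None,
                    base_fit: Optional[PopPKFit] = None
                    ) -> tuple[CovariateModelSpec, PopPKFit]:
    """Forward/backward covariate model building.

    Forward step: among unused (parameter, covariate) pairs, test the Pearson
    correlation between each parameter's conditional random-effect means and
    the covariate; add the pair with the smallest p-value below ``p_in`` and
    refit.  Backward step: drop any included effect whose likelihood-ratio
    p-value exceeds ``p_out``.  Iterates to a fixed point (or ``max_iter``,
    with a warning on oscillation).  Deterministic given the SAEM seed.

    Returns the selected spec and the corresponding fit (the base fit when
    the spec is empty).
    """
    cfg = config or SearchConfig()
    spec = CovariateModelSpec({})
    fit = base_fit if base_fit is not None else fit_covariate_model(data, spec,
                                                                    config=cfg.saem)
    if not candidates:
        return spec, fit
    loglik = None  # computed lazily, only when a backward step needs it
    seen: set[frozenset] = set()
    for _ in range(cfg.max_iter):
        changed = False
        key = frozenset(spec.pairs())
        if key in seen:
            warnings.warn("covariate search oscillated; stopping at the current model")
            break
        seen.add(key)

        screened = _screen_pvalues(fit, data, candidates, spec)
        if screened and screened[0][0] < cfg.p_in:
            _, p_add, c_add = screened[0]
            cand_spec = spec.with_pair(p_add, c_add)
            try:
                cand_fit = fit_covariate_model(data, cand_spec, config=cfg.saem)
            except ConfigError:  # collinear with an existing effect
                cand_fit = None
            if cand_fit is not None:
                spec, fit = cand_spec, cand_fit
                loglik = None
                changed = True

        # backward: LRT-prune weak effects
        for p, c in list(spec.pairs()):
            reduced = spec.without_pair(p, c)
            red_fit = fit_covariate_model(data, reduced, config=cfg.saem)
            if loglik is None:
                loglik = _loglik(fit, data, spec, cfg)
            ll_red = (_loglik(red_fit, data, reduced, cfg) if reduced.pairs()
                      else importance_loglik(red_fit, data, seed=cfg.saem.seed,
                                             n_is=cfg.n_is, blq=cfg.saem.blq))
            lrt = max(2.0 * (loglik - ll_red), 0.0)
            p_lrt = float(stats.chi2.sf(lrt, df=1))
            if p_lrt > cfg.p_out:
                spec, fit = reduced, red_fit
                loglik = ll_red
                changed = True
        if not changed:
            break
    return spec, fit
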