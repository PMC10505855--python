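"""Posterior and prior-predictive sampling for the joint foraging model.

Sampling uses emcee's affine-invariant ensemble MCMC over the packed
parameter vector (positive GP scales and the income-latent sd are sampled on
the log scale, with the Jacobian included in the target density).  Several
independent ensembles play the role of chains for split-R-hat and effective
sample size, computed with arviz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az
import emcee

from .domain import CovariateScaling, DomainError, TripTable
from .model import (
    ModelLayout,
    ModelParams,
    PriorConfig,
    TripDesign,
    build_design,
    joint_log_density,
    log_jacobian_packed,
    sample_params_from_prior,
    softmax_probs,
)

__all__ = [
    "FitConfig",
    "PosteriorDraws",
    "DiagnosticsReport",
    "PriorPredictive",
    "fit_posterior",
    "sample_prior_predictive",
    "diagnostics",
]

logger = logging.getLogger("patchchoice")


@dataclass
class FitConfig:
    """MCMC settings.

    ``n_chains`` independent ensembles of ``n_walkers`` walkers each run
    ``n_warmup`` discarded steps plus enough further steps to collect
    ``n_draws`` retained draws per chain.  ``target_accept`` is kept for
    interface compatibility; the ensemble sampler has no step-size tuning
    knob, so it is unused.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0
    n_walkers: Optional[int] = None  # default: 2 * n_params + 2 (rounded even)

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_draws"):
            if getattr(self, name) < 1:
                raise DomainError(f"{name} must be a positive integer")
        if not 0 < self.target_accept < 1:
            raise DomainError("target_accept must lie in (0, 1)")


@dataclass
class DiagnosticsReport:
    """Per-parameter split-R-hat and bulk ESS with pass/fail flags."""

    param_names: list
    rhat: Optional[np.ndarray]
    ess: Optional[np.ndarray]
    rhat_threshold: float
    ess_threshold: float
    degenerate: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        if self.rhat is None or self.ess is None:
            return False
        ok = np.ones(len(self.param_names), dtype=bool)
        finite = np.isfinite(self.rhat) & np.isfinite(self.ess)
        ok &= ~finite | ((self.rhat <= self.rhat_threshold) & (self.ess >= self.ess_threshold))
        # degenerate (constant) parameters are flagged, not failed
        return bool(ok.all())

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "rhat_threshold": self.rhat_threshold,
            "ess_threshold": self.ess_threshold,
            "max_rhat": float(np.nanmax(self.rhat)) if self.rhat is not None and np.isfinite(self.rhat).any() else None,
            "min_ess": float(np.nanmin(self.ess)) if self.ess is not None and np.isfinite(self.ess).any() else None,
            "degenerate_parameters": list(self.degenerate),
            "notes": list(self.notes),
            "per_parameter": {
                name: {
                    "rhat": None if self.rhat is None or not np.isfinite(self.rhat[i]) else float(self.rhat[i]),
                    "ess": None if self.ess is None or not np.isfinite(self.ess[i]) else float(self.ess[i]),
                }
                for i, name in enumerate(self.param_names)
            },
        }


@dataclass
class PosteriorDraws:
    """Posterior sample with (chain, draw) indexing.

    ``draws`` holds packed parameter vectors (sampler coordinates; positive
    scales as logs), shape (n_chains, n_draws, n_params).  ``scaling`` is the
    covariate standardization active at fit time, needed to translate
    raw-valued counterfactual profiles.
    """

    layout: ModelLayout
    draws: np.ndarray
    scaling: Optional[CovariateScaling] = None
    report: Optional[DiagnosticsReport] = None
    warn: bool = False

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != self.layout.n_params:
            raise DomainError(
                f"draws must have shape (chains, draws, {self.layout.n_params})"
            )

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def param_names(self) -> list:
        return self.layout.param_names()

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def params_at(self, chain: int, draw: int) -> ModelParams:
        return ModelParams.unpack(self.draws[chain, draw], self.layout)

    def iter_params(self):
        for vec in self.flat():
            yield ModelParams.unpack(vec, self.layout)

    @staticmethod
    def from_params(params_list, layout: ModelLayout, scaling=None) -> "PosteriorDraws":
        """Wrap explicit parameter sets as a single-chain draws object."""
        arr = np.stack([p.pack() for p in params_list])[None, :, :]
        return PosteriorDraws(layout=layout, draws=arr, scaling=scaling)

    def to_frame(self) -> pd.DataFrame:
        names = self.param_names
        flat = self.flat()
        chain = np.repeat(np.arange(self.n_chains), self.n_draws)
        draw = np.tile(np.arange(self.n_draws), self.n_chains)
        df = pd.DataFrame(flat, columns=names)
        df.insert(0, "draw", draw)
        df.insert(0, "chain", chain)
        return df


# ---------------------------------------------------------------------------
# Posterior sampling
# ---------------------------------------------------------------------------

def _log_posterior(vec: np.ndarray, design: TripDesign, priors: PriorConfig,
                   layout: ModelLayout) -> float:
    if not np.all(np.isfinite(vec)):
        return -np.inf
    params = ModelParams.unpack(vec, layout)
    lp = joint_log_density(design, params, priors)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_jacobian_packed(vec, layout)


def fit_posterior(
    trips: TripTable,
    priors: PriorConfig,
    config: FitConfig,
    layout: Optional[ModelLayout] = None,
    scaling: Optional[CovariateScaling] = None,
) -> PosteriorDraws:
    """Sample the joint posterior of the choice and success models.

    ``trips`` must be standardized.  If any trip has missing income, the
    layout enables the household income latent and it is sampled jointly.
    Convergence is checked against the config thresholds; failures set the
    WARN flag on the returned draws (and are logged), never silently ignored.
    """
    if not trips.is_standardized:
        raise DomainError("standardize_covariates must be applied before fitting")
    if layout is None:
        has_missing = bool(trips.df["income_std"].isna().any())
        layout = ModelLayout(patches=trips.catalog.names, impute_income=has_missing)
    design = build_design(trips, layout)
    for s in range(len(layout.seasons)):
        if not (design.season_idx == s).any():
            raise DomainError(f"no trips observed in season {layout.seasons[s]!r}")

    ndim = layout.n_params
    nwalkers = config.n_walkers or (2 * ndim + 2)
    nwalkers += nwalkers % 2
    keep_steps = max(1, int(np.ceil(config.n_draws / nwalkers)))
    total_steps = config.n_warmup + keep_steps

    chains = []
    center = ModelParams.zeros(layout).pack()
    for c in range(config.n_chains):
        chain_seed = (config.seed + 1000003 * (c + 1)) % (2**31)
        rng = np.random.default_rng(chain_seed)
        p0 = center[None, :] + 0.1 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, _log_posterior, args=(design, priors, layout)
        )
        sampler.random_state = np.random.RandomState(chain_seed).get_state()
        sampler.run_mcmc(p0, total_steps, progress=False)
        post = sampler.get_chain(discard=config.n_warmup)  # (steps, walkers, ndim)
        flat = post.reshape(-1, ndim)
        chains.append(flat[: config.n_draws])
        logger.info(
            "chain %d: %d steps, mean acceptance %.3f",
            c,
            total_steps,
            float(np.mean(sampler.acceptance_fraction)),
        )
    draws = np.stack(chains)

    out = PosteriorDraws(layout=layout, draws=draws, scaling=scaling)
    report = diagnostics(out, rhat_threshold=config.rhat_threshold,
                         ess_threshold=config.ess_threshold)
    out.report = report
    out.warn = not report.passed
    if out.warn:
        logger.warning(
            "WARN: convergence diagnostics failed (max R-hat %s, min ESS %s)",
            report.to_dict()["max_rhat"],
            report.to_dict()["min_ess"],
        )
    return out


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
) -> DiagnosticsReport:
    """Split-R-hat and bulk ESS per scalar parameter.

    With a single chain R-hat is undefined and reported as such; constant
    parameters are flagged degenerate rather than raising.
    """
    names = draws.param_names
    arr = draws.draws  # (chain, draw, dim)
    degenerate = [
        names[i] for i in range(arr.shape[2]) if np.allclose(arr[:, :, i], arr[0, 0, i])
    ]
    notes = []
    if draws.n_chains < 2:
        notes.append("single chain: R-hat undefined")
        return DiagnosticsReport(
            param_names=names,
            rhat=None,
            ess=None,
            rhat_threshold=rhat_threshold,
            ess_threshold=ess_threshold,
            degenerate=degenerate,
            notes=notes,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(arr)
        rhat = az.rhat(ds)["x"].values.astype(float)
        ess = az.ess(ds, method="bulk")["x"].values.astype(float)
    if degenerate:
        notes.append(f"{len(degenerate)} constant parameter(s) flagged degenerate")
    return DiagnosticsReport(
        param_names=names,
        rhat=rhat,
        ess=ess,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
        degenerate=degenerate,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Prior predictive
# ---------------------------------------------------------------------------

@dataclass
class PriorPredictive:
    """Per-draw prior-predictive probabilities for one covariate profile."""

    choice_probs: np.ndarray  # (n_draws, K)
    success_probs: np.ndarray  # (n_draws,)
    patches: tuple

    def summary(self, mass: float = 0.89) -> dict:
        from .predict import hpd_interval  # deferred: predictions sit above inference

        out = {"patches": {}, "success": {}}
        for k, name in enumerate(self.patches):
            lo, hi = hpd_interval(self.choice_probs[:, k], mass)
            out["patches"][name] = {
                "mean": float(self.choice_probs[:, k].mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
            }
        lo, hi = hpd_interval(self.success_probs, mass)
        out["success"] = {"mean": float(self.success_probs.mean()), "hpd_lo": lo, "hpd_hi": hi}
        return out


def sample_prior_predictive(
    priors: PriorConfig,
    template,
    n_draws: int,
    seed: int,
    layout: Optional[ModelLayout] = None,
    scaling: Optional[CovariateScaling] = None,
) -> PriorPredictive:
    """Push a covariate profile through parameters drawn from the prior.

    ``template`` is a HarvesterProfile; with the default symmetric priors
    the Monte-Carlo mean of each patch's choice probability is 1/K and the
    mean success probability is 1/2 (a symmetry consequence, independent of
    the prior scales).
    """
    from .predict import profile_push  # deferred import, see PriorPredictive

    layout = layout or ModelLayout.default()
    rng = np.random.default_rng(seed)
    K = layout.n_patches
    choice = np.empty((n_draws, K))
    succ = np.empty(n_draws)
    for i in range(n_draws):
        params = sample_params_from_prior(priors, layout, rng)
        probs, succ_k = profile_push(params, template, scaling)
        choice[i] = probs
        # trip-level success marginalized over the patch the profile would choose
        succ[i] = float(probs @ succ_k) if np.isfinite(succ_k).all() else np.nan
    return PriorPredictive(choice_probs=choice, success_probs=succ, patches=layout.patches)
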