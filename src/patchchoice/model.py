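"""Joint model of foraging patch choice and within-patch harvest success.

Patch choice for trip i is categorical over the K catalog patches with
probabilities softmax(eta_i), where each patch's linear predictor combines a
season-varying intercept, a gender-varying intercept, a latent
Gaussian-process age effect over four ordered age classes, and linear terms
in standardized household income, sharing-network in-/out-degree and trip
group size.  Harvest success given the chosen patch is Bernoulli with a
logistic link on an analogous linear predictor (patch enters through the
intercepts; the success model shares one age effect and one coefficient
vector across patches).  One household's missing income is handled by a
latent standardized income shared across that household's trips, with a
Normal(income_mu, income_sigma) prior and Normal(0.5, 1) / half-Cauchy(0, 1)
hyper-priors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .domain import (
    AGE_CLASSES,
    GENDERS,
    SEASONS,
    DomainError,
    PatchCatalog,
    TripRecord,
    TripTable,
)

__all__ = [
    "ModelLayout",
    "ModelParams",
    "PriorSpec",
    "PriorConfig",
    "TripDesign",
    "build_design",
    "linear_predictor_choice",
    "softmax_probs",
    "choice_loglik",
    "gp_age_cov",
    "success_linpred",
    "success_prob",
    "success_loglik",
    "log_prior",
    "joint_log_density",
    "sample_params_from_prior",
]

DEFAULT_COVARIATES = ("income_std", "in_degree_std", "out_degree_std", "group_size_std")

#: Integer positions of the ordered age classes on the GP input axis.
AGE_POSITIONS = np.array([1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# Layout and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelLayout:
    """Shapes of the parameter blocks.

    The default layout is the full model (7 patches, 2 seasons, 2 genders,
    4 age classes, 4 covariates in each sub-model).  Reduced layouts — fewer
    patches, no gender/age blocks, choice model only — are used for oracle
    tests and scenario experiments; empty tuples disable the block.
    """

    patches: tuple[str, ...]
    seasons: tuple[str, ...] = SEASONS
    genders: tuple[str, ...] = GENDERS
    age_classes: tuple[str, ...] = AGE_CLASSES
    choice_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    success_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_success: bool = True
    impute_income: bool = False

    @staticmethod
    def default(catalog: Optional[PatchCatalog] = None, *, impute_income: bool = False) -> "ModelLayout":
        cat = catalog or PatchCatalog.default()
        return ModelLayout(patches=cat.names, impute_income=impute_income)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def has_gender(self) -> bool:
        return len(self.genders) > 0

    @property
    def has_age(self) -> bool:
        return len(self.age_classes) > 0

    @property
    def age_positions(self) -> np.ndarray:
        return AGE_POSITIONS[: len(self.age_classes)]

    def block_shapes(self) -> dict[str, tuple[int, ...]]:
        """Ordered map of flat-packing block name -> array shape."""
        K, S = self.n_patches, len(self.seasons)
        shapes: dict[str, tuple[int, ...]] = {"alpha_choice": (K, S)}
        if self.has_gender:
            shapes["gamma_choice"] = (K, len(self.genders))
        if self.choice_covariates:
            shapes["beta_choice"] = (K, len(self.choice_covariates))
        if self.has_age:
            shapes["age_effect_choice"] = (K, len(self.age_classes))
            shapes["log_gp_choice"] = (3,)
        if self.include_success:
            shapes["alpha_succ"] = (K, S)
            if self.has_gender:
                shapes["gamma_succ"] = (K, len(self.genders))
            if self.success_covariates:
                shapes["beta_succ"] = (len(self.success_covariates),)
            if self.has_age:
                shapes["age_effect_succ"] = (len(self.age_classes),)
                shapes["log_gp_succ"] = (3,)
        if self.impute_income:
            shapes["income_mu"] = (1,)
            shapes["log_income_sigma"] = (1,)
            shapes["income_miss"] = (1,)
        return shapes

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for s in self.block_shapes().values())

    def param_names(self) -> list[str]:
        names = []
        for block, shape in self.block_shapes().items():
            if shape == (1,):
                names.append(block)
            elif len(shape) == 1:
                names.extend(f"{block}[{i}]" for i in range(shape[0]))
            else:
                names.extend(
                    f"{block}[{i},{j}]" for i in range(shape[0]) for j in range(shape[1])
                )
        return names


@dataclass
class ModelParams:
    """One full set of model parameters (one posterior draw, or a truth).

    GP hyperparameters are stored on their natural positive scale
    (``gp_* = (eta_sq, rho_sq, sigma_sq)``); the flat packing used by the
    sampler carries their logs.
    """

    layout: ModelLayout
    alpha_choice: np.ndarray
    beta_choice: Optional[np.ndarray] = None
    gamma_choice: Optional[np.ndarray] = None
    age_effect_choice: Optional[np.ndarray] = None
    gp_choice: Optional[np.ndarray] = None  # (eta_sq, rho_sq, sigma_sq)
    alpha_succ: Optional[np.ndarray] = None
    gamma_succ: Optional[np.ndarray] = None
    beta_succ: Optional[np.ndarray] = None
    age_effect_succ: Optional[np.ndarray] = None
    gp_succ: Optional[np.ndarray] = None
    income_mu: Optional[float] = None
    income_sigma: Optional[float] = None
    income_miss: Optional[float] = None

    @staticmethod
    def zeros(layout: ModelLayout) -> "ModelParams":
        """All intercepts/coefficients/age effects zero; unit GP scales."""
        K, S = layout.n_patches, len(layout.seasons)
        p = ModelParams(layout=layout, alpha_choice=np.zeros((K, S)))
        if layout.has_gender:
            p.gamma_choice = np.zeros((K, len(layout.genders)))
        if layout.choice_covariates:
            p.beta_choice = np.zeros((K, len(layout.choice_covariates)))
        if layout.has_age:
            p.age_effect_choice = np.zeros((K, len(layout.age_classes)))
            p.gp_choice = np.ones(3)
        if layout.include_success:
            p.alpha_succ = np.zeros((K, S))
            if layout.has_gender:
                p.gamma_succ = np.zeros((K, len(layout.genders)))
            if layout.success_covariates:
                p.beta_succ = np.zeros(len(layout.success_covariates))
            if layout.has_age:
                p.age_effect_succ = np.zeros(len(layout.age_classes))
                p.gp_succ = np.ones(3)
        if layout.impute_income:
            p.income_mu = 0.0
            p.income_sigma = 1.0
            p.income_miss = 0.0
        return p

    # -- flat packing (sampler coordinates: positive scales as logs) --------

    def pack(self) -> np.ndarray:
        parts = []
        for block, shape in self.layout.block_shapes().items():
            if block == "log_gp_choice":
                parts.append(np.log(self.gp_choice))
            elif block == "log_gp_succ":
                parts.append(np.log(self.gp_succ))
            elif block == "income_mu":
                parts.append(np.array([self.income_mu]))
            elif block == "log_income_sigma":
                parts.append(np.array([np.log(self.income_sigma)]))
            elif block == "income_miss":
                parts.append(np.array([self.income_miss]))
            else:
                parts.append(np.asarray(getattr(self, block), dtype=float).ravel())
        return np.concatenate(parts)

    @staticmethod
    def unpack(vector: np.ndarray, layout: ModelLayout) -> "ModelParams":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (layout.n_params,):
            raise ValueError(f"expected vector of length {layout.n_params}, got {vector.shape}")
        p = ModelParams(layout=layout, alpha_choice=np.empty((layout.n_patches, len(layout.seasons))))
        pos = 0
        for block, shape in layout.block_shapes().items():
            size = int(np.prod(shape))
            chunk = vector[pos : pos + size].reshape(shape)
            pos += size
            if block == "log_gp_choice":
                p.gp_choice = np.exp(chunk)
            elif block == "log_gp_succ":
                p.gp_succ = np.exp(chunk)
            elif block == "income_mu":
                p.income_mu = float(chunk[0])
            elif block == "log_income_sigma":
                p.income_sigma = float(np.exp(chunk[0]))
            elif block == "income_miss":
                p.income_miss = float(chunk[0])
            else:
                setattr(p, block, chunk.copy())
        return p


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

_FAMILIES = ("normal", "half_cauchy")


@dataclass(frozen=True)
class PriorSpec:
    family: str
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise DomainError(f"unknown prior family {self.family!r}")
        if self.scale < 0:
            raise DomainError("prior scale must be nonnegative")


@dataclass(frozen=True)
class PriorConfig:
    """Prior for each parameter block.

    Defaults are weakly informative and symmetric about zero for the choice
    block: Normal(0, 1) intercepts and coefficients, half-Cauchy(0, 1) GP
    scales, and the income-imputation hyper-priors Normal(0.5, 1) for the
    latent mean and half-Cauchy(0, 1) for the latent sd.  Symmetry of the
    choice-block priors is what pins the prior-predictive patch-choice mean
    at 1/K and the prior-predictive success mean at 1/2.
    """

    intercept: PriorSpec = PriorSpec("normal", 0.0, 1.0)
    coefficient: PriorSpec = PriorSpec("normal", 0.0, 1.0)
    gp_scale: PriorSpec = PriorSpec("half_cauchy", 0.0, 1.0)
    income_mu: PriorSpec = PriorSpec("normal", 0.5, 1.0)
    income_sigma: PriorSpec = PriorSpec("half_cauchy", 0.0, 1.0)

    @staticmethod
    def default() -> "PriorConfig":
        return PriorConfig()

    @staticmethod
    def from_dict(data: dict) -> "PriorConfig":
        kwargs = {}
        for block, spec in data.items():
            if block not in ("intercept", "coefficient", "gp_scale", "income_mu", "income_sigma"):
                raise DomainError(f"unknown prior block {block!r}")
            try:
                kwargs[block] = PriorSpec(spec["family"], float(spec["loc"]), float(spec["scale"]))
            except (KeyError, TypeError) as exc:
                raise DomainError(f"prior block {block!r} malformed: needs family/loc/scale") from None
        return PriorConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PriorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return PriorConfig.from_dict(data or {})

    def to_dict(self) -> dict:
        out = {}
        for block in ("intercept", "coefficient", "gp_scale", "income_mu", "income_sigma"):
            s: PriorSpec = getattr(self, block)
            out[block] = {"family": s.family, "loc": s.loc, "scale": s.scale}
        return out


# ---------------------------------------------------------------------------
# Design arrays
# ---------------------------------------------------------------------------

@dataclass
class TripDesign:
    """Trip table unpacked into integer-coded index arrays for the model."""

    layout: ModelLayout
    patch_idx: np.ndarray
    season_idx: np.ndarray
    gender_idx: np.ndarray
    age_idx: np.ndarray
    Xc: np.ndarray  # (n, n_choice_cov) standardized; NaN income where missing
    Xs: np.ndarray
    y: np.ndarray  # success flags
    missing_income: np.ndarray  # boolean mask

    @property
    def n(self) -> int:
        return len(self.patch_idx)

    def _fill_income(self, X: np.ndarray, covariates: tuple[str, ...], params: ModelParams) -> np.ndarray:
        if not self.missing_income.any() or "income_std" not in covariates:
            return X
        if params.income_miss is None:
            raise DomainError("missing income present but no imputation latent is bound")
        X = X.copy()
        X[self.missing_income, covariates.index("income_std")] = params.income_miss
        return X

    def choice_X(self, params: ModelParams) -> np.ndarray:
        return self._fill_income(self.Xc, self.layout.choice_covariates, params)

    def success_X(self, params: ModelParams) -> np.ndarray:
        return self._fill_income(self.Xs, self.layout.success_covariates, params)


def build_design(trips: TripTable, layout: ModelLayout) -> TripDesign:
    """Index-code a standardized trip table against a model layout."""
    if not trips.is_standardized:
        raise DomainError("trips must be standardized before building a design")
    df = trips.df
    patch_idx = np.array([layout.patches.index(p) for p in df["patch"]])
    season_idx = np.array([layout.seasons.index(s) for s in df["season"]])
    gender_idx = (
        np.array([layout.genders.index(g) for g in df["gender"]])
        if layout.has_gender
        else np.zeros(len(df), dtype=int)
    )
    age_idx = (
        np.array([layout.age_classes.index(a) for a in df["age_class"]])
        if layout.has_age
        else np.zeros(len(df), dtype=int)
    )
    Xc = df[list(layout.choice_covariates)].to_numpy(dtype=float) if layout.choice_covariates else np.zeros((len(df), 0))
    Xs = df[list(layout.success_covariates)].to_numpy(dtype=float) if layout.success_covariates else np.zeros((len(df), 0))
    missing = df["income_std"].isna().to_numpy() if "income_std" in df.columns else np.zeros(len(df), bool)
    return TripDesign(
        layout=layout,
        patch_idx=patch_idx,
        season_idx=season_idx,
        gender_idx=gender_idx,
        age_idx=age_idx,
        Xc=Xc,
        Xs=Xs,
        y=df["success"].to_numpy(dtype=float),
        missing_income=missing,
    )


def _record_design(record: TripRecord, layout: ModelLayout) -> TripDesign:
    cov = {
        "income_std": record.income_std,
        "in_degree_std": record.in_degree_std,
        "out_degree_std": record.out_degree_std,
        "group_size_std": record.group_size_std,
    }
    Xc = np.array([[cov[c] for c in layout.choice_covariates]]) if layout.choice_covariates else np.zeros((1, 0))
    Xs = np.array([[cov[c] for c in layout.success_covariates]]) if layout.success_covariates else np.zeros((1, 0))
    return TripDesign(
        layout=layout,
        patch_idx=np.array([layout.patches.index(record.patch)]),
        season_idx=np.array([layout.seasons.index(record.season)]),
        gender_idx=np.array([layout.genders.index(record.gender)]) if layout.has_gender else np.zeros(1, int),
        age_idx=np.array([layout.age_classes.index(record.age_class)]) if layout.has_age else np.zeros(1, int),
        Xc=Xc,
        Xs=Xs,
        y=np.array([float(record.success)]),
        missing_income=np.isnan(Xc[:, layout.choice_covariates.index("income_std")])
        if "income_std" in layout.choice_covariates
        else np.zeros(1, bool),
    )


# ---------------------------------------------------------------------------
# Linear predictors and link functions
# ---------------------------------------------------------------------------

def choice_linpred_matrix(design: TripDesign, params: ModelParams) -> np.ndarray:
    """(n, K) matrix of patch-choice linear predictors."""
    layout = design.layout
    eta = params.alpha_choice.T[design.season_idx]  # (n, K)
    if layout.has_gender:
        eta = eta + params.gamma_choice.T[design.gender_idx]
    if layout.has_age:
        eta = eta + params.age_effect_choice.T[design.age_idx]
    if layout.choice_covariates:
        eta = eta + design.choice_X(params) @ params.beta_choice.T
    return eta


def linear_predictor_choice(record: TripRecord, params: ModelParams) -> np.ndarray:
    """Patch-choice linear predictor for a single trip record.

    eta_k = alpha[k, season] + gamma[k, gender] + age_effect[k, age]
            + sum_c beta[k, c] * x_c
    """
    design = _record_design(record, params.layout)
    if design.missing_income.any() and params.income_miss is None:
        raise DomainError("record has missing income and no imputation latent is bound")
    return choice_linpred_matrix(design, params)[0]


def softmax_probs(eta: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Numerically stable softmax over the last axis.

    ``mask`` is a boolean array over patches (True = available); masked-out
    patches get probability exactly 0.  Stable for |eta| up to ~700 via
    max-subtraction.
    """
    eta = np.asarray(eta, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DomainError("softmax mask excludes every patch")
        eta = np.where(mask, eta, -np.inf)
    shifted = eta - np.max(eta, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        w = np.exp(shifted)
    w = np.where(np.isneginf(shifted), 0.0, w)
    return w / np.sum(w, axis=-1, keepdims=True)


def choice_loglik(trips, params: ModelParams, mask: Optional[np.ndarray] = None) -> float:
    """Categorical log-likelihood of the observed patch choices.

    ``trips`` is a standardized TripTable or a prebuilt TripDesign.  With a
    patch mask, observing a masked patch is an impossible observation and
    raises.
    """
    design = trips if isinstance(trips, TripDesign) else build_design(trips, params.layout)
    if mask is not None and not np.asarray(mask, bool)[design.patch_idx].all():
        raise DomainError("observed patch is excluded by the mask")
    eta = choice_linpred_matrix(design, params)
    logp = _log_softmax(eta, mask)
    return float(logp[np.arange(design.n), design.patch_idx].sum())


def _log_softmax(eta: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if mask is not None:
        eta = np.where(np.asarray(mask, bool), eta, -np.inf)
    m = np.max(eta, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        lse = m + np.log(np.sum(np.exp(eta - m), axis=-1, keepdims=True))
    return eta - lse


def gp_age_cov(eta_sq: float, rho_sq: float, sigma_sq: float,
               age_positions: Optional[Sequence[float]] = None) -> np.ndarray:
    """Squared-exponential covariance over ordered age-class positions.

    K[a,b] = eta_sq * exp(-rho_sq * d(a,b)^2) + 1{a=b} * sigma_sq, with d the
    absolute distance between integer age positions (1..4 by default).
    eta_sq is the marginal variance, rho_sq the inverse squared length-scale,
    sigma_sq an independent (jitter) variance ensuring positive-definiteness.
    """
    if not (eta_sq > 0 and rho_sq >= 0 and sigma_sq > 0):
        raise DomainError("GP hyperparameters must be positive (rho_sq nonnegative)")
    pos = np.asarray(age_positions if age_positions is not None else AGE_POSITIONS, dtype=float)
    d2 = (pos[:, None] - pos[None, :]) ** 2
    return eta_sq * np.exp(-rho_sq * d2) + sigma_sq * np.eye(len(pos))


def success_linpred(design: TripDesign, params: ModelParams) -> np.ndarray:
    layout = design.layout
    k = design.patch_idx
    theta = params.alpha_succ[k, design.season_idx]
    if layout.has_gender:
        theta = theta + params.gamma_succ[k, design.gender_idx]
    if layout.has_age:
        theta = theta + params.age_effect_succ[design.age_idx]
    if layout.success_covariates:
        theta = theta + design.success_X(params) @ params.beta_succ
    return theta


def success_prob(record: TripRecord, params: ModelParams) -> float:
    """P(successful harvest) for a single trip given its chosen patch."""
    design = _record_design(record, params.layout)
    if design.missing_income.any() and params.income_miss is None:
        raise DomainError("record has missing income and no imputation latent is bound")
    return float(expit(success_linpred(design, params)[0]))


def success_loglik(trips, params: ModelParams) -> float:
    """Bernoulli log-likelihood of the harvest-success flags.

    Computed as y*theta - log(1 + exp(theta)) in log-sum-exp form, finite for
    any finite linear predictor.
    """
    design = trips if isinstance(trips, TripDesign) else build_design(trips, params.layout)
    theta = success_linpred(design, params)
    # log p = -log(1+e^{-theta}) for y=1, -log(1+e^{theta}) for y=0
    return float(-np.logaddexp(0.0, np.where(design.y > 0.5, -theta, theta)).sum())


# ---------------------------------------------------------------------------
# Priors and joint density
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _normal_logpdf(x, loc, scale) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * _LOG_2PI - np.log(scale) - 0.5 * ((x - loc) / scale) ** 2))


def _half_cauchy_logpdf(x, scale) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)))


def _mvn_logpdf_zero_mean(rows: np.ndarray, cov: np.ndarray) -> float:
    """Sum of MVN(0, cov) log-densities over the rows of ``rows``."""
    rows = np.atleast_2d(rows)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    m = cov.shape[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    z = np.linalg.solve(L, rows.T)  # (m, nrows)
    quad = float(np.sum(z**2))
    nrows = rows.shape[0]
    return -0.5 * (nrows * (m * _LOG_2PI + logdet) + quad)


def log_prior(params: ModelParams, priors: PriorConfig) -> float:
    """Log prior density of a full parameter set.

    Includes the GP multivariate-normal prior on the age-effect blocks given
    their hyperparameters; the hyperparameters themselves (and the income
    latent sd) carry half-Cauchy priors evaluated on their natural scale
    (the sampling-coordinate Jacobian lives in the posterior density, not
    here).  Returns -inf for out-of-support values.
    """
    layout = params.layout
    for spec in (priors.intercept, priors.coefficient, priors.gp_scale, priors.income_sigma):
        if spec.scale == 0:
            raise DomainError("log_prior requires strictly positive prior scales")
    lp = 0.0
    icp, coef = priors.intercept, priors.coefficient
    lp += _normal_logpdf(params.alpha_choice, icp.loc, icp.scale)
    if layout.has_gender:
        lp += _normal_logpdf(params.gamma_choice, icp.loc, icp.scale)
    if layout.choice_covariates:
        lp += _normal_logpdf(params.beta_choice, coef.loc, coef.scale)
    if layout.has_age:
        if np.any(np.asarray(params.gp_choice) <= 0):
            return -np.inf
        K = gp_age_cov(*params.gp_choice, layout.age_positions)
        lp += _mvn_logpdf_zero_mean(params.age_effect_choice, K)
        lp += _half_cauchy_logpdf(params.gp_choice, priors.gp_scale.scale)
    if layout.include_success:
        lp += _normal_logpdf(params.alpha_succ, icp.loc, icp.scale)
        if layout.has_gender:
            lp += _normal_logpdf(params.gamma_succ, icp.loc, icp.scale)
        if layout.success_covariates:
            lp += _normal_logpdf(params.beta_succ, coef.loc, coef.scale)
        if layout.has_age:
            if np.any(np.asarray(params.gp_succ) <= 0):
                return -np.inf
            Ks = gp_age_cov(*params.gp_succ, layout.age_positions)
            lp += _mvn_logpdf_zero_mean(params.age_effect_succ[None, :], Ks)
            lp += _half_cauchy_logpdf(params.gp_succ, priors.gp_scale.scale)
    if layout.impute_income:
        if params.income_sigma is None or params.income_sigma <= 0:
            return -np.inf
        lp += _normal_logpdf(params.income_mu, priors.income_mu.loc, priors.income_mu.scale)
        lp += _half_cauchy_logpdf(params.income_sigma, priors.income_sigma.scale)
        lp += _normal_logpdf(params.income_miss, params.income_mu, params.income_sigma)
    return lp


def joint_log_density(trips, params: ModelParams, priors: PriorConfig) -> float:
    """log prior + choice log-likelihood + success log-likelihood."""
    design = trips if isinstance(trips, TripDesign) else build_design(trips, params.layout)
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    ll = choice_loglik(design, params)
    if design.layout.include_success:
        ll += success_loglik(design, params)
    return lp + ll


def log_jacobian_packed(vector: np.ndarray, layout: ModelLayout) -> float:
    """Log Jacobian of the log-transform for positive scales in the packing.

    The sampler works on log(eta_sq) etc.; the density on those coordinates
    is prior(natural) * exp(sum of the log-coordinates).
    """
    jac = 0.0
    pos = 0
    for block, shape in layout.block_shapes().items():
        size = int(np.prod(shape))
        if block in ("log_gp_choice", "log_gp_succ", "log_income_sigma"):
            jac += float(np.sum(vector[pos : pos + size]))
        pos += size
    return jac


def sample_params_from_prior(priors: PriorConfig, layout: ModelLayout,
                             rng: np.random.Generator) -> ModelParams:
    """Draw one full parameter set from the prior.

    Age-effect blocks are drawn from their GP prior given freshly drawn
    hyperparameters.  Zero prior scales are honoured as point masses (used
    for degenerate prior-predictive checks).
    """

    def normal(spec: PriorSpec, shape):
        if spec.scale == 0:
            return np.full(shape, spec.loc)
        return rng.normal(spec.loc, spec.scale, size=shape)

    def half_cauchy(spec: PriorSpec, shape):
        if spec.scale == 0:
            return np.zeros(shape)
        return np.abs(spec.loc + spec.scale * rng.standard_cauchy(size=shape))

    def gp_block(n_rows: int):
        hyper = half_cauchy(priors.gp_scale, (3,))
        if np.all(hyper == 0):
            return np.zeros((n_rows, len(layout.age_classes))), np.zeros(3)
        hyper = np.maximum(hyper, 1e-12)
        K = gp_age_cov(*hyper, layout.age_positions)
        L = np.linalg.cholesky(K)
        z = rng.standard_normal((n_rows, len(layout.age_classes)))
        return z @ L.T, hyper

    K_, S = layout.n_patches, len(layout.seasons)
    p = ModelParams(layout=layout, alpha_choice=normal(priors.intercept, (K_, S)))
    if layout.has_gender:
        p.gamma_choice = normal(priors.intercept, (K_, len(layout.genders)))
    if layout.choice_covariates:
        p.beta_choice = normal(priors.coefficient, (K_, len(layout.choice_covariates)))
    if layout.has_age:
        p.age_effect_choice, p.gp_choice = gp_block(K_)
    if layout.include_success:
        p.alpha_succ = normal(priors.intercept, (K_, S))
        if layout.has_gender:
            p.gamma_succ = normal(priors.intercept, (K_, len(layout.genders)))
        if layout.success_covariates:
            p.beta_succ = normal(priors.coefficient, (len(layout.success_covariates),))
        if layout.has_age:
            block, p.gp_succ = gp_block(1)
            p.age_effect_succ = block[0]
    if layout.impute_income:
        p.income_mu = float(normal(priors.income_mu, ()))
        p.income_sigma = float(half_cauchy(priors.income_sigma, ()))
        sd = p.income_sigma
        p.income_miss = float(p.income_mu + sd * rng.standard_normal()) if sd > 0 else p.income_mu
    return p
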