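"""Phylogenetic linear mixed models for dive duration, written from scratch.

The model for record ``r`` of species ``s(r)`` is

    ln t_r = x_rᵀ β + u_phylo[s(r)] + u_species[s(r)] + ε_r

with ``u_phylo ~ N(0, σ²_p C)`` (``C`` the unit-diagonal Brownian-motion
matrix of the phylogeny), ``u_species ~ N(0, σ²_s I)`` capturing
species-level repeated-measures correlation not explained by the tree, and
``ε ~ N(0, σ²_e I)``.  Marginally ``y ~ N(Xβ, V)`` with

    V = σ²_p Z C Zᵀ + σ²_s Z Zᵀ + σ²_e I,

``Z`` the record→species incidence matrix.  Two fitters are provided:

* :func:`fit_reml` — restricted maximum likelihood, profiling β out of the
  likelihood and optimizing the variance components numerically; β̂ is then
  the GLS estimate with Wald 95% intervals.
* :func:`fit_gibbs` — a Gibbs sampler with a flat prior on β and weak scaled
  inverse-chi-square priors on the variances (scale 1, degree of belief
  0.002, the conventional weak default for this model class); estimates are
  posterior means, intervals the 2.5/97.5 posterior percentiles.

Model fit is summarized by the conditional R² of Nakagawa & Schielzeth:
the share of total variance attributable to fixed plus random effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import norm

from ._util import normalize_species_name
from .data_prep import DiveDataset
from .phylo import Phylogeny, PhyloCovariance, bm_covariance, prune_to_species

__all__ = [
    "ModelDesign",
    "VarianceComponents",
    "Coefficient",
    "FitResult",
    "GibbsPriors",
    "DesignError",
    "build_design",
    "marginal_loglik",
    "fit_reml",
    "fit_gibbs",
    "conditional_r2",
    "fit_result_table_row",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10  # keeps factorizations stable when a component vanishes
_JITTER = 1e-10

ALL_COMPONENTS = ("phylo", "species")


class DesignError(ValueError):
    """The model design is degenerate (rank deficiency, single species, ...)."""


@dataclass(frozen=True)
class VarianceComponents:
    """Variances on the ln-duration scale."""

    sigma2_phylo: float
    sigma2_species: float
    sigma2_resid: float

    def __post_init__(self):
        vals = (self.sigma2_phylo, self.sigma2_species, self.sigma2_resid)
        if any(v < 0 for v in vals):
            raise ValueError("variance components must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one variance component must be positive")

    @property
    def total(self) -> float:
        return self.sigma2_phylo + self.sigma2_species + self.sigma2_resid


@dataclass(frozen=True)
class Coefficient:
    name: str
    estimate: float
    lower95: float
    upper95: float

    def __post_init__(self):
        if not (self.lower95 <= self.estimate <= self.upper95):
            raise ValueError(
                f"interval for {self.name} does not bracket the estimate"
            )


@dataclass(frozen=True)
class FitResult:
    """Coefficients, variance components and fit summary of one model."""

    coefficients: tuple
    varcomp: VarianceComponents
    conditional_r2: float
    n_records: int
    n_species: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def coef(self, name: str) -> Coefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "coefficients": [asdict(c) for c in self.coefficients],
            "varcomp": asdict(self.varcomp),
            "conditional_r2": self.conditional_r2,
            "n_records": self.n_records,
            "n_species": self.n_species,
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class GibbsPriors:
    """Scaled inverse-chi-square priors on each variance (flat prior on β)."""

    scale: float = 1.0
    nu: float = 0.002

    def __post_init__(self):
        if self.scale <= 0 or self.nu <= 0:
            raise ValueError("prior scale and degree of belief must be positive")


@dataclass(frozen=True)
class ModelDesign:
    """Response, fixed-effect matrix and random-effect structure of one fit."""

    response: np.ndarray
    which_response: str
    fixed_matrix: np.ndarray
    fixed_names: tuple
    species_index: np.ndarray
    species_labels: tuple
    phylo_cov: PhyloCovariance

    def __post_init__(self):
        y = np.asarray(self.response, float)
        X = np.asarray(self.fixed_matrix, float)
        idx = np.asarray(self.species_index, int)
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "fixed_matrix", X)
        object.__setattr__(self, "species_index", idx)
        if X.shape[0] != y.shape[0] or idx.shape[0] != y.shape[0]:
            raise DesignError("response, fixed matrix and species map disagree in length")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("fixed-effect matrix is rank deficient")
        if tuple(self.phylo_cov.labels) != tuple(self.species_labels):
            raise DesignError("phylogenetic covariance is not aligned to species")
        if idx.min() < 0 or idx.max() >= len(self.species_labels):
            raise DesignError("species_index out of range")

    @property
    def n_records(self) -> int:
        return len(self.response)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    def incidence(self) -> np.ndarray:
        """Record→species incidence matrix Z (n_records × n_species)."""
        Z = np.zeros((self.n_records, self.n_species))
        Z[np.arange(self.n_records), self.species_index] = 1.0
        return Z


def build_design(
    ds: DiveDataset,
    which_response: str = "median",
    include_temperature: bool = True,
    tree: Phylogeny | None = None,
) -> ModelDesign:
    """Assemble the response, fixed effects and phylogenetic covariance.

    The response is the natural log of the chosen duration column; rows
    missing it are dropped (logged).  Fixed effects are an intercept, ln body
    mass, and (optionally) temperature in °C.  Species absent from the tree
    are dropped with a logged count; the tree is pruned to the species that
    remain and its unit-diagonal Brownian-motion matrix is aligned to them.
    """
    if tree is None:
        raise DesignError("a phylogeny is required")
    col = {"median": "median_dive_min", "max": "max_dive_min"}.get(which_response)
    if col is None:
        raise DesignError(f"which_response must be 'median' or 'max', got {which_response!r}")

    frame = ds.frame
    have = frame[col].notna() & (frame[col] > 0)
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.info("dropped %d records without a %s duration", n_dropped, which_response)
    frame = frame.loc[have]
    if frame.empty:
        raise DesignError("no records carry the requested response")

    tip_by_norm = tree.label_index()
    matched = frame["species"].map(
        lambda s: tip_by_norm.get(normalize_species_name(s))
    )
    missing_mask = matched.isna()
    if missing_mask.any():
        n_sp = frame.loc[missing_mask, "species"].nunique()
        logger.info(
            "dropped %d records of %d species absent from the tree",
            int(missing_mask.sum()), n_sp,
        )
        frame = frame.loc[~missing_mask]
        matched = matched.loc[~missing_mask]
    if frame.empty:
        raise DesignError("no species in the dataset occur in the tree")

    species_labels = tuple(pd.unique(matched))
    if len(species_labels) < 2:
        raise DesignError(
            "at least two species are required: the phylogenetic variance is "
            "unidentifiable from a single species"
        )
    pruned = prune_to_species(tree, species_labels)
    cov = bm_covariance(pruned, normalize=True).subset(species_labels)

    pos = {l: i for i, l in enumerate(species_labels)}
    species_index = matched.map(pos).to_numpy(int)

    y = np.log(frame[col].to_numpy(float))
    cols = [np.ones(len(frame)), np.log(frame["mass_g"].to_numpy(float))]
    names = ["intercept", "ln_mass"]
    if include_temperature:
        cols.append(frame["temp_C"].to_numpy(float))
        names.append("temp_C")
    X = np.column_stack(cols)

    return ModelDesign(
        response=y,
        which_response=which_response,
        fixed_matrix=X,
        fixed_names=tuple(names),
        species_index=species_index,
        species_labels=species_labels,
        phylo_cov=cov,
    )


def _v_parts(design: ModelDesign):
    """Record-level covariance building blocks: Z C Zᵀ and Z Zᵀ."""
    sp = design.species_index
    A = design.phylo_cov.matrix[np.ix_(sp, sp)]
    B = (sp[:, None] == sp[None, :]).astype(float)
    return A, B


def _chol_v(design: ModelDesign, vc: VarianceComponents):
    A, B = _v_parts(design)
    n = design.n_records
    V = vc.sigma2_phylo * A + vc.sigma2_species * B + vc.sigma2_resid * np.eye(n)
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    try:  # retry with jitter before giving up
        return cho_factor(V + _JITTER * np.eye(n), lower=True)
    except np.linalg.LinAlgError as e:
        raise FloatingPointError(
            f"marginal covariance not positive definite (vc={vc})"
        ) from e


def marginal_loglik(
    design: ModelDesign, beta: np.ndarray, vc: VarianceComponents
) -> float:
    """Log density of the response under ``N(Xβ, V)``.

    ``V`` is assembled from the variance components and factorized (Cholesky);
    the matrix is never inverted elementwise.
    """
    beta = np.asarray(beta, float)
    c_and_lower = _chol_v(design, vc)
    r = design.response - design.fixed_matrix @ beta
    alpha = cho_solve(c_and_lower, r)
    logdet = 2.0 * np.sum(np.log(np.diag(c_and_lower[0])))
    n = design.n_records
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ alpha))


def _active_vc(theta: np.ndarray, components) -> VarianceComponents:
    vals = {"phylo": 0.0, "species": 0.0}
    for name, t in zip(components, theta[:-1]):
        vals[name] = float(np.exp(t))
    return VarianceComponents(
        sigma2_phylo=vals["phylo"],
        sigma2_species=vals["species"],
        sigma2_resid=float(np.exp(theta[-1])),
    )


def _gls(design: ModelDesign, vc: VarianceComponents):
    """GLS point estimate, its covariance, and the REML log-likelihood."""
    X, y = design.fixed_matrix, design.response
    c_and_lower = _chol_v(design, vc)
    ViX = cho_solve(c_and_lower, X)
    Viy = cho_solve(c_and_lower, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    cov_beta = np.linalg.inv(XtViX)
    r = y - X @ beta
    quad = float(r @ cho_solve(c_and_lower, r))
    logdet_v = 2.0 * np.sum(np.log(np.diag(c_and_lower[0])))
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise FloatingPointError("XᵀV⁻¹X not positive definite")
    n, p = X.shape
    reml = -0.5 * (logdet_v + logdet_x + quad + (n - p) * np.log(2 * np.pi))
    return beta, cov_beta, float(reml)


def fit_reml(
    design: ModelDesign,
    components: tuple = ALL_COMPONENTS,
    start: VarianceComponents | None = None,
    maxiter: int = 200,
) -> FitResult:
    """Restricted-maximum-likelihood fit of the phylogenetic mixed model.

    The restricted likelihood (fixed effects profiled out) is maximized over
    log variance components with L-BFGS-B; β̂ is the GLS estimate at the
    optimum and 95% intervals are Wald.  ``components`` selects which random
    effects besides the residual enter the model.  Deterministic given the
    design and starting values.
    """
    components = tuple(components)
    for c in components:
        if c not in ALL_COMPONENTS:
            raise ValueError(f"unknown component {c!r}")
    X, y = design.fixed_matrix, design.response
    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = float(np.var(y - X @ ols_beta, ddof=X.shape[1]))
    resid_var = max(resid_var, 1e-6)

    if start is not None:
        init = [getattr(start, f"sigma2_{c}") for c in components]
        init.append(start.sigma2_resid)
        theta0 = np.log(np.maximum(init, _VAR_FLOOR))
    else:
        k = len(components) + 1
        theta0 = np.log(np.full(k, resid_var / k))

    def neg_reml(theta):
        vc = _active_vc(theta, components)
        try:
            _, _, reml = _gls(design, vc)
        except FloatingPointError:
            return 1e12
        return -reml

    bounds = [(np.log(_VAR_FLOOR), np.log(1e6 * resid_var))] * len(theta0)
    res = optimize.minimize(
        neg_reml, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"REML optimizer failed: {res.message}; trace={res}")

    vc = _active_vc(res.x, components)
    beta, cov_beta, reml = _gls(design, vc)
    se = np.sqrt(np.diag(cov_beta))
    z = norm.ppf(0.975)
    coefs = tuple(
        Coefficient(name, float(b), float(b - z * s), float(b + z * s))
        for name, b, s in zip(design.fixed_names, beta, se)
    )
    fit = FitResult(
        coefficients=coefs,
        varcomp=vc,
        conditional_r2=_conditional_r2(beta, vc, design),
        n_records=design.n_records,
        n_species=design.n_species,
        method="reml",
        diagnostics={
            "reml_loglik": reml,
            "n_evaluations": int(res.nfev),
            "converged": bool(res.success),
            "components": list(components),
        },
    )
    return fit


def _ess(draws: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(draws, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # sum adjacent pairs until a pair sum goes nonpositive
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / max(tau, 1.0))


def fit_gibbs(
    design: ModelDesign,
    priors: GibbsPriors | None = None,
    n_iter: int = 13000,
    burn_in: int = 3000,
    thin: int = 10,
    seed: int = 0,
    components: tuple = ALL_COMPONENTS,
    ess_threshold: float = 100.0,
) -> FitResult:
    """Bayesian fit via Gibbs sampling.

    One sweep updates, in turn: β given the random effects (multivariate
    normal under the flat prior), the phylogenetic species effects (joint
    multivariate normal using the precision ``ZᵀZ/σ²_e + C⁻¹/σ²_p``), the
    i.i.d. species effects (independent normals), and each variance from its
    scaled inverse-chi-square full conditional.  Point estimates are posterior
    means of the retained draws; intervals are 2.5/97.5 percentiles.
    Deterministic given ``seed``.  Parameters whose effective sample size
    falls below ``ess_threshold`` trigger a warning in the diagnostics.
    """
    if priors is None:
        priors = GibbsPriors()
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    components = tuple(components)
    use_phylo = "phylo" in components
    use_species = "species" in components

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    X, y = design.fixed_matrix, design.response
    n, p = X.shape
    k = design.n_species
    sp = design.species_index
    counts = np.bincount(sp, minlength=k).astype(float)

    XtX = X.T @ X
    XtX_chol = cho_factor(XtX, lower=True)
    cov_beta_unit = np.linalg.inv(XtX)
    cov_beta_chol = cholesky(cov_beta_unit + _JITTER * np.eye(p), lower=True)

    if use_phylo:
        C = design.phylo_cov.matrix
        Cinv = np.linalg.inv(C + _JITTER * np.eye(k))
        Cinv = 0.5 * (Cinv + Cinv.T)

    beta = np.asarray(np.linalg.lstsq(X, y, rcond=None)[0], float)
    resid_var = max(float(np.var(y - X @ beta)), 1e-4)
    u_p = np.zeros(k)
    u_s = np.zeros(k)
    s2p = resid_var / 3 if use_phylo else 0.0
    s2s = resid_var / 3 if use_species else 0.0
    s2e = resid_var / 3

    nu0, V0 = priors.nu, priors.scale

    def draw_variance(ss: float, m: int) -> float:
        df = nu0 + m
        scale = nu0 * V0 + ss
        return max(scale / rng.chisquare(df), _VAR_FLOOR)

    kept_beta, kept_vc = [], []
    for it in range(n_iter):
        # β | rest
        r = y - u_p[sp] - u_s[sp]
        mean_beta = cho_solve(XtX_chol, X.T @ r)
        beta = mean_beta + np.sqrt(s2e) * (cov_beta_chol @ rng.standard_normal(p))

        fixed = X @ beta
        if use_phylo:
            # u_phylo | rest: precision = diag(counts)/σ²_e + C⁻¹/σ²_p
            r = y - fixed - u_s[sp]
            prec = Cinv / s2p
            prec[np.diag_indices(k)] += counts / s2e
            L = cholesky(prec, lower=True)
            rhs = np.bincount(sp, weights=r, minlength=k) / s2e
            mean_u = cho_solve((L, True), rhs)
            z = rng.standard_normal(k)
            u_p = mean_u + np.linalg.solve(L.T, z)
            s2p = draw_variance(float(u_p @ Cinv @ u_p), k)
        if use_species:
            r = y - fixed - u_p[sp]
            prec_s = counts / s2e + 1.0 / s2s
            mean_s = (np.bincount(sp, weights=r, minlength=k) / s2e) / prec_s
            u_s = mean_s + rng.standard_normal(k) / np.sqrt(prec_s)
            s2s = draw_variance(float(u_s @ u_s), k)
        eps = y - fixed - u_p[sp] - u_s[sp]
        s2e = draw_variance(float(eps @ eps), n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_beta.append(beta.copy())
            kept_vc.append((s2p, s2s, s2e))

    B = np.asarray(kept_beta)
    VC = np.asarray(kept_vc)
    post_mean = B.mean(axis=0)
    lo = np.percentile(B, 2.5, axis=0)
    hi = np.percentile(B, 97.5, axis=0)
    coefs = tuple(
        Coefficient(name, float(m), float(min(l, m)), float(max(h, m)))
        for name, m, l, h in zip(design.fixed_names, post_mean, lo, hi)
    )
    vc = VarianceComponents(
        sigma2_phylo=float(VC[:, 0].mean()) if use_phylo else 0.0,
        sigma2_species=float(VC[:, 1].mean()) if use_species else 0.0,
        sigma2_resid=float(VC[:, 2].mean()),
    )

    ess = {name: _ess(B[:, j]) for j, name in enumerate(design.fixed_names)}
    ess["sigma2_resid"] = _ess(VC[:, 2])
    if use_phylo:
        ess["sigma2_phylo"] = _ess(VC[:, 0])
    if use_species:
        ess["sigma2_species"] = _ess(VC[:, 1])
    low_ess = sorted(nm for nm, e in ess.items() if e < ess_threshold)
    if low_ess:
        logger.warning("low effective sample size for: %s", ", ".join(low_ess))

    mcse = {
        name: float(B[:, j].std(ddof=1) / np.sqrt(max(ess[name], 1.0)))
        for j, name in enumerate(design.fixed_names)
    }
    fit = FitResult(
        coefficients=coefs,
        varcomp=vc,
        conditional_r2=_conditional_r2(post_mean, vc, design),
        n_records=design.n_records,
        n_species=design.n_species,
        method="gibbs",
        diagnostics={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "n_draws": int(B.shape[0]),
            "seed": int(seed),
            "effective_sample_size": ess,
            "mc_se": mcse,
            "low_ess_warning": low_ess,
            "components": list(components),
        },
    )
    return fit


def _conditional_r2(beta, vc: VarianceComponents, design: ModelDesign) -> float:
    fitted = design.fixed_matrix @ np.asarray(beta, float)
    var_fixed = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    num = var_fixed + vc.sigma2_phylo + vc.sigma2_species
    den = num + vc.sigma2_resid
    if den <= 0:
        raise ValueError("total variance is zero; conditional R² undefined")
    return num / den


def conditional_r2(fit: FitResult, design: ModelDesign) -> float:
    """Conditional R²: (fixed + random variance) / (fixed + random + residual).

    The fixed-effect variance is the sample variance of ``Xβ̂`` over the
    records; the random contribution is the phylogenetic plus species
    variance.  Lies in [0, 1] and is invariant to positive rescaling of the
    response.
    """
    beta = np.array([c.estimate for c in fit.coefficients])
    return _conditional_r2(beta, fit.varcomp, design)


def fit_result_table_row(
    fit: FitResult, group: str, response: str, sep: str = "\t"
) -> str:
    """One coefficient-table row: group, response, estimates (CI), R², N."""

    def cell(c: Coefficient) -> str:
        return f"{c.estimate:.2f} ({c.lower95:.2f},{c.upper95:.2f})"

    cells = [group, response]
    cells.append(cell(fit.coef("intercept")))
    cells.append(cell(fit.coef("ln_mass")))
    if any(c.name == "temp_C" for c in fit.coefficients):
        cells.append(cell(fit.coef("temp_C")))
    cells.append(f"{fit.conditional_r2:.2f}")
    cells.append(f"{fit.n_records} ({fit.n_species})")
    return sep.join(cells)
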