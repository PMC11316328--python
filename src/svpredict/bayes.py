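"""Gibbs samplers for multi-kernel RKHS regression and BayesC.

Two Bayesian regression families, written from scratch:

* **Multi-kernel RKHS** — ``y = μ + Σ_k g_k + e`` with ``g_k ~ N(0, K_k σ²_k)``
  for a list of relationship kernels (e.g. the six class-specific additive
  GRMs, or additive + dominance + epistatic SNP kernels). Each kernel is
  eigendecomposed once and its effect is sampled in the eigenbasis, where
  the full conditional is diagonal. Variance components get conjugate
  scaled-inverse-χ² updates.

* **BayesC** — ``y = μ + Xβ + e`` over standardized marker dosages, where
  each marker has an effect with probability π (common effect variance)
  and zero effect otherwise; π ~ Beta parameterized by prior counts ``p0``
  and prior mean inclusion ``π0``.

Both samplers support a Gaussian response and a binary response via
Albert–Chib probit augmentation (single threshold at 0, residual variance
fixed to 1 for identifiability). Phenotypes to be predicted are *masked*:
they are removed from the likelihood and imputed from the current state
each sweep, and the reported prediction is the posterior mean of the
genetic predictor (for binary traits, the normal CDF of its mean).

Variance hyperpriors follow the common "R² heuristic": scaled-inverse-χ²
with df = 5 and scale chosen so the prior mode assigns half the phenotypic
variance to the model terms (split equally) and half to the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm
from scipy.special import ndtr

from .containers import KernelMatrix

_EIG_DROP = 1e-10  # relative cutoff for near-zero kernel eigenvalues


@dataclass
class MCMCSettings:
    """Chain length controls. ``paper_scale`` matches the published runs
    (100,000 iterations, burn-in 500, thinning 5); ``test_scale`` is the
    short default used throughout the test suite."""

    n_iter: int = 100_000
    burn_in: int = 500
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "MCMCSettings":
        return cls(100_000, 500, 5, seed)

    @classmethod
    def test_scale(cls, seed: int = 0) -> "MCMCSettings":
        return cls(5_000, 500, 5, seed)

    @property
    def n_samples(self) -> int:
        return 1 + (self.n_iter - self.burn_in - 1) // self.thin


@dataclass
class KernelRegressionSpec:
    """Multi-kernel RKHS model specification."""

    kernels: list[KernelMatrix]
    kernel_names: list[str] | None = None
    response: str = "gaussian"
    df: float = 5.0
    residual_df: float = 5.0
    r2_prior: float = 0.5
    #: (per-kernel variances, residual variance) to freeze the sampler in
    #: fixed-variance mode for closed-form cross-checks.
    fixed_variances: tuple[list[float], float] | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("need at least one kernel")
        if self.response not in ("gaussian", "ordinal"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.df <= 0 or self.residual_df <= 0:
            raise ValueError("hyperprior df must be positive")
        n = self.kernels[0].n
        if any(K.n != n for K in self.kernels):
            raise ValueError("kernels must share accession order/size")
        if self.kernel_names is None:
            self.kernel_names = [f"K{i + 1}_{K.kind}" for i, K in enumerate(self.kernels)]


@dataclass
class BayesCSpec:
    """BayesC model specification over a standardized design matrix."""

    X: np.ndarray
    response: str = "gaussian"
    p0: float = 5.0
    pi0: float = 0.01
    df: float = 5.0
    residual_df: float = 5.0
    r2_prior: float = 0.5
    fixed_pi: float | None = None
    fixed_variances: tuple[float, float] | None = None  # (sigma_beta2, sigma_e2)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not (0.0 < self.pi0 < 1.0):
            raise ValueError("pi0 must lie in (0, 1)")
        if self.p0 <= 0:
            raise ValueError("p0 (prior counts) must be positive")
        if self.response not in ("gaussian", "ordinal"):
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class PosteriorSummary:
    """Posterior means and samples from one sampler run."""

    response: str
    mask: np.ndarray  # boolean, True = phenotype withheld from the likelihood
    mu_mean: float
    variance_means: dict[str, float]
    variance_samples: dict[str, np.ndarray]
    genetic_values: np.ndarray  # posterior mean of the genetic predictor
    eta_mean: np.ndarray  # posterior mean of mu + genetic predictor
    n_samples: int
    effect_means: np.ndarray | None = None
    inclusion_probs: np.ndarray | None = None
    pi_mean: float | None = None
    pi_samples: np.ndarray | None = None
    #: posterior mean of the realized (over accessions) variance of each
    #: kernel's genetic values — the attribution quantity for variance
    #: partitioning, better identified than the raw variance component
    #: when markers outnumber accessions
    realized_component_variances: dict[str, float] | None = None

    def predictions(self) -> np.ndarray:
        """Predicted value for every accession (masked or not).

        Quantitative: posterior mean of μ + g. Binary: probability of the
        upper class, Φ(E[η]).
        """
        if self.response == "ordinal":
            p = ndtr(self.eta_mean)
            return np.clip(p, 1e-12, 1.0 - 1e-12)
        return self.eta_mean.copy()


def predict(summary: PosteriorSummary, indices: np.ndarray | None = None) -> np.ndarray:
    """Out-of-sample predictions for masked accessions.

    ``indices`` defaults to every masked row; requesting an unmasked row is
    an error (its phenotype entered the likelihood, so the value would be
    an in-sample fit, not a prediction).
    """
    masked = np.flatnonzero(summary.mask)
    if indices is None:
        indices = masked
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        return np.empty(0)
    bad = np.setdiff1d(indices, masked)
    if bad.size:
        raise ValueError(f"rows {bad[:5].tolist()} were not masked during fitting")
    return summary.predictions()[indices]


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _as_mask(n: int, mask) -> np.ndarray:
    if mask is None:
        return np.zeros(n, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype != bool:
        out = np.zeros(n, dtype=bool)
        out[mask] = True
        return out
    return mask.copy()


def _chi2_scale_inv(rng, df: float, ssq: float, scale: float, m: float) -> float:
    """Draw from the scaled-inverse-χ² full conditional."""
    return (ssq + df * scale) / rng.chisquare(df + m)


def _sample_liability(rng, eta: np.ndarray, z01: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Albert–Chib step: liabilities truncated at 0 by the observed class."""
    n = eta.shape[0]
    liab = np.empty(n)
    obs = ~mask
    lo = np.where(z01[obs] > 0.5, -eta[obs], -np.inf)
    hi = np.where(z01[obs] > 0.5, np.inf, -eta[obs])
    liab[obs] = eta[obs] + truncnorm.rvs(lo, hi, size=obs.sum(), random_state=rng)
    if mask.any():
        liab[mask] = eta[mask] + rng.standard_normal(int(mask.sum()))
    return liab


# ---------------------------------------------------------------------------
# multi-kernel RKHS
# ---------------------------------------------------------------------------

def fit_rkhs(y: np.ndarray, spec: KernelRegressionSpec,
             settings: MCMCSettings, mask=None) -> PosteriorSummary:
    """Gibbs sampler for the multi-kernel RKHS model.

    ``y`` holds the phenotype for every accession (binary traits on the
    internal {0, 1} scale); ``mask`` marks accessions whose phenotypes are
    withheld and predicted. Kernels must be PSD within tolerance.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    mask = _as_mask(n, mask)
    if mask.all():
        raise ValueError("all phenotypes masked: nothing to fit")
    rng = np.random.default_rng(settings.seed)
    ordinal = spec.response == "ordinal"

    bases = []
    for K in spec.kernels:
        K.check_psd()
        w, U = np.linalg.eigh(K.values)
        keep = w > _EIG_DROP * max(w[-1], 1.0)
        bases.append((U[:, keep], w[keep]))

    obs = ~mask
    if ordinal:
        z01 = y.copy()
        vy = 1.0
    else:
        vy = float(np.var(y[obs])) or 1.0

    nk = len(spec.kernels)
    mean_diags = [float(np.mean(np.diag(K.values))) or 1.0 for K in spec.kernels]
    scale_k = [vy * spec.r2_prior / nk / md * (spec.df + 2.0) / spec.df
               for md in mean_diags]
    scale_e = vy * (1.0 - spec.r2_prior) * (spec.residual_df + 2.0) / spec.residual_df

    fixed = spec.fixed_variances is not None
    if fixed:
        sig_k = [float(v) for v in spec.fixed_variances[0]]
        sig_e = float(spec.fixed_variances[1])
        if len(sig_k) != nk:
            raise ValueError("fixed variances must match kernel count")
    else:
        sig_k = [vy * spec.r2_prior / nk / md for md in mean_diags]
        sig_e = vy * (1.0 - spec.r2_prior)
    if ordinal:
        sig_e = 1.0

    mu = float(np.mean(y[obs]))
    b = [np.zeros(U.shape[1]) for U, _ in bases]
    g = [np.zeros(n) for _ in bases]
    y_cur = y.copy()
    if ordinal:
        y_cur = np.where(y > 0.5, 0.5, -0.5)  # crude liability start

    names = list(spec.kernel_names)
    keep_var = {nm: [] for nm in names}
    keep_var["residual"] = []
    realized = {nm: [] for nm in names}  # Var over accessions of each g_k
    sum_g = np.zeros(n)
    sum_eta = np.zeros(n)
    sum_mu = 0.0
    n_saved = 0

    for it in range(settings.n_iter):
        g_tot = np.sum(g, axis=0) if nk else np.zeros(n)
        eta = mu + g_tot
        if ordinal:
            y_cur = _sample_liability(rng, eta, z01, mask)
        elif mask.any():
            y_cur[mask] = eta[mask] + np.sqrt(sig_e) * rng.standard_normal(int(mask.sum()))

        # intercept
        r_mu = y_cur - g_tot
        mu = float(np.mean(r_mu) + np.sqrt(sig_e / n) * rng.standard_normal())

        # kernel effects in each eigenbasis (diagonal full conditionals)
        r = y_cur - mu - g_tot
        for k, (U, d) in enumerate(bases):
            r += g[k]
            t = U.T @ r
            var = 1.0 / (1.0 / sig_e + 1.0 / (d * sig_k[k]))
            b[k] = var * t / sig_e + np.sqrt(var) * rng.standard_normal(d.shape[0])
            g[k] = U @ b[k]
            r -= g[k]
            if not fixed:
                ssq = float(np.sum(b[k] ** 2 / d))
                sig_k[k] = _chi2_scale_inv(rng, spec.df, ssq, scale_k[k], d.shape[0])

        if not fixed and not ordinal:
            sig_e = _chi2_scale_inv(rng, spec.residual_df, float(r @ r), scale_e, n)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            n_saved += 1
            g_tot = np.sum(g, axis=0)
            sum_g += g_tot
            sum_eta += mu + g_tot
            sum_mu += mu
            for nm, s, gk in zip(names, sig_k, g):
                keep_var[nm].append(s)
                realized[nm].append(float(gk.var()))
            keep_var["residual"].append(sig_e)

    var_samples = {nm: np.asarray(v) for nm, v in keep_var.items()}
    return PosteriorSummary(
        response=spec.response, mask=mask, mu_mean=sum_mu / n_saved,
        variance_means={nm: float(v.mean()) for nm, v in var_samples.items()},
        variance_samples=var_samples,
        genetic_values=sum_g / n_saved, eta_mean=sum_eta / n_saved,
        n_samples=n_saved,
        realized_component_variances={nm: float(np.mean(v))
                                      for nm, v in realized.items()},
    )


# ---------------------------------------------------------------------------
# BayesC
# ---------------------------------------------------------------------------

def standardize_design(X: np.ndarray, rows: np.ndarray | None = None):
    """Center/scale columns with statistics from ``rows`` (training set).

    Returns the standardized matrix plus the (mean, sd) used. A constant
    column (on the training rows) cannot be standardized and is an error.
    """
    X = np.asarray(X, dtype=float)
    ref = X if rows is None else X[rows]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"column {j} is constant on the training rows")
    return (X - mean) / sd, mean, sd


def fit_bayesc(y: np.ndarray, spec: BayesCSpec, settings: MCMCSettings,
               mask=None) -> PosteriorSummary:
    """Gibbs sampler for BayesC with spike-and-slab marker effects.

    Masked rows are excluded from the likelihood entirely; predictions are
    ``X E[βδ] + E[μ]`` (probit-transformed for a binary response).
    """
    y = np.asarray(y, dtype=float)
    X = spec.X
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y length does not match X rows")
    mask = _as_mask(n, mask)
    obs = np.flatnonzero(~mask)
    if obs.size == 0:
        raise ValueError("all phenotypes masked: nothing to fit")
    rng = np.random.default_rng(settings.seed)
    ordinal = spec.response == "ordinal"

    Xo = np.asfortranarray(X[obs])
    no = obs.size
    if np.any(Xo.std(axis=0) == 0):
        j = int(np.flatnonzero(Xo.std(axis=0) == 0)[0])
        raise ValueError(f"design column {j} constant on training rows")
    cj = np.einsum("ij,ij->j", Xo, Xo)

    yo = y[obs].astype(float)
    if ordinal:
        z01 = yo.copy()
        vy = 1.0
    else:
        vy = float(np.var(yo)) or 1.0

    scale_b = vy * spec.r2_prior / (p * spec.pi0) * (spec.df + 2.0) / spec.df
    scale_e = vy * (1.0 - spec.r2_prior) * (spec.residual_df + 2.0) / spec.residual_df

    fixed = spec.fixed_variances is not None
    if fixed:
        sig_b, sig_e = map(float, spec.fixed_variances)
    else:
        sig_b = vy * spec.r2_prior / (p * spec.pi0)
        sig_e = vy * (1.0 - spec.r2_prior)
    if ordinal:
        sig_e = 1.0
    pi = spec.fixed_pi if spec.fixed_pi is not None else spec.pi0

    beta = np.zeros(p)
    delta = np.zeros(p, dtype=bool)
    mu = float(np.mean(yo))
    y_lat = np.where(z01 > 0.5, 0.5, -0.5) if ordinal else yo
    r = y_lat - mu  # residual on observed rows (beta = 0 at start)

    sum_beta = np.zeros(p)
    sum_delta = np.zeros(p)
    pi_draws, var_b, var_e = [], [], []
    sum_mu = 0.0
    n_saved = 0

    for it in range(settings.n_iter):
        if ordinal:
            eta_o = y_lat - r  # current mu + X beta on observed rows
            lo = np.where(z01 > 0.5, -eta_o, -np.inf)
            hi = np.where(z01 > 0.5, np.inf, -eta_o)
            new_lat = eta_o + truncnorm.rvs(lo, hi, size=no, random_state=rng)
            r += new_lat - y_lat
            y_lat = new_lat

        # intercept
        r += mu
        mu = float(np.mean(r) + np.sqrt(sig_e / no) * rng.standard_normal())
        r -= mu

        with np.errstate(divide="ignore"):  # pi = 1 -> always include
            log_prior_odds = np.log(pi) - np.log1p(-pi)
        unif = rng.random(p)
        norm = rng.standard_normal(p)
        for j in range(p):
            xj = Xo[:, j]
            rhs = xj @ r
            if delta[j]:
                rhs += cj[j] * beta[j]
            C = cj[j] + sig_e / sig_b
            log_odds = (log_prior_odds
                        + 0.5 * np.log(sig_e / (sig_b * C))
                        + 0.5 * rhs * rhs / (sig_e * C))
            p_in = 1.0 / (1.0 + np.exp(-log_odds)) if log_odds < 35 else 1.0
            old = beta[j] if delta[j] else 0.0
            if unif[j] < p_in:
                new = rhs / C + np.sqrt(sig_e / C) * norm[j]
                delta[j] = True
            else:
                new = 0.0
                delta[j] = False
            if new != old:
                r += xj * (old - new)
            beta[j] = new

        n_in = int(delta.sum())
        if not fixed:
            ssq_b = float(np.sum(beta[delta] ** 2))
            sig_b = _chi2_scale_inv(rng, spec.df, ssq_b, scale_b, n_in)
            if not ordinal:
                sig_e = _chi2_scale_inv(rng, spec.residual_df, float(r @ r),
                                        scale_e, no)
        if spec.fixed_pi is None:
            pi = rng.beta(spec.p0 * spec.pi0 + n_in, spec.p0 * (1.0 - spec.pi0) + p - n_in)
            pi = min(max(pi, 1e-8), 1.0 - 1e-8)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            n_saved += 1
            sum_beta += np.where(delta, beta, 0.0)
            sum_delta += delta
            sum_mu += mu
            pi_draws.append(pi)
            var_b.append(sig_b)
            var_e.append(sig_e)

    effect_means = sum_beta / n_saved
    incl = sum_delta / n_saved
    mu_mean = sum_mu / n_saved
    g_all = X @ effect_means
    var_samples = {"marker_effect": np.asarray(var_b), "residual": np.asarray(var_e)}
    return PosteriorSummary(
        response=spec.response, mask=mask, mu_mean=mu_mean,
        variance_means={k: float(v.mean()) for k, v in var_samples.items()},
        variance_samples=var_samples,
        genetic_values=g_all, eta_mean=mu_mean + g_all, n_samples=n_saved,
        effect_means=effect_means, inclusion_probs=incl,
        pi_mean=float(np.mean(pi_draws)), pi_samples=np.asarray(pi_draws),
    )
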