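"""Bayesian multi-kernel (reaction-norm) mixed model via Gibbs sampling.

Model:  y = μ 1 + Σ_t u_t + ε,   u_t ~ N(0, σ²_t K_t),   ε ~ N(0, σ²_ε I)

Each random vector is represented in the eigenbasis of its kernel restricted
to the training observations: K_t[train, train] = B_t B_t′ with B_t = U S from
a thin SVD of the kernel's low-rank factor, so u_t = B_t α_t with
α_t ~ N(0, σ²_t I).  Because B_t′ B_t = S² is diagonal, the full coordinate
block of α_t has an independent conjugate normal conditional and is updated in
one vectorised draw; variances get scaled-inverse-χ² conjugate updates.

Predictions for masked observations use the exact conditional mean of a
(possibly singular) joint Gaussian, u_test = K[test, train] K[train, train]⁺ u_train,
which in the factored representation is simply (F_test V) α_t.  For a
within-site interaction kernel (GE, AE) the cross-block entries of K are zero,
so a site absent from training receives exactly zero interaction contribution
— information flows to untested environments only through W, g and a.

Priors: every variance gets a scaled-inverse-χ² prior with small degrees of
freedom and scale set from a phenotypic-variance split (residual R² = 0.5, the
rest shared equally among terms), the de-facto default of this model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import DataBundle, PhenotypeTable
from .kernels import KernelSet, ObsKernel, build_kernel_set

EIGEN_TRUNCATION = 1e-10  # drop eigenpairs with λ < 1e-10 · λ_max


@dataclass
class McmcSettings:
    """Gibbs sampler settings.

    Defaults (12 000 iterations, 2 000 burn-in, thinning 5) give stable
    posterior means at desk scale; shorter chains are adequate for
    cross-validation sweeps where only posterior-mean predictions are used.
    """

    n_iterations: int = 12000
    burn_in: int = 2000
    thinning: int = 5
    seed: int = 0
    prior_df: float = 5.0
    r2_residual: float = 0.5
    fixed_variances: dict[str, float] = field(default_factory=dict)
    fixed_mu: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class FitResult:
    """Posterior summaries of one model fit."""

    model_name: str
    mu: float
    mu_sd: float
    variance_components: dict[str, float]
    variance_draws: dict[str, np.ndarray]
    effects: dict[str, np.ndarray]       # posterior-mean contribution, length n_obs
    effect_sds: dict[str, np.ndarray]
    fitted: np.ndarray                   # μ̂ + Σ effects on observed rows (NaN elsewhere)
    predicted: np.ndarray                # μ̂ + Σ effects on masked rows (NaN elsewhere)
    mask: np.ndarray                     # True where the response was held out
    n_obs: int
    ess: dict[str, float]

    def prediction_frame(self, kernel_set: KernelSet):
        out = kernel_set.obs.copy()
        out["predicted"] = np.where(self.mask, self.predicted, self.fitted)
        return out


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for a 1-D chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


class _TermBasis:
    """Per-kernel training eigenbasis and test cross-projector.

    Handles block-diagonal kernels (within-site interactions) by independent
    per-block SVDs; ``B`` maps α → u_train, ``P`` maps α → u_test.
    """

    def __init__(self, kernel: ObsKernel, train: np.ndarray, test: np.ndarray):
        self.name = kernel.name
        n_tr, n_te = train.size, test.size
        pieces = []
        if kernel.blocks is None:
            pieces.append((np.arange(n_tr), np.arange(n_te),
                           kernel.factor[train], kernel.factor[test]))
        else:
            btr, bte = kernel.blocks[train], kernel.blocks[test]
            for b in np.unique(kernel.blocks):
                r_tr = np.where(btr == b)[0]
                r_te = np.where(bte == b)[0]
                if r_tr.size == 0 and r_te.size == 0:
                    continue
                pieces.append((r_tr, r_te, kernel.factor[train[r_tr]],
                               kernel.factor[test[r_te]]))
        self.blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        d2 = []
        for r_tr, r_te, F_tr, F_te in pieces:
            if r_tr.size == 0:
                # no training data in this block: prior-only coordinates would
                # never inform predictions, and the conditional-mean projector
                # K[test, train] K⁺ u_train is zero here by construction
                continue
            U, S, Vt = np.linalg.svd(F_tr, full_matrices=False)
            keep = S**2 > EIGEN_TRUNCATION * max(S[0] ** 2 if S.size else 0.0, 1e-300)
            U, S, V = U[:, keep], S[keep], Vt[keep].T
            B = U * S
            P = F_te @ V if r_te.size else np.zeros((0, S.size))
            self.blocks.append((r_tr, r_te, B, P))
            d2.append(S**2)
        self.d2 = np.concatenate(d2) if d2 else np.zeros(0)
        self.rank = self.d2.size
        self.n_tr, self.n_te = n_tr, n_te

    def matvec(self, alpha: np.ndarray) -> np.ndarray:
        u = np.zeros(self.n_tr)
        k = 0
        for r_tr, _, B, _ in self.blocks:
            u[r_tr] = B @ alpha[k: k + B.shape[1]]
            k += B.shape[1]
        return u

    def rmatvec(self, e: np.ndarray) -> np.ndarray:
        out = np.empty(self.rank)
        k = 0
        for r_tr, _, B, _ in self.blocks:
            out[k: k + B.shape[1]] = B.T @ e[r_tr]
            k += B.shape[1]
        return out

    def predict(self, alpha: np.ndarray) -> np.ndarray:
        u = np.zeros(self.n_te)
        k = 0
        for _, r_te, B, P in self.blocks:
            if r_te.size:
                u[r_te] = P @ alpha[k: k + B.shape[1]]
            k += B.shape[1]
        return u


def fit(
    kernel_set: KernelSet,
    y: np.ndarray,
    mask: Optional[np.ndarray] = None,
    settings: Optional[McmcSettings] = None,
) -> FitResult:
    """Gibbs-sample the multi-kernel model; predict masked observations.

    ``mask`` marks held-out records (their y is ignored); records with NaN
    responses are treated as masked as well.  Deterministic given the seed in
    ``settings``.
    """
    settings = settings or McmcSettings()
    y = np.asarray(y, dtype=float)
    n = kernel_set.n_obs
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match {n} observations")
    mask = np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).copy()
    mask |= ~np.isfinite(y)
    train = np.where(~mask)[0]
    test = np.where(mask)[0]
    if train.size == 0:
        raise ValueError("all responses are masked; nothing to fit")

    rng = np.random.default_rng(settings.seed)
    y_tr = y[train]
    vary = float(np.var(y_tr))
    terms = list(kernel_set.kernels)
    bases = {t: _TermBasis(kernel_set.kernels[t], train, test) for t in terms}

    df0 = settings.prior_df
    r2_term = (1.0 - settings.r2_residual) / max(len(terms), 1)
    scale_factor = (df0 + 2.0) / df0
    prior_scale = {}
    for t in terms:
        md = kernel_set.kernels[t].mean_diagonal(train)
        prior_scale[t] = max(vary, 1e-12) * r2_term / max(md, 1e-12) * scale_factor
    prior_scale_e = max(vary, 1e-12) * settings.r2_residual * scale_factor

    sigma2 = {t: settings.fixed_variances.get(t, max(vary, 1e-12) * r2_term)
              for t in terms}
    sigma2_e = settings.fixed_variances.get("residual", max(vary, 1e-12) * settings.r2_residual)
    mu = float(np.mean(y_tr)) if settings.fixed_mu is None else settings.fixed_mu
    alpha = {t: np.zeros(bases[t].rank) for t in terms}
    u_tr = {t: np.zeros(train.size) for t in terms}
    e = y_tr - mu

    n_keep = 0
    mu_draws = []
    var_draws: dict[str, list[float]] = {t: [] for t in terms}
    var_draws["residual"] = []
    sum_u = {t: np.zeros(train.size) for t in terms}
    sumsq_u = {t: np.zeros(train.size) for t in terms}
    sum_p = {t: np.zeros(test.size) for t in terms}
    sumsq_p = {t: np.zeros(test.size) for t in terms}

    for it in range(settings.n_iterations):
        if settings.fixed_mu is None:
            r = e + mu
            mu = rng.normal(float(np.mean(r)), np.sqrt(sigma2_e / train.size))
            e = r - mu
        for t in terms:
            basis = bases[t]
            if basis.rank == 0:
                continue
            e += u_tr[t]
            c = basis.rmatvec(e)
            prec = basis.d2 / sigma2_e + 1.0 / sigma2[t]
            mean = c / sigma2_e / prec
            alpha[t] = mean + rng.standard_normal(basis.rank) / np.sqrt(prec)
            u_tr[t] = basis.matvec(alpha[t])
            e -= u_tr[t]
            if t not in settings.fixed_variances:
                ss = float(alpha[t] @ alpha[t])
                dof = df0 + basis.rank
                sigma2[t] = (df0 * prior_scale[t] + ss) / rng.chisquare(dof)
        if "residual" not in settings.fixed_variances:
            ss = float(e @ e)
            sigma2_e = (df0 * prior_scale_e + ss) / rng.chisquare(df0 + train.size)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            n_keep += 1
            mu_draws.append(mu)
            for t in terms:
                var_draws[t].append(sigma2[t])
                sum_u[t] += u_tr[t]
                sumsq_u[t] += u_tr[t] ** 2
                if test.size:
                    p = bases[t].predict(alpha[t])
                    sum_p[t] += p
                    sumsq_p[t] += p**2
            var_draws["residual"].append(sigma2_e)

    mu_arr = np.asarray(mu_draws)
    effects = {}
    effect_sds = {}
    for t in terms:
        full = np.zeros(n)
        full_sd = np.zeros(n)
        full[train] = sum_u[t] / n_keep
        full_sd[train] = np.sqrt(np.maximum(sumsq_u[t] / n_keep - (sum_u[t] / n_keep) ** 2, 0.0))
        if test.size:
            full[test] = sum_p[t] / n_keep
            full_sd[test] = np.sqrt(np.maximum(sumsq_p[t] / n_keep - (sum_p[t] / n_keep) ** 2, 0.0))
        effects[t] = full
        effect_sds[t] = full_sd

    mu_hat = float(mu_arr.mean())
    total = mu_hat + sum(effects[t] for t in terms)
    fitted = np.where(mask, np.nan, total)
    predicted = np.where(mask, total, np.nan)
    vcomp = {t: float(np.mean(var_draws[t])) for t in var_draws}
    draws = {t: np.asarray(v) for t, v in var_draws.items()}
    ess = {t: _effective_sample_size(d) for t, d in draws.items()}
    return FitResult(
        model_name=kernel_set.model_name,
        mu=mu_hat,
        mu_sd=float(mu_arr.std()),
        variance_components=vcomp,
        variance_draws=draws,
        effects=effects,
        effect_sds=effect_sds,
        fitted=fitted,
        predicted=predicted,
        mask=mask,
        n_obs=n,
        ess=ess,
    )


def predict(fit_result: FitResult, kernel_set: KernelSet, targets: np.ndarray) -> np.ndarray:
    """Predicted values for masked target records (by observation index)."""
    targets = np.asarray(targets)
    if targets.dtype == bool:
        targets = np.where(targets)[0]
    bad = [int(t) for t in targets if t < 0 or t >= fit_result.n_obs]
    if bad:
        raise ValueError(f"target rows outside the kernel index: {bad[:10]}")
    unmasked = [int(t) for t in targets if not fit_result.mask[t]]
    if unmasked:
        raise ValueError(f"target rows were not masked during fitting: {unmasked[:10]}")
    return fit_result.predicted[targets]


def fit_model_by_name(
    model_name: str,
    bundle: DataBundle,
    settings: Optional[McmcSettings] = None,
    mask: Optional[np.ndarray] = None,
    **kernel_kwargs,
) -> tuple[FitResult, KernelSet]:
    """Build the named model's kernels from a data bundle and fit it."""
    ks = build_kernel_set(
        model_name,
        bundle.phenotypes,
        markers=bundle.markers,
        pedigree=bundle.pedigree,
        env_covariates=bundle.env_covariates,
        **kernel_kwargs,
    )
    y = bundle.phenotypes.df["y"].to_numpy(dtype=float)
    res = fit(ks, y, mask=mask, settings=settings)
    return res, ks
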