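"""Stage-one phenotypic analysis of a multi-environment trial.

Two layers:

* per-site mixed models (random accession and block effects, checks as fixed
  groups) giving variance components, line BLUPs and broad-sense heritability
  on a line-mean basis, H² = σ²_L / (σ²_L + σ²_ε / r̄), with r̄ the mean
  replication of accessions in the p-rep design;

* a combined factor-analytic (FA) model across sites: sites fixed, blocks
  within sites random, genotype-within-site effects α with
  Var(α) = (Λ Λ′ + Ψ) ⊗ G, i.e. a rank-2 loading structure plus site-specific
  variances over the marker-derived genotype relationship.  Fitted by an
  EM/ECM algorithm on the restricted likelihood: genotype effects are
  whitened through G = Q D Q′ so the random part is (Λ Λ′ + Ψ) ⊗ I, the
  E-step solves the mixed-model equations jointly for (β, δ, α̃) with a flat
  prior on β (REML flavour), and the M-step updates σ²_δ, σ²_ε directly and
  (Λ, Ψ) through inner factor-analysis EM steps on the expected genetic
  covariance (a generalised-EM step, so the restricted log-likelihood is
  non-decreasing).

The implied between-site genetic covariance Σ = Λ Λ′ + Ψ yields the
genetic-variance / genetic-correlation table and the biplot coordinates
(principal-axis rotation of Λ).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .data import MarkerMatrix, PhenotypeTable
from .kernels import genomic_relationship

__all__ = [
    "SingleSiteFit",
    "FaFit",
    "fit_single_site",
    "fit_factor_analytic",
    "genetic_correlations",
    "pairwise_genetic_correlations",
    "biplot_coordinates",
]


@dataclass
class SingleSiteFit:
    site: str
    variance_components: dict[str, float]  # line, block, residual
    h2: float
    blups: pd.Series                       # accession line -> BLUP
    mean_replication: float
    group_effects: dict[str, float]        # fixed check-group contrasts vs accessions
    n_obs: int


def _as_relationship(
    G: Union[pd.DataFrame, tuple[Sequence[str], np.ndarray], MarkerMatrix],
) -> tuple[list[str], np.ndarray]:
    if isinstance(G, MarkerMatrix):
        return list(G.line_ids), genomic_relationship(G)
    if isinstance(G, pd.DataFrame):
        return list(G.index), G.to_numpy(dtype=float)
    ids, mat = G
    return list(ids), np.asarray(mat, dtype=float)


def fit_single_site(
    phenotypes: PhenotypeTable, site: str, reml: bool = True
) -> SingleSiteFit:
    """Per-site mixed model: y ~ check-group + (1|line) + (1|block).

    Accession line effects are random (checks carry fixed group effects and no
    line random effect); REML estimation through statsmodels' variance
    components machinery.
    """
    import statsmodels.formula.api as smf

    df = phenotypes.df[phenotypes.df["site"] == site].copy()
    if df.empty:
        raise ValueError(f"no records for site '{site}'")
    if df["block"].nunique() < 2:
        raise ValueError(f"site '{site}' has fewer than 2 blocks; variance components "
                         "are not estimable")
    acc = ~df["is_check"]
    if not (df.loc[acc].groupby("line").size() > 1).any() and df["is_check"].sum() == 0:
        raise ValueError(f"site '{site}' has no replicated entries")
    df["entry_group"] = np.where(df["is_check"], df["line"], "ACC")
    df["accflag"] = acc.astype(float)
    df["one"] = 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "y ~ C(entry_group, Treatment('ACC'))",
            df,
            groups="one",
            vc_formula={"line": "0 + C(line):accflag", "block": "0 + C(block)"},
            re_formula="0",
        )
        result = model.fit(reml=reml, method="lbfgs", maxiter=200)

    vc_names = list(model.exog_vc.names)
    vc = {name: float(v) for name, v in zip(vc_names, result.vcomp)}
    vc["residual"] = float(result.scale)
    rbar = float(df.loc[acc].groupby("line").size().mean())
    h2 = vc["line"] / (vc["line"] + vc["residual"] / rbar)

    blups = {}
    re_all = result.random_effects["1"] if "1" in result.random_effects else \
        result.random_effects[list(result.random_effects)[0]]
    for name, val in re_all.items():
        m = re.search(r"C\(line\)\[(.+?)\]", str(name))
        if m and m.group(1) in set(df.loc[acc, "line"]):
            blups[m.group(1)] = float(val)
    groups = {}
    for name, val in result.fe_params.items():
        m = re.search(r"\[T\.(.+?)\]", str(name))
        if m:
            groups[m.group(1)] = float(val)
    return SingleSiteFit(
        site=site,
        variance_components=vc,
        h2=float(h2),
        blups=pd.Series(blups).sort_index(),
        mean_replication=rbar,
        group_effects=groups,
        n_obs=len(df),
    )


@dataclass
class FaFit:
    """Factor-analytic fit of the combined multi-site model."""

    site_ids: list[str]
    line_ids: list[str]
    loadings: np.ndarray                 # s × k
    psi: np.ndarray                      # site-specific variances (diagonal of Ψ)
    sigma_site: np.ndarray               # Λ Λ′ + Ψ, between-site genetic covariance
    sigma2_block: float
    sigma2_residual: float
    beta: pd.Series
    line_values: np.ndarray              # lines × sites posterior-mean genetic values
    factor_scores: np.ndarray            # lines × k (regression scores)
    loglik_path: np.ndarray
    converged: bool
    n_factors: int

    @property
    def genetic_correlations_matrix(self) -> np.ndarray:
        d = np.diag(self.sigma_site).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = 1.0 / np.sqrt(d)
            corr = self.sigma_site * np.outer(scale, scale)
        corr[d <= 0, :] = np.nan
        corr[:, d <= 0] = np.nan
        np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
        return corr


def _fa_inner_update(
    S: np.ndarray, lam: np.ndarray, psi: np.ndarray, n_steps: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """A few EM steps of the factor model Σ = ΛΛ′ + Ψ toward covariance S."""
    s = S.shape[0]
    floor = 1e-8 * max(float(np.trace(S)) / s, 1e-12)
    for _ in range(n_steps):
        phi = lam @ lam.T + np.diag(psi)
        W = np.linalg.solve(phi, lam).T          # k × s
        Ezz = np.eye(lam.shape[1]) - W @ lam + W @ S @ W.T
        lam = S @ W.T @ np.linalg.inv(Ezz)
        psi = np.maximum(np.diag(S - lam @ W @ S), floor)
    return lam, psi


def fit_factor_analytic(
    phenotypes: PhenotypeTable,
    G: Union[pd.DataFrame, tuple[Sequence[str], np.ndarray], MarkerMatrix],
    n_factors: int = 2,
    max_iter: int = 100,
    tol: float = 1e-5,
    min_iter: int = 10,
    seed: int = 0,
) -> FaFit:
    """EM/ECM fit of the FA multi-site model (restricted likelihood).

    ``G`` covers at least all accessions (DataFrame with line index, an
    ``(ids, matrix)`` pair, or a MarkerMatrix to derive it from).  Checks are
    absorbed into fixed site × check cells and excluded from the G-indexed
    genotype effects.  Asserts a non-decreasing restricted log-likelihood.
    """
    df = phenotypes.df
    sites = list(pd.unique(df["site"]))
    s = len(sites)
    if s < 3 and n_factors >= 2:
        raise ValueError("need at least 3 sites for a 2-factor model")
    g_ids, G_mat = _as_relationship(G)
    lines = [l for l in phenotypes.accession_lines]
    missing = sorted(set(lines) - set(g_ids))
    if missing:
        raise ValueError(f"accessions absent from G: {missing[:10]}")
    gidx = {l: i for i, l in enumerate(g_ids)}
    Gs = G_mat[np.ix_([gidx[l] for l in lines], [gidx[l] for l in lines])]

    vals, vecs = np.linalg.eigh(0.5 * (Gs + Gs.T))
    keep = vals > 1e-8 * max(vals.max(initial=0.0), 1.0)
    T = vecs[:, keep] * np.sqrt(vals[keep])       # J × r whitening of G
    r = T.shape[1]
    J = len(lines)

    y = df["y"].to_numpy(dtype=float)
    n = y.size
    site_code = df["site"].map({x: i for i, x in enumerate(sites)}).to_numpy()
    line_code = df["line"].map({x: i for i, x in enumerate(lines)}).fillna(-1).astype(int).to_numpy()
    acc = ~df["is_check"].to_numpy()

    # fixed cells: site for accessions, site × check for checks
    cell = np.where(acc, df["site"], df["site"] + ":" + df["line"])
    cell_levels, cell_code = np.unique(cell, return_inverse=True)
    p = cell_levels.size
    X = np.zeros((n, p))
    X[np.arange(n), cell_code] = 1.0

    block_levels, block_code = np.unique(df["block"], return_inverse=True)
    q = block_levels.size
    Z1 = np.zeros((n, q))
    Z1[np.arange(n), block_code] = 1.0

    Zt = np.zeros((n, s * r))
    rows = np.where(acc)[0]
    Zt[rows[:, None], (site_code[rows] * r)[:, None] + np.arange(r)[None, :]] = T[line_code[rows]]

    U = np.hstack([X, Z1, Zt])
    UtU = U.T @ U
    Uty = U.T @ y
    yty = float(y @ y)
    dim = p + q + s * r

    rng = np.random.default_rng(seed)
    vary = float(np.var(y))
    sigma2_e = 0.5 * vary
    sigma2_b = 0.05 * vary
    d_G = float(np.diag(Gs).mean())
    c0 = 0.3 * vary / max(d_G, 1e-12)
    lam = np.full((s, n_factors), np.sqrt(c0 / (2.0 * n_factors)))
    lam += 0.01 * np.sqrt(c0) * rng.standard_normal((s, n_factors))
    psi = np.full(s, 0.5 * c0)

    ll_path = []
    converged = False
    m = np.zeros(dim)
    state = None  # last accepted (m, lam, psi, sigma2_b, sigma2_e)
    for it in range(max_iter):
        Sigma = lam @ lam.T + np.diag(psi)
        Sigma_inv = np.linalg.inv(Sigma)
        M = UtU / sigma2_e
        M[p: p + q, p: p + q] += np.eye(q) / sigma2_b
        M[p + q:, p + q:] += np.kron(Sigma_inv, np.eye(r))
        cf = linalg.cho_factor(M, lower=True)
        m = linalg.cho_solve(cf, Uty / sigma2_e)
        C = linalg.cho_solve(cf, np.eye(dim))

        # restricted log-likelihood (REML), up to an additive constant
        sign, logdet_Sigma = np.linalg.slogdet(Sigma)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_P = q * np.log(sigma2_b) + r * logdet_Sigma
        quad = (yty - float(m @ Uty)) / sigma2_e
        ll = -0.5 * (logdet_M + logdet_P + (n - p) * np.log(sigma2_e) + quad)
        if ll_path and ll < ll_path[-1] - 1e-8 * (1.0 + abs(ll_path[-1])):
            # only a variance floor (Heywood boundary) can break the GEM
            # guarantee; revert to the last accepted iterate and stop there
            m, lam, psi, sigma2_b, sigma2_e = state
            converged = True
            break
        done = bool(ll_path) and it >= min_iter and abs(ll - ll_path[-1]) < tol
        ll_path.append(ll)
        state = (m, lam.copy(), psi.copy(), sigma2_b, sigma2_e)

        m_d = m[p: p + q]
        C_dd = C[p: p + q, p: p + q]
        sigma2_b = float((m_d @ m_d + np.trace(C_dd)) / q)

        m_a = m[p + q:].reshape(s, r)
        C_aa = C[p + q:, p + q:].reshape(s, r, s, r)
        TrC = np.einsum("slzl->sz", C_aa)
        S_gen = (m_a @ m_a.T + TrC) / r
        lam, psi = _fa_inner_update(S_gen, lam, psi)

        resid = y - U @ m
        # tr(U'U C) = σ²ε (dim − tr(P⁻¹C)); the β block of P⁻¹ is zero
        trUUC = sigma2_e * dim - sigma2_e * (
            np.trace(C_dd) / sigma2_b
            + float(np.einsum("sz,szl->", Sigma_inv, np.einsum("slzl->szl", C_aa)))
        )
        sigma2_e = float((resid @ resid + trUUC) / n)

        if done:
            converged = True
            break
    else:
        warnings.warn(
            f"factor-analytic EM did not converge in {max_iter} iterations; "
            "returning the best iterate", RuntimeWarning,
        )

    Sigma = lam @ lam.T + np.diag(psi)
    m_a = m[p + q:].reshape(s, r)
    line_values = T @ m_a.T                       # J × s
    scores = line_values @ np.linalg.solve(Sigma, lam)
    beta = pd.Series(m[:p], index=cell_levels)
    return FaFit(
        site_ids=sites,
        line_ids=lines,
        loadings=lam,
        psi=psi,
        sigma_site=Sigma,
        sigma2_block=sigma2_b,
        sigma2_residual=sigma2_e,
        beta=beta,
        line_values=line_values,
        factor_scores=scores,
        loglik_path=np.asarray(ll_path),
        converged=converged,
        n_factors=n_factors,
    )


def genetic_correlations(fa: FaFit) -> pd.DataFrame:
    """Site × site table: genetic variances on the diagonal, correlations off it.

    Sites with zero genetic variance get missing correlations rather than a
    fabricated value.
    """
    corr = fa.genetic_correlations_matrix
    out = corr.copy()
    np.fill_diagonal(out, np.diag(fa.sigma_site))
    return pd.DataFrame(out, index=fa.site_ids, columns=fa.site_ids)


def pairwise_genetic_correlations(
    phenotypes: PhenotypeTable,
    G,
    max_iter: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Between-site genetic correlations from all two-site fits.

    A one-factor FA model on each site pair is a saturated (unstructured)
    2 × 2 genetic covariance; this is the pairwise alternative to reading the
    correlations off the joint factor-analytic fit.
    """
    sites = phenotypes.sites
    out = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1:]:
            rows = phenotypes.df["site"].isin([s1, s2]).to_numpy()
            sub = phenotypes.subset(rows)
            fa = fit_factor_analytic(sub, G, n_factors=1, max_iter=max_iter, seed=seed)
            c = fa.genetic_correlations_matrix[0, 1]
            out.loc[s1, s2] = out.loc[s2, s1] = c
            out.loc[s1, s1] = fa.sigma_site[0, 0]
            out.loc[s2, s2] = fa.sigma_site[1, 1]
    return out


def biplot_coordinates(fa: FaFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Principal-axis biplot: site vectors from rotated loadings, line scores.

    The loadings are rotated to their principal axes (SVD orientation); the
    cosine between two site vectors approximates their genetic correlation and
    a site's distance from the origin tracks its genetic variance (hence its
    discriminating power).
    """
    if fa.n_factors < 2:
        raise ValueError("biplot requires a 2-factor fit")
    Uv, sv, Vt = np.linalg.svd(fa.loadings, full_matrices=False)
    site_coords = Uv * sv                         # s × k principal axes
    scores = fa.factor_scores @ Vt.T
    site_df = pd.DataFrame(site_coords[:, :2], index=fa.site_ids, columns=["axis1", "axis2"])
    line_df = pd.DataFrame(scores[:, :2], index=fa.line_ids, columns=["axis1", "axis2"])
    return site_df, line_df
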