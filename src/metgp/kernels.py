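"""Relationship kernels and their observation-level algebra.

The reaction-norm models are defined entirely through named positive
semidefinite covariance structures over the plot-level observations:

* ``E``, ``L`` — IID site / line main effects (indicator products Z Z′);
* ``W`` — environmental-covariable kernel, Ω = W_s W_s′ / Q expanded to plots;
* ``G`` — genomic relationship, G = X_c X_c′ / p (VanRaden-style);
* ``A`` — pedigree additive relationship (tabular method);
* ``GE``, ``AE`` — Hadamard products of the expanded genetic kernels with the
  site-indicator kernel, the reaction-norm G × E construction.

Every kernel is stored as an :class:`ObsKernel` holding a low-rank factor
``F`` (so K = F F′, optionally masked to within-site blocks), from which the
dense matrix is materialised on demand.  Kernels are dense at observation
level; memory is O(n_obs²) which is fine at trial scale (a few thousand
plots).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import DataBundle, EnvCovariateTable, MarkerMatrix, Pedigree, PhenotypeTable

#: Valid model names (Table-style labels; the baseline is L+E).
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "L+E": ("E", "L"),
    "L+E+W": ("E", "L", "W"),
    "E+W+G": ("E", "W", "G"),
    "E+W+G+GE": ("E", "W", "G", "GE"),
    "E+W+A": ("E", "W", "A"),
    "E+W+A+AE": ("E", "W", "A", "AE"),
    "E+W+G+A": ("E", "W", "G", "A"),
    "E+W+G+A+GE+AE": ("E", "W", "G", "A", "GE", "AE"),
}

#: Variance-component label attached to each kernel term.
VARIANCE_LABELS = {
    "E": "sigma2_E",
    "L": "sigma2_L",
    "W": "sigma2_w",
    "G": "sigma2_g",
    "A": "sigma2_a",
    "GE": "sigma2_gE",
    "AE": "sigma2_aE",
}

PSD_RTOL = 1e-8


def genomic_relationship(
    markers: MarkerMatrix, center: bool = True, scale_mode: str = "p"
) -> np.ndarray:
    """Genomic relationship matrix from marker codes.

    ``scale_mode='p'`` divides by the marker count (G = X_c X_c′ / p);
    ``'vanraden'`` divides by 2 Σ p_q (1 − p_q) on the dosage scale;
    centering removes column (allele-frequency) means first.
    """
    if markers.n_markers == 0:
        raise ValueError("cannot build G from zero markers")
    if markers.n_lines < 2:
        raise ValueError("need at least two lines for a relationship matrix")
    X = markers.codes
    col_means = X.mean(axis=0)
    Xc = X - col_means if center else X.copy()
    if scale_mode == "p":
        denom = float(markers.n_markers)
    elif scale_mode == "vanraden":
        # dosage-scale allele frequencies
        p = col_means / 2.0
        denom = float(2.0 * np.sum(p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("VanRaden denominator is zero (all markers monomorphic)")
    else:
        raise ValueError(f"unknown scale_mode '{scale_mode}' (use 'p' or 'vanraden')")
    G = Xc @ Xc.T / denom
    return 0.5 * (G + G.T)


def additive_relationship(pedigree: Pedigree) -> tuple[list[str], np.ndarray]:
    """Additive (numerator) relationship matrix by the recursive tabular method.

    A_ii = 1 + ½ A_{f,m}; A_ij = ½ (A_{j,f} + A_{j,m}); unknown parents
    contribute zero.  Returns (ids in topological order, A).
    """
    order = pedigree.topological_order()
    idx = {i: k for k, i in enumerate(order)}
    parents = {i: (p1, p2) for i, p1, p2 in pedigree.records}
    n = len(order)
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        f, m = parents[ind]
        fi = idx[f] if f is not None else None
        mi = idx[m] if m is not None else None
        for j in range(k):
            a = 0.0
            if fi is not None:
                a += 0.5 * A[j, fi]
            if mi is not None:
                a += 0.5 * A[j, mi]
            A[j, k] = A[k, j] = a
        inb = 0.5 * A[fi, mi] if (fi is not None and mi is not None) else 0.0
        A[k, k] = 1.0 + inb
    return order, A


def env_kernel(table: EnvCovariateTable, standardize: bool = True) -> np.ndarray:
    """Site-similarity kernel Ω = W_s W_s′ / Q from environmental covariables.

    Columns are standardised (mean 0, population SD 1) by default so that the
    attached variance component is on a scale comparable to the other terms.
    """
    if table.n_sites < 2:
        raise ValueError("need at least two sites for an environmental kernel")
    W = table.values.copy()
    if standardize:
        sd = W.std(axis=0)
        bad = np.where(sd == 0)[0]
        if bad.size:
            names = [table.covariable_names[b] for b in bad]
            raise ValueError(f"constant covariable column(s) under standardization: {names}")
        W = (W - W.mean(axis=0)) / sd
    Omega = W @ W.T / table.q
    return 0.5 * (Omega + Omega.T)


def expand_to_observations(kernel: np.ndarray, level_index: np.ndarray) -> np.ndarray:
    """Expand a level-kernel (line- or site-level) to observation level.

    ``level_index[r]`` is the kernel row of observation r; the result is
    K_obs[r, s] = K[level(r), level(s)] (i.e. Z K Z′).  Raises if any
    observation is unmapped (negative or out of range).
    """
    level_index = np.asarray(level_index)
    bad = np.where((level_index < 0) | (level_index >= kernel.shape[0]))[0]
    if bad.size:
        raise ValueError(f"observations with no kernel level: rows {bad.tolist()[:10]}")
    return kernel[np.ix_(level_index, level_index)]


def interaction_kernel(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Hadamard (cell-by-cell) product of two observation-level kernels.

    PSD by the Schur product theorem when both inputs are PSD.
    """
    if k1.shape != k2.shape:
        raise ValueError(f"kernel dimension mismatch: {k1.shape} vs {k2.shape}")
    return k1 * k2


def assert_valid_kernel(K: np.ndarray, name: str = "kernel") -> None:
    """Assert symmetry and positive semidefiniteness (min eig ≥ −1e−8·max)."""
    if not np.allclose(K, K.T, atol=1e-10):
        raise AssertionError(f"{name} is not symmetric")
    ev = np.linalg.eigvalsh(K)
    lo, hi = ev[0], max(ev[-1], 0.0)
    if lo < -PSD_RTOL * max(hi, 1.0):
        raise AssertionError(f"{name} is not PSD: min eigenvalue {lo:.3e}")


def _psd_factor(K: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Low-rank factor F with K = F F′ from an eigendecomposition."""
    vals, vecs = np.linalg.eigh(0.5 * (K + K.T))
    top = vals.max(initial=0.0)
    keep = vals > rtol * max(top, 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


@dataclass
class ObsKernel:
    """Observation-level kernel K = F F′, optionally masked to blocks.

    When ``blocks`` is set, K[r, s] = (F F′)[r, s] if blocks[r] == blocks[s]
    else 0 — the structure of the Hadamard interaction with a site-indicator
    kernel.  The dense matrix is built lazily from the factor.
    """

    name: str
    factor: np.ndarray  # n_obs × r
    blocks: Optional[np.ndarray] = None  # block label per observation, or None
    variance_label: str = ""
    _matrix: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_obs(self) -> int:
        return self.factor.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            K = self.factor @ self.factor.T
            if self.blocks is not None:
                same = self.blocks[:, None] == self.blocks[None, :]
                K = K * same
            self._matrix = 0.5 * (K + K.T)
        return self._matrix

    def mean_diagonal(self, rows: Optional[np.ndarray] = None) -> float:
        d = np.einsum("ij,ij->i", self.factor, self.factor)
        if rows is not None:
            d = d[rows]
        return float(d.mean())

    def validate(self) -> None:
        assert_valid_kernel(self.matrix, self.name)


@dataclass
class KernelSet:
    """Named observation-level kernels sharing one observation ordering."""

    obs: pd.DataFrame  # site, line, rep, is_check per observation
    kernels: dict[str, ObsKernel]
    model_name: str
    residual_label: str = "sigma2_e"

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    @property
    def term_names(self) -> list[str]:
        return list(self.kernels)

    def validate(self) -> None:
        for k in self.kernels.values():
            if k.n_obs != self.n_obs:
                raise AssertionError(f"kernel {k.name} has {k.n_obs} rows, expected {self.n_obs}")
            k.validate()


def _indicator_factor(labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """One-hot incidence Z for a factor; returns (Z, integer codes)."""
    codes, _ = pd.factorize(labels)
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, codes


def build_kernel_set(
    model_name: str,
    phenotypes: PhenotypeTable,
    markers: Optional[MarkerMatrix] = None,
    pedigree: Optional[Pedigree] = None,
    env_covariates: Optional[EnvCovariateTable] = None,
    *,
    center_markers: bool = True,
    marker_scale_mode: str = "p",
    standardize_covariables: bool = True,
    validate: Optional[bool] = None,
) -> KernelSet:
    """Assemble the kernels of a named reaction-norm model.

    Model names follow the accuracy-table convention, e.g. ``"E+W+G+A+GE+AE"``;
    ``E`` and ``L`` are indicator-product kernels, ``W`` the expanded Ω,
    ``G``/``A`` expanded genetic kernels and ``GE``/``AE`` their Hadamard
    products with the site indicator.
    """
    if model_name not in MODEL_TERMS:
        raise ValueError(
            f"unknown model '{model_name}'; valid names: {', '.join(MODEL_TERMS)}"
        )
    terms = MODEL_TERMS[model_name]
    df = phenotypes.df
    Z_site, site_codes = _indicator_factor(df["site"])
    Z_line, line_codes = _indicator_factor(df["line"])
    obs_lines = list(pd.unique(df["line"]))
    obs_sites = list(pd.unique(df["site"]))

    need = {
        "G": markers, "GE": markers, "A": pedigree, "AE": pedigree,
        "W": env_covariates,
    }
    for t in terms:
        if t in need and need[t] is None:
            src = {"G": "marker matrix", "GE": "marker matrix",
                   "A": "pedigree", "AE": "pedigree", "W": "covariable table"}[t]
            raise ValueError(f"model '{model_name}' requires a {src}")

    kernels: dict[str, ObsKernel] = {}

    def line_factor_from(level_K: np.ndarray, ids: list[str], what: str) -> np.ndarray:
        index = {lid: i for i, lid in enumerate(ids)}
        missing = sorted(set(obs_lines) - set(ids))
        if missing:
            raise ValueError(f"lines absent from {what}: {missing[:10]}")
        rows = np.array([index[l] for l in obs_lines])
        F_line = _psd_factor(level_K[np.ix_(rows, rows)])
        return F_line[line_codes]

    F_G = F_A = None
    if "G" in terms or "GE" in terms:
        G = genomic_relationship(markers, center=center_markers, scale_mode=marker_scale_mode)
        F_G = line_factor_from(G, markers.line_ids, "marker matrix")
    if "A" in terms or "AE" in terms:
        ids, A = additive_relationship(pedigree)
        F_A = line_factor_from(A, ids, "pedigree")

    for t in terms:
        if t == "E":
            kernels["E"] = ObsKernel("E", Z_site.copy())
        elif t == "L":
            kernels["L"] = ObsKernel("L", Z_line.copy())
        elif t == "W":
            Omega = env_kernel(env_covariates, standardize=standardize_covariables)
            sindex = {s: i for i, s in enumerate(env_covariates.site_ids)}
            missing = sorted(set(obs_sites) - set(env_covariates.site_ids))
            if missing:
                raise ValueError(f"sites absent from covariable table: {missing}")
            rows = np.array([sindex[s] for s in obs_sites])
            F_site = _psd_factor(Omega[np.ix_(rows, rows)])
            kernels["W"] = ObsKernel("W", F_site[site_codes])
        elif t == "G":
            kernels["G"] = ObsKernel("G", F_G)
        elif t == "A":
            kernels["A"] = ObsKernel("A", F_A)
        elif t == "GE":
            kernels["GE"] = ObsKernel("GE", F_G.copy(), blocks=site_codes.copy())
        elif t == "AE":
            kernels["AE"] = ObsKernel("AE", F_A.copy(), blocks=site_codes.copy())
        kernels[t].variance_label = VARIANCE_LABELS[t]

    obs = df[["site", "line", "rep", "is_check"]].copy()
    ks = KernelSet(obs=obs, kernels=kernels, model_name=model_name)
    if validate is None:
        validate = ks.n_obs <= 250  # full eigencheck is cheap only at desk scale
    if validate:
        ks.validate()
    return ks
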