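"""Synthetic multi-environment trial generator with known ground truth.

Emulates the statistical structure the reaction-norm models assume: a
DArTseq-scale marker panel driving genomic values, a shallow pedigree driving
additive family structure, site-level temperature covariables driving
environment similarity, kernel-structured G × E, and a partially replicated
(p-rep) augmented field design with repeated checks.

The generative model for one trait is the full reaction-norm decomposition

    y_ijk = μ + E_i + w_ij + L_j + g_j + a_j + gE_ij + aE_ij + ε_ijk

with each term drawn from its multivariate normal (covariances I, Ω, I, G, A
and the within-site Hadamard expansions of G and A).  Terms whose variance is
set to zero are identically zero, so nested special cases (pure noise, main
effects only, ...) are exact.

Every operation is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data import DataBundle, EnvCovariateTable, MarkerMatrix, Pedigree, PhenotypeTable
from .kernels import additive_relationship, env_kernel, genomic_relationship, _psd_factor

#: Default variance components, on the **phenotypic-variance scale**: each
#: entry is the variance the term contributes to a plot record.  Chosen to sit
#: in the range of multi-site wheat yield trials: per-site total genetic
#: variance ≈ 1.9 t² ha⁻² and an implied between-site genetic correlation
#: (σ²_g+σ²_a)/(σ²_g+σ²_a+σ²_gE+σ²_aE) ≈ 0.74, inside the 0.4–0.85 band such
#: trials show.  Internally each target is converted to kernel units by the
#: mean kernel diagonal (PAV-coded G = X_c X_c′/p has a small diagonal, so its
#: kernel-unit variance parameter is correspondingly larger); `SimTruth`
#: records the kernel-unit values the models estimate.
DEFAULT_VARIANCES = {
    "E": 1.0,
    "W": 0.5,
    "L": 0.0,
    "G": 1.0,
    "A": 0.4,
    "GE": 0.35,
    "AE": 0.15,
    "block": 0.2,
    "residual": 1.0,
}

#: The five temperature summaries used as environmental covariables.
TEMPERATURE_COVARIABLES = [
    "tmin_vegetative",
    "tmin_cycle",
    "tmax_grainfill",
    "tmax_cycle",
    "tmean_cycle",
]


@dataclass
class SimConfig:
    """Configuration of one synthetic trial.

    Defaults reproduce the reference trial scale: 803 accessions, 5 sites,
    5 temperature covariables, 3 checks, and a p-rep design in which 81% of
    accessions appear once per site, 15% twice, 4% three times, with 6% of
    plots given to checks.
    """

    n_lines: int = 803
    n_markers: int = 2000
    n_sites: int = 5
    n_covariables: int = 5
    n_checks: int = 3
    prep_fractions: tuple[float, float, float] = (0.81, 0.15, 0.04)
    check_plot_fraction: float = 0.06
    variance_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCES)
    )
    mu: float = 6.0  # overall trait mean (t ha⁻¹ scale for yield)
    marker_dialect: str = "pav"  # 'pav' {0,1} or 'dosage' {0,1,2}
    markers_from_pedigree: bool = False  # gene-drop markers through the pedigree
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    block_size: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.prep_fractions) - 1.0) > 1e-8:
            raise ValueError(
                f"prep_fractions must sum to 1, got {sum(self.prep_fractions):.6f}"
            )
        if self.n_checks < 0:
            raise ValueError("n_checks must be non-negative")
        if not 0.0 <= self.check_plot_fraction < 1.0:
            raise ValueError("check_plot_fraction must be in [0, 1)")
        bad = {k: v for k, v in self.variance_components.items() if v < 0}
        if bad:
            raise ValueError(f"negative variance components: {bad}")

    def variances(self) -> dict[str, float]:
        out = dict(DEFAULT_VARIANCES)
        out.update(self.variance_components)
        return out


@dataclass
class SimTruth:
    """Realised ground truth of one simulated trait."""

    line_ids: list[str]
    site_ids: list[str]
    true_genetic_values: np.ndarray  # lines × sites, L + g + a + gE + aE
    true_marker_effects: np.ndarray
    true_variance_components: dict[str, float]  # kernel units (what models estimate)
    target_variances: dict[str, float]          # phenotypic-scale targets
    components: dict[str, np.ndarray]
    seed: int


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def simulate_markers(
    n_lines: int,
    n_markers: int,
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
    dialect: str = "pav",
) -> MarkerMatrix:
    """Biallelic marker panel with controlled allele frequencies.

    Allele counts per column are fixed to the target frequency (then permuted
    across lines), so realised column frequencies stay inside the requested
    range and no column is monomorphic.
    """
    lo, hi = allele_freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"allele frequency range must satisfy 0 < lo <= hi < 1, got ({lo}, {hi})")
    if n_lines < 2:
        raise ValueError("need at least two lines")
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if dialect not in ("pav", "dosage"):
        raise ValueError(f"unknown marker dialect '{dialect}'")
    rng = _rng(seed, 1)
    ploidy = 1 if dialect == "pav" else 2
    n_alleles = n_lines * ploidy
    freqs = rng.uniform(lo, hi, size=n_markers)
    counts = np.round(freqs * n_alleles).astype(int)
    counts = np.clip(counts, max(1, int(np.ceil(lo * n_alleles))),
                     min(n_alleles - 1, int(np.floor(hi * n_alleles))))
    X = np.zeros((n_lines, n_markers))
    for m in range(n_markers):
        alleles = np.zeros(n_alleles)
        alleles[: counts[m]] = 1.0
        rng.shuffle(alleles)
        X[:, m] = alleles.reshape(n_lines, ploidy).sum(axis=1) if ploidy == 2 else alleles
    line_ids = [f"L{j + 1:04d}" for j in range(n_lines)]
    return MarkerMatrix(line_ids=line_ids, codes=X)


def gene_drop_markers(
    pedigree: Pedigree,
    line_ids: list[str],
    n_markers: int,
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
    dialect: str = "pav",
) -> MarkerMatrix:
    """Drop founder alleles through a pedigree to the requested lines.

    Founders get two gametes per marker at the target allele frequency; every
    descendant inherits one random allele from each parent.  This produces the
    family covariance structure (and the decaying G spectrum) a real breeding
    panel shows, at the price of making G overlap A.  Near-monomorphic columns
    are kept (a redraw would break the inheritance structure); a constant
    column is re-seeded with a fresh founder configuration.
    """
    lo, hi = allele_freq_range
    rng = _rng(seed, 7)
    order = pedigree.topological_order()
    parents = {i: (p1, p2) for i, p1, p2 in pedigree.records}
    missing = sorted(set(line_ids) - set(order))
    if missing:
        raise ValueError(f"lines absent from pedigree: {missing[:10]}")
    freqs = rng.uniform(lo, hi, size=n_markers)
    for _ in range(50):
        haps: dict[str, np.ndarray] = {}
        for ind in order:
            f, m = parents[ind]
            h = np.empty((2, n_markers))
            for k, par in enumerate((f, m)):
                if par is None:
                    h[k] = (rng.random(n_markers) < freqs).astype(float)
                else:
                    pick = rng.integers(0, 2, size=n_markers)
                    h[k] = haps[par][pick, np.arange(n_markers)]
            haps[ind] = h
        dosage = np.stack([haps[l].sum(axis=0) for l in line_ids])
        X = np.minimum(dosage, 1.0) if dialect == "pav" else dosage
        if X.std(axis=0).min() > 0:
            break
    else:
        raise RuntimeError("could not generate polymorphic markers after 50 redraws")
    return MarkerMatrix(line_ids=list(line_ids), codes=X)


def simulate_pedigree(
    n_founders: int, n_generations: int, offspring_per_cross: int, seed: int = 0
) -> Pedigree:
    """Random-mating pedigree: founders plus crosses within each generation."""
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = _rng(seed, 2)
    records: list[tuple[str, Optional[str], Optional[str]]] = [
        (f"F{i + 1:03d}", None, None) for i in range(n_founders)
    ]
    prev = [r[0] for r in records]
    for g in range(1, n_generations + 1):
        n_crosses = max(len(prev) // 2, 1)
        newgen = []
        for c in range(n_crosses):
            p1, p2 = rng.choice(prev, size=2, replace=False)
            for o in range(offspring_per_cross):
                cid = f"G{g}C{c + 1:03d}O{o + 1}"
                records.append((cid, str(p1), str(p2)))
                newgen.append(cid)
        prev = newgen
    return Pedigree(records=records)


def simulate_env_covariates(
    n_sites: int, n_covariables: int = 5, seed: int = 0
) -> EnvCovariateTable:
    """Site × Q table of temperature-style covariables with between-site spread.

    The first five columns mimic the standard growth-phase temperature
    summaries (minimum at vegetative stage / over the cycle, maximum during
    grain filling / over the cycle, cycle mean); extra columns are generic.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    if n_covariables < 1:
        raise ValueError("need at least one covariable")
    rng = _rng(seed, 3)
    tmean = rng.normal(19.7, 3.0, size=n_sites)
    tmin_cycle = tmean - np.abs(rng.normal(8.0, 1.0, size=n_sites))
    tmax_cycle = tmean + np.abs(rng.normal(9.0, 1.0, size=n_sites))
    tmin_veg = tmin_cycle + rng.normal(0.0, 1.5, size=n_sites)
    tmax_gf = tmax_cycle + rng.normal(0.0, 1.5, size=n_sites)
    base = np.column_stack([tmin_veg, tmin_cycle, tmax_gf, tmax_cycle, tmean])
    names = list(TEMPERATURE_COVARIABLES)
    if n_covariables <= 5:
        values = base[:, :n_covariables]
        names = names[:n_covariables]
    else:
        extra = rng.normal(0.0, 1.0, size=(n_sites, n_covariables - 5))
        values = np.column_stack([base, extra])
        names += [f"ec_{q + 1}" for q in range(5, n_covariables)]
    site_ids = [f"S{i + 1}" for i in range(n_sites)]
    return EnvCovariateTable(site_ids=site_ids, values=values, covariable_names=names)


def _prep_counts(n_acc: int, fractions: tuple[float, float, float]) -> np.ndarray:
    counts = np.round(np.asarray(fractions) * n_acc).astype(int)
    if counts.min() < 0:
        raise ValueError(f"infeasible replication fractions {fractions} for {n_acc} accessions")
    diff = n_acc - counts.sum()
    counts[int(np.argmax(counts))] += diff
    if counts.min() < 0 or counts.sum() != n_acc:
        raise ValueError(
            f"replication fractions {fractions} infeasible for {n_acc} accessions "
            f"(shortfall {counts.sum() - n_acc})"
        )
    return counts


def simulate_design(config: SimConfig) -> PhenotypeTable:
    """p-rep augmented-block design skeleton (no trait values).

    Per site, accessions are partitioned into once / twice / three-times
    replicated groups by deterministic rounding of ``prep_fractions`` (so the
    realised proportions are exact to within one accession per group), check
    plots fill ``check_plot_fraction`` of the total, and replicates of an
    entry land in distinct blocks.
    """
    rng = _rng(config.seed, 4)
    acc_ids = [f"L{j + 1:04d}" for j in range(config.n_lines)]
    check_ids = [f"CHK{c + 1}" for c in range(config.n_checks)]
    counts = _prep_counts(config.n_lines, config.prep_fractions)
    rows = []
    for i in range(config.n_sites):
        site = f"S{i + 1}"
        perm = rng.permutation(config.n_lines)
        reps = np.empty(config.n_lines, dtype=int)
        reps[perm[: counts[0]]] = 1
        reps[perm[counts[0]: counts[0] + counts[1]]] = 2
        reps[perm[counts[0] + counts[1]:]] = 3
        acc_plots = int(reps.sum())
        f = config.check_plot_fraction
        n_check_plots = int(round(acc_plots * f / (1.0 - f))) if config.n_checks else 0
        total = acc_plots + n_check_plots
        n_blocks = max(int(np.ceil(total / config.block_size)), int(reps.max()))
        for j, lid in enumerate(acc_ids):
            blocks = rng.choice(n_blocks, size=reps[j], replace=False)
            for k, b in enumerate(sorted(blocks)):
                rows.append((site, lid, f"{site}B{b + 1}", k + 1, False))
        for p in range(n_check_plots):
            lid = check_ids[p % config.n_checks]
            b = p % n_blocks
            rep = p // config.n_checks + 1
            rows.append((site, lid, f"{site}B{b + 1}", rep, True))
    df = pd.DataFrame(rows, columns=["site", "line", "block", "rep", "is_check"])
    df["y"] = np.nan
    return PhenotypeTable(df)


def simulate_phenotypes(
    skeleton: PhenotypeTable,
    markers: MarkerMatrix,
    pedigree: Pedigree,
    env_covariates: EnvCovariateTable,
    config: SimConfig,
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw trait values on a design skeleton from the reaction-norm model.

    Genomic values are built from explicit marker effects (g = X_c b with
    b ~ N(0, σ²_g/p)), additive values from a pedigree-A factor, the
    covariable regression from γ ~ N(0, σ²_w I_Q), and G × E / A × E terms as
    independent per-site draws with line-covariance G / A — exactly the
    covariance structure Σ σ²·K the fitted models assume.
    """
    df = skeleton.df
    lines = list(pd.unique(df["line"]))
    sites = list(pd.unique(df["site"]))
    problems = []
    missing_m = sorted(set(lines) - set(markers.line_ids))
    if missing_m:
        problems.append(f"lines absent from markers: {missing_m[:10]}")
    missing_p = sorted(set(lines) - set(pedigree.ids))
    if missing_p:
        problems.append(f"lines absent from pedigree: {missing_p[:10]}")
    missing_s = sorted(set(sites) - set(env_covariates.site_ids))
    if missing_s:
        problems.append(f"sites absent from covariables: {missing_s}")
    if problems:
        raise ValueError("; ".join(problems))

    target = config.variances()
    rng = _rng(config.seed, 5)
    J, S = len(lines), len(sites)

    mrow = markers.row_index()
    X = markers.codes[[mrow[l] for l in lines]]
    Xc = X - X.mean(axis=0)
    p = markers.n_markers
    d_G = float(np.einsum("ij,ij->i", Xc, Xc).mean() / p)  # mean diag of X_c X_c'/p

    ped_ids, A_full = additive_relationship(pedigree)
    pidx = {l: i for i, l in enumerate(ped_ids)}
    A = A_full[np.ix_([pidx[l] for l in lines], [pidx[l] for l in lines])]
    d_A = float(np.diag(A).mean())
    F_A = _psd_factor(A)

    sidx = {s: i for i, s in enumerate(env_covariates.site_ids)}
    Wfull = env_covariates.values
    sd = Wfull.std(axis=0)
    Ws = (Wfull - Wfull.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Ws = Ws[[sidx[s] for s in sites]] / np.sqrt(env_covariates.q)
    d_W = float(np.einsum("ij,ij->i", Ws, Ws).mean())

    # kernel-unit variance parameters from phenotypic-scale targets
    var = dict(target)
    for key, d in (("G", d_G), ("GE", d_G), ("A", d_A), ("AE", d_A), ("W", d_W)):
        var[key] = target[key] / d if d > 0 else 0.0

    b = rng.normal(0.0, np.sqrt(var["G"] / p), size=p) if var["G"] > 0 else np.zeros(p)
    g = Xc @ b

    a = F_A @ rng.normal(size=F_A.shape[1]) * np.sqrt(var["A"]) if var["A"] > 0 else np.zeros(J)

    L_eff = rng.normal(0.0, np.sqrt(var["L"]), size=J) if var["L"] > 0 else np.zeros(J)

    E_eff = rng.normal(0.0, np.sqrt(var["E"]), size=S) if var["E"] > 0 else np.zeros(S)

    gamma = (rng.normal(0.0, np.sqrt(var["W"]), size=env_covariates.q)
             if var["W"] > 0 else np.zeros(env_covariates.q))
    w_site = Ws @ gamma

    G_mat = genomic_relationship(markers)  # full line set, canonical order
    rows = [mrow[l] for l in lines]
    F_G = _psd_factor(G_mat[np.ix_(rows, rows)])
    gE = (F_G @ rng.normal(size=(F_G.shape[1], S)) * np.sqrt(var["GE"])
          if var["GE"] > 0 else np.zeros((J, S)))
    aE = (F_A @ rng.normal(size=(F_A.shape[1], S)) * np.sqrt(var["AE"])
          if var["AE"] > 0 else np.zeros((J, S)))

    blocks = list(pd.unique(df["block"]))
    bidx = {bl: i for i, bl in enumerate(blocks)}
    block_eff = (rng.normal(0.0, np.sqrt(var["block"]), size=len(blocks))
                 if var["block"] > 0 else np.zeros(len(blocks)))

    li = df["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    si = df["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    bi = df["block"].map(bidx).to_numpy()
    eps = rng.normal(0.0, np.sqrt(var["residual"]), size=len(df))
    y = (config.mu + E_eff[si] + w_site[si] + L_eff[li] + g[li] + a[li]
         + gE[li, si] + aE[li, si] + block_eff[bi] + eps)

    out = df.copy()
    out["y"] = y
    genetic = (L_eff + g + a)[:, None] + gE + aE
    truth = SimTruth(
        line_ids=lines,
        site_ids=sites,
        true_genetic_values=genetic,
        true_marker_effects=b,
        true_variance_components=dict(var),
        target_variances=dict(target),
        components={
            "site_effects": E_eff, "w_site": w_site, "gamma": gamma,
            "line_iid": L_eff, "g": g, "a": a, "gE": gE, "aE": aE,
            "block_effects": block_eff,
        },
        seed=config.seed,
    )
    return PhenotypeTable(out), truth


def simulate_dataset(config: SimConfig) -> tuple[DataBundle, SimTruth]:
    """One coherent trial: markers, pedigree, covariables, design, phenotypes.

    All trial entries (accessions and checks) are genotyped; the pedigree puts
    every entry as a cross of two random founders, giving half/full-sib family
    structure in A.
    """
    rng = _rng(config.seed, 6)
    n_total = config.n_lines + config.n_checks
    ids = [f"L{j + 1:04d}" for j in range(config.n_lines)]
    ids += [f"CHK{c + 1}" for c in range(config.n_checks)]

    # two-generation breeding genealogy from few founders, emulating the dense
    # relatedness of an elite-nursery panel: founders → intermediate parents →
    # trial entries (full sibs, half sibs and cousins via shared grandparents)
    n_f = max(4, n_total // 15)
    n_mid = max(4, n_total // 8)
    records: list[tuple[str, Optional[str], Optional[str]]] = [
        (f"F{i + 1:03d}", None, None) for i in range(n_f)
    ]
    founders = [r[0] for r in records]
    mids = []
    for k in range(n_mid):
        i1, i2 = rng.choice(n_f, size=2, replace=False)
        mid = f"P{k + 1:03d}"
        records.append((mid, founders[i1], founders[i2]))
        mids.append(mid)
    for lid in ids:
        i1, i2 = rng.choice(n_mid, size=2, replace=False)
        records.append((lid, mids[i1], mids[i2]))
    pedigree = Pedigree(records=records)

    if config.markers_from_pedigree:
        # realistic family-structured panel; note G then overlaps A and the
        # G/A variance split is only weakly identified (as in real data)
        markers = gene_drop_markers(
            pedigree, ids, config.n_markers, config.allele_freq_range,
            seed=config.seed, dialect=config.marker_dialect,
        )
    else:
        markers = simulate_markers(
            n_total, config.n_markers, config.allele_freq_range,
            seed=config.seed, dialect=config.marker_dialect,
        )
        markers.line_ids = ids

    env = simulate_env_covariates(config.n_sites, config.n_covariables, seed=config.seed)
    skeleton = simulate_design(config)
    phenotypes, truth = simulate_phenotypes(skeleton, markers, pedigree, env, config)
    bundle = DataBundle(
        phenotypes=phenotypes, markers=markers, pedigree=pedigree, env_covariates=env
    )
    bundle.validate()
    return bundle, truth
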