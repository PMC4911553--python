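"""The four prediction problems and their accuracy summaries.

* **CV1** — whole lines held out: all records of a test line are masked in
  every site (predicting lines never observed anywhere).
* **CV2** — plot records held out at random (sparse testing: a line may be
  observed in some sites and predicted in others).
* **pairwise** — train on exactly one site's records, predict another site
  (the fit sees only the two sites' records, the test site masked).
* **leave-one-site-out** — train on all other sites, predict the held-out
  site; its covariable row stays in W, so information reaches the unobserved
  environment only through W and the genetic main effects.

Accuracy is the within-site Pearson correlation between observed and
predicted values of test records, averaged (with SD) over replicates.  Checks
are design infrastructure: they never enter test sets and are excluded from
accuracy computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import DataBundle, PhenotypeTable
from .mcmc import McmcSettings, fit_model_by_name

SCHEMES = ("CV1", "CV2", "pairwise", "leave-one-site-out")


@dataclass
class CvPlan:
    """Fold assignments for one scheme.

    Each fold is a pair of boolean arrays over the phenotype records:
    ``subset`` (records that participate in the fit at all — only the two
    sites for pairwise) and ``mask`` (records whose response is hidden and
    predicted).  ``meta`` carries the replicate number or train/test sites.
    """

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    meta: list[dict]
    seed: int
    test_fraction: float = 0.2


def make_cv_plan(
    scheme: str,
    phenotypes: PhenotypeTable,
    test_fraction: float = 0.2,
    n_replicates: int = 50,
    seed: int = 0,
) -> CvPlan:
    """Build fold assignments; deterministic given the seed.

    CV1 assigns all records of a line to the same fold; CV2 assigns plot
    records independently; pairwise enumerates ordered site pairs;
    leave-one-site-out enumerates sites.  Check plots never enter test sets.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme '{scheme}'; valid: {SCHEMES}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    df = phenotypes.df
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 11])
    n = len(df)
    is_check = df["is_check"].to_numpy()
    all_in = np.ones(n, dtype=bool)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    meta: list[dict] = []

    if scheme == "CV1":
        lines = phenotypes.accession_lines
        if len(lines) < 5:
            raise ValueError("CV1 needs at least 5 accession lines")
        n_test = max(1, int(round(test_fraction * len(lines))))
        line_arr = df["line"].to_numpy()
        for rep in range(n_replicates):
            test_lines = set(rng.choice(lines, size=n_test, replace=False))
            mask = np.array([l in test_lines for l in line_arr]) & ~is_check
            folds.append((all_in, mask))
            meta.append({"replicate": rep})
    elif scheme == "CV2":
        cand = np.where(~is_check)[0]
        n_test = max(1, int(round(test_fraction * cand.size)))
        for rep in range(n_replicates):
            take = rng.choice(cand, size=n_test, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[take] = True
            folds.append((all_in, mask))
            meta.append({"replicate": rep})
    elif scheme == "pairwise":
        site_arr = df["site"].to_numpy()
        for train_site in phenotypes.sites:
            for test_site in phenotypes.sites:
                if test_site == train_site:
                    continue
                subset = (site_arr == train_site) | (site_arr == test_site)
                mask = (site_arr == test_site) & subset & ~is_check
                folds.append((subset, mask))
                meta.append({"train_site": train_site, "test_site": test_site})
    else:  # leave-one-site-out
        site_arr = df["site"].to_numpy()
        for test_site in phenotypes.sites:
            mask = (site_arr == test_site) & ~is_check
            folds.append((all_in, mask))
            meta.append({"test_site": test_site})
    return CvPlan(scheme=scheme, folds=folds, meta=meta, seed=seed,
                  test_fraction=test_fraction)


@dataclass
class AccuracyReport:
    """Per-site accuracies of one model under one scheme."""

    model_name: str
    scheme: str
    correlations: pd.DataFrame  # columns: site, replicate/fold keys, r, n_test

    def summary(self) -> pd.DataFrame:
        """Mean correlation and its SD across replicates, per site."""
        g = self.correlations.groupby("site")["r"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out.insert(0, "scheme", self.scheme)
        out.insert(0, "model", self.model_name)
        if self.scheme in ("pairwise", "leave-one-site-out"):
            out["std"] = np.nan  # single run per fold; no replicate spread
        return out

    @property
    def mean_accuracy(self) -> float:
        return float(self.correlations["r"].mean())


def _site_correlations(
    df: pd.DataFrame, observed: np.ndarray, predicted: np.ndarray,
    mask: np.ndarray, meta: dict, value_mode: str,
) -> list[dict]:
    rows = []
    sub = pd.DataFrame({
        "site": df["site"].to_numpy()[mask],
        "line": df["line"].to_numpy()[mask],
        "obs": observed[mask],
        "pred": predicted[mask],
    })
    if value_mode == "line_mean":
        sub = sub.groupby(["site", "line"], as_index=False)[["obs", "pred"]].mean()
    for site, grp in sub.groupby("site"):
        ok = np.isfinite(grp["obs"]) & np.isfinite(grp["pred"])
        n_test = int(ok.sum())
        if n_test < 3 or grp.loc[ok, "obs"].std() == 0:
            r = np.nan  # too few test records: report missing, never fabricate
        elif grp.loc[ok, "pred"].std() == 0:
            # constant predictions (e.g. an IID line effect under CV1 carries
            # no information): no discriminating ability, scored as 0
            r = 0.0
        else:
            r = float(np.corrcoef(grp.loc[ok, "obs"], grp.loc[ok, "pred"])[0, 1])
        rows.append({"site": site, "r": r, "n_test": n_test, **meta})
    return rows


def run_scheme(
    model_name: str,
    bundle: DataBundle,
    plan: CvPlan,
    settings: Optional[McmcSettings] = None,
    value_mode: str = "plot",
    permute_seed: Optional[int] = None,
) -> AccuracyReport:
    """Mask, fit, predict and score every fold of a CV plan.

    ``value_mode='plot'`` correlates raw plot records of the test set with
    their predictions within site; ``'line_mean'`` averages replicates first.
    ``permute_seed`` permutes responses within the whole table before running
    (null calibration).
    """
    settings = settings or McmcSettings()
    df = bundle.phenotypes.df
    y_all = df["y"].to_numpy(dtype=float)
    if permute_seed is not None:
        y_all = np.random.default_rng([permute_seed & 0x7FFFFFFF, 13]).permutation(y_all)
    rows = []
    for fold_no, ((subset, mask), meta) in enumerate(zip(plan.folds, plan.meta)):
        sub_idx = np.where(subset)[0]
        sub_pheno = bundle.phenotypes.subset(subset)
        sub_pheno.df["y"] = y_all[sub_idx]
        sub_bundle = DataBundle(
            phenotypes=sub_pheno, markers=bundle.markers,
            pedigree=bundle.pedigree, env_covariates=bundle.env_covariates,
        )
        sub_mask = mask[sub_idx]
        fold_settings = McmcSettings(
            n_iterations=settings.n_iterations, burn_in=settings.burn_in,
            thinning=settings.thinning,
            seed=int(np.random.default_rng(
                [settings.seed & 0x7FFFFFFF, fold_no + 17]).integers(2**31)),
            prior_df=settings.prior_df, r2_residual=settings.r2_residual,
            fixed_variances=dict(settings.fixed_variances), fixed_mu=settings.fixed_mu,
        )
        res, _ = fit_model_by_name(model_name, sub_bundle, settings=fold_settings,
                                   mask=sub_mask, validate=False)
        # leakage guard: masked records must have no fitted (training) value
        assert not np.any(np.isfinite(res.fitted[sub_mask]))
        rows += _site_correlations(sub_pheno.df, y_all[sub_idx], res.predicted,
                                   sub_mask, meta, value_mode)
    return AccuracyReport(model_name=model_name, scheme=plan.scheme,
                          correlations=pd.DataFrame(rows))


def summarize_reports(reports: list[AccuracyReport]) -> dict[str, pd.DataFrame]:
    """Long and wide (site × model) accuracy tables plus scheme averages.

    The wide table has one row per site and one column per model, the layout
    of the standard multi-site accuracy tables; the best model per site is
    flagged in the long table.
    """
    long = pd.concat([r.summary() for r in reports], ignore_index=True)
    long["best_in_site"] = False
    for (scheme, site), grp in long.groupby(["scheme", "site"]):
        best = grp["mean"].idxmax()
        if pd.notna(best):
            long.loc[best, "best_in_site"] = True
    wide = {}
    for scheme, grp in long.groupby("scheme"):
        wide[scheme] = grp.pivot_table(index="site", columns="model", values="mean")
    scheme_avg = long.groupby(["scheme", "model"])["mean"].mean().reset_index()
    scheme_avg = scheme_avg.rename(columns={"mean": "average_accuracy"})
    return {"long": long, "wide": wide, "scheme_averages": scheme_avg}
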