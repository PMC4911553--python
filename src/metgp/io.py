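"""Delimited-text readers and writers for the four trial inputs.

Formats (CSV or TSV, autodetected from the extension):

* markers — first column ``line``, one column per marker;
* pedigree — columns ``id, parent1, parent2`` (empty = unknown parent);
* phenotypes — long format ``site, line, block, rep, is_check, <trait...>``;
* covariables — first column ``site``, one column per covariable.

Readers validate cross-references and mean-impute missing marker codes
(imputation keeps each column's mean, hence G's expectation).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data import DataBundle, EnvCovariateTable, MarkerMatrix, Pedigree, PhenotypeTable
from .simulate import SimTruth

PathLike = Union[str, Path]


def _sep(path: PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_markers(markers: MarkerMatrix, path: PathLike) -> None:
    df = pd.DataFrame(markers.codes,
                      columns=[f"m{k + 1}" for k in range(markers.n_markers)])
    df.insert(0, "line", markers.line_ids)
    df.to_csv(path, sep=_sep(path), index=False)


def read_markers(
    path: PathLike, maf_filter: Optional[float] = None
) -> tuple[MarkerMatrix, dict]:
    """Read a marker table; mean-impute missing codes; optional MAF filter.

    Returns the matrix and a validation report (imputed cells, dropped
    columns).  The MAF filter is off by default.
    """
    df = pd.read_csv(path, sep=_sep(path))
    if "line" not in df.columns:
        raise ValueError(f"marker file {path} lacks a 'line' column")
    ids = df["line"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate line ids in marker file: {dup[:10]}")
    X = df.drop(columns="line").to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        col_means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_means[idx[1]]
    report = {"n_imputed": n_missing, "n_dropped_columns": 0}
    if maf_filter is not None:
        scale = 2.0 if X.max() > 1.0 else 1.0
        freq = X.mean(axis=0) / scale
        maf = np.minimum(freq, 1.0 - freq)
        keep = maf >= maf_filter
        report["n_dropped_columns"] = int((~keep).sum())
        X = X[:, keep]
    return MarkerMatrix(line_ids=ids, codes=X), report


def write_pedigree(pedigree: Pedigree, path: PathLike) -> None:
    df = pd.DataFrame(pedigree.records, columns=["id", "parent1", "parent2"])
    df.to_csv(path, sep=_sep(path), index=False)


def read_pedigree(path: PathLike) -> Pedigree:
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    need = {"id", "parent1", "parent2"}
    if not need <= set(df.columns):
        raise ValueError(f"pedigree file {path} must have columns {sorted(need)}")
    records = [
        (r.id, r.parent1 or None, r.parent2 or None)
        for r in df.itertuples(index=False)
    ]
    return Pedigree(records=records)


def write_phenotypes(phenotypes: PhenotypeTable, path: PathLike,
                     trait: str = "grain_yield") -> None:
    df = phenotypes.df.rename(columns={"y": trait})
    df.to_csv(path, sep=_sep(path), index=False)


def read_phenotypes(path: PathLike, trait: Optional[str] = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep=_sep(path))
    base = ["site", "line", "block", "rep", "is_check"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {missing}")
    traits = [c for c in df.columns if c not in base]
    if trait is None:
        if not traits:
            raise ValueError(f"phenotype file {path} has no trait column")
        trait = traits[0]
    if trait not in df.columns:
        raise ValueError(f"trait '{trait}' not in phenotype file (has {traits})")
    out = df[base].copy()
    out["y"] = df[trait].astype(float)
    out["is_check"] = out["is_check"].astype(bool)
    return PhenotypeTable(out)


def write_env_covariates(env: EnvCovariateTable, path: PathLike) -> None:
    df = pd.DataFrame(env.values, columns=env.covariable_names)
    df.insert(0, "site", env.site_ids)
    df.to_csv(path, sep=_sep(path), index=False)


def read_env_covariates(path: PathLike) -> EnvCovariateTable:
    df = pd.read_csv(path, sep=_sep(path))
    if "site" not in df.columns:
        raise ValueError(f"covariable file {path} lacks a 'site' column")
    sites = df["site"].astype(str).tolist()
    names = [c for c in df.columns if c != "site"]
    return EnvCovariateTable(site_ids=sites, values=df[names].to_numpy(dtype=float),
                             covariable_names=names)


def write_truth(truth: SimTruth, path: PathLike) -> None:
    """SimTruth as a JSON sidecar (arrays as nested lists)."""
    d = {
        "line_ids": truth.line_ids,
        "site_ids": truth.site_ids,
        "true_genetic_values": truth.true_genetic_values.tolist(),
        "true_marker_effects": truth.true_marker_effects.tolist(),
        "true_variance_components": truth.true_variance_components,
        "target_variances": truth.target_variances,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(d))


def read_truth(path: PathLike) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        line_ids=d["line_ids"],
        site_ids=d["site_ids"],
        true_genetic_values=np.asarray(d["true_genetic_values"]),
        true_marker_effects=np.asarray(d["true_marker_effects"]),
        true_variance_components=d["true_variance_components"],
        target_variances=d["target_variances"],
        components={},
        seed=d["seed"],
    )


def write_bundle(bundle: DataBundle, outdir: PathLike, trait: str = "grain_yield",
                 truth: Optional[SimTruth] = None) -> dict[str, Path]:
    """Write a full bundle to a directory; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"phenotypes": outdir / "phenotypes.csv"}
    write_phenotypes(bundle.phenotypes, paths["phenotypes"], trait=trait)
    if bundle.markers is not None:
        paths["markers"] = outdir / "markers.csv"
        write_markers(bundle.markers, paths["markers"])
    if bundle.pedigree is not None:
        paths["pedigree"] = outdir / "pedigree.csv"
        write_pedigree(bundle.pedigree, paths["pedigree"])
    if bundle.env_covariates is not None:
        paths["covariables"] = outdir / "covariables.csv"
        write_env_covariates(bundle.env_covariates, paths["covariables"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        write_truth(truth, paths["truth"])
    return paths


def read_bundle(
    phenotypes: PathLike,
    markers: Optional[PathLike] = None,
    pedigree: Optional[PathLike] = None,
    covariables: Optional[PathLike] = None,
    trait: Optional[str] = None,
    maf_filter: Optional[float] = None,
) -> tuple[DataBundle, dict]:
    """Read and cross-validate a bundle; returns (bundle, validation report)."""
    pheno = read_phenotypes(phenotypes, trait=trait)
    report: dict = {}
    mk = ped = env = None
    if markers is not None:
        mk, report = read_markers(markers, maf_filter=maf_filter)
    if pedigree is not None:
        ped = read_pedigree(pedigree)
    if covariables is not None:
        env = read_env_covariates(covariables)
    bundle = DataBundle(phenotypes=pheno, markers=mk, pedigree=ped, env_covariates=env)
    bundle.validate()
    return bundle, report
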