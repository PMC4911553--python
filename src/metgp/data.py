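"""Core data containers for multi-environment trial (MET) genomic prediction.

The canonical in-memory objects are thin dataclasses around numpy arrays and
pandas DataFrames:

* :class:`MarkerMatrix` — lines × markers codes (DArTseq-style presence/absence
  {0,1} or SNP dosage {0,1,2}).
* :class:`Pedigree` — (id, parent1, parent2) records, topologically orderable.
* :class:`EnvCovariateTable` — site × Q environmental covariables (e.g. mean /
  min / max temperatures over growth phases).
* :class:`PhenotypeTable` — plot-level records of a p-rep augmented design.

Row order of ``MarkerMatrix.codes`` defines the canonical line order for every
kernel derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["site", "line", "block", "rep", "is_check", "y"]


@dataclass
class MarkerMatrix:
    line_ids: list[str]
    codes: np.ndarray  # lines × markers, float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("marker codes must be a 2-D lines × markers array")
        if len(self.line_ids) != self.codes.shape[0]:
            raise ValueError(
                f"{len(self.line_ids)} line ids but {self.codes.shape[0]} marker rows"
            )

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def row_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.line_ids)}


@dataclass
class Pedigree:
    """Parent records; unknown parents are ``None`` (founders)."""

    records: list[tuple[str, Optional[str], Optional[str]]]

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def topological_order(self) -> list[str]:
        """Return ids ordered parents-before-offspring.

        Raises ``ValueError`` naming a cycle member if the pedigree is cyclic.
        """
        parents = {i: {p for p in (p1, p2) if p is not None} for i, p1, p2 in self.records}
        order: list[str] = []
        placed: set[str] = set()
        pending = dict(parents)
        while pending:
            ready = [i for i, ps in pending.items() if ps <= placed]
            if not ready:
                cyc = sorted(pending)[0]
                raise ValueError(f"pedigree contains a cycle involving '{cyc}'")
            for i in ready:
                order.append(i)
                placed.add(i)
                del pending[i]
        return order


@dataclass
class EnvCovariateTable:
    site_ids: list[str]
    values: np.ndarray  # sites × Q
    covariable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariable values must be a 2-D site × Q array")
        if len(self.site_ids) != self.values.shape[0]:
            raise ValueError("site_ids length does not match value rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariable table contains non-finite values")
        if not self.covariable_names:
            self.covariable_names = [f"ec_{q + 1}" for q in range(self.values.shape[1])]

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


class PhenotypeTable:
    """Plot-level phenotype records in long format.

    Columns: ``site, line, block, rep, is_check, y`` (``y`` may be NaN for a
    design skeleton with no trait values yet).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table is missing columns {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.df["site"]))

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.df["line"]))

    @property
    def accession_lines(self) -> list[str]:
        return list(pd.unique(self.df.loc[~self.df["is_check"], "line"]))

    def subset(self, rows: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[np.asarray(rows)].reset_index(drop=True))

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.df.copy())


@dataclass
class DataBundle:
    """Everything one trait's analysis needs, cross-referenced."""

    phenotypes: PhenotypeTable
    markers: Optional[MarkerMatrix] = None
    pedigree: Optional[Pedigree] = None
    env_covariates: Optional[EnvCovariateTable] = None

    def validate(self) -> None:
        pheno_lines = set(self.phenotypes.lines)
        if self.markers is not None:
            known = set(self.markers.line_ids)
            missing = sorted(pheno_lines - known)
            if missing:
                raise ValueError(f"phenotype lines absent from marker matrix: {missing[:10]}")
        if self.pedigree is not None:
            known = set(self.pedigree.ids)
            missing = sorted(pheno_lines - known)
            if missing:
                raise ValueError(f"phenotype lines absent from pedigree: {missing[:10]}")
        if self.env_covariates is not None:
            known = set(self.env_covariates.site_ids)
            missing = sorted(set(self.phenotypes.sites) - known)
            if missing:
                raise ValueError(f"phenotype sites absent from covariable table: {missing}")
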