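"""Genotype/phenotype containers, CSV readers and validation.

Genotype files are plain CSV with a header row of marker IDs, a first
column of line IDs and biallelic dosage codes in {0, 1, 2}.  Phenotype
files are long-format CSV with columns ``line, family, env, trait, value``.
Monomorphic markers are dropped on load (their standard deviation is zero,
so neither the relationship matrix nor the standardization is defined for
them) and missing dosages are rejected rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["line", "family", "env", "trait", "value"]


class ValidationError(ValueError):
    """Raised when an input file violates the data contract."""


def standardize_markers(X: np.ndarray) -> np.ndarray:
    """Center and standardize a dosage matrix column-wise.

    Columns are centered to mean zero and scaled by the population
    standard deviation (divisor ``n``), so every column of the result has
    sum of squares exactly ``n`` and the genomic relationship matrix
    ``MM'/p`` has mean diagonal exactly 1.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Dosage matrix without constant columns.

    Returns
    -------
    M : ndarray of shape (n, p)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("dosage matrix must be 2-dimensional")
    sd = X.std(axis=0)  # population SD (ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValidationError(
            f"constant column(s) at index {bad.tolist()}: remove monomorphic "
            "markers (preprocessing) before standardizing"
        )
    return (X - X.mean(axis=0)) / sd


@dataclass
class MarkerMatrix:
    """Line-indexed dosage matrix with its standardized form.

    Attributes
    ----------
    line_ids : list of str
        Unique line identifiers, in genotype-file order.  All downstream
        matrices (M, G, G*) inherit this row order.
    marker_ids : list of str
        Unique marker identifiers after monomorphic removal.
    X : ndarray of shape (n, p)
        Dosages in {0, 1, 2}.
    M : ndarray of shape (n, p)
        Centered, population-SD standardized dosages.
    """

    line_ids: list[str]
    marker_ids: list[str]
    X: np.ndarray
    M: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line IDs in genotype matrix")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker IDs in genotype matrix")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.X.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        self.M = standardize_markers(self.X)

    @property
    def n(self) -> int:
        return len(self.line_ids)

    @property
    def p(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_dosage(
        cls,
        X: np.ndarray,
        line_ids: Sequence[str],
        marker_ids: Sequence[str],
        drop_monomorphic: bool = True,
    ) -> "MarkerMatrix":
        """Build a MarkerMatrix, optionally dropping monomorphic markers."""
        X = np.asarray(X, dtype=float)
        marker_ids = list(marker_ids)
        if drop_monomorphic and X.size:
            keep = X.std(axis=0) > 0
            n_dropped = int((~keep).sum())
            if n_dropped:
                dropped = [m for m, k in zip(marker_ids, keep) if not k]
                logger.warning(
                    "dropping %d monomorphic marker(s): %s",
                    n_dropped,
                    ", ".join(dropped[:10]) + ("..." if n_dropped > 10 else ""),
                )
                X = X[:, keep]
                marker_ids = [m for m, k in zip(marker_ids, keep) if k]
        return cls(list(line_ids), marker_ids, X)


@dataclass
class PhenotypeTable:
    """Long-format phenotype records with family/environment/trait labels."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing column(s): {missing}")
        df = df[PHENOTYPE_COLUMNS].copy()
        for col in ("line", "family", "env", "trait"):
            df[col] = df[col].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if df["value"].isna().any():
            raise ValidationError("phenotype table contains missing values")
        dup = df.duplicated(subset=["line", "env", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                "duplicate phenotype record for "
                f"(line={row['line']}, env={row['env']}, trait={row['trait']})"
            )
        fam = df.groupby("line")["family"].nunique()
        if (fam > 1).any():
            raise ValidationError(
                f"line(s) assigned to more than one family: "
                f"{fam[fam > 1].index.tolist()}"
            )
        self.records = df.reset_index(drop=True)

    @property
    def families(self) -> list[str]:
        """Family IDs in first-appearance order."""
        return list(dict.fromkeys(self.records["family"]))

    @property
    def environments(self) -> list[str]:
        return list(dict.fromkeys(self.records["env"]))

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.records["trait"]))

    def family_of(self) -> dict[str, str]:
        """Mapping line ID -> family ID."""
        return dict(zip(self.records["line"], self.records["family"]))


@dataclass
class Dataset:
    """A MarkerMatrix joined with its phenotype table."""

    markers: MarkerMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        if self.markers.n < 3:
            raise ValidationError("need at least 3 genotyped lines")
        known = set(self.markers.line_ids)
        pheno_lines = set(self.phenotypes.records["line"])
        orphans = sorted(pheno_lines - known)
        if orphans:
            raise ValidationError(
                f"phenotype line(s) absent from genotype matrix: {orphans}"
            )

    @property
    def families(self) -> list[str]:
        return self.phenotypes.families

    def family_labels(self) -> np.ndarray:
        """Family label per genotyped line (line order); '' if unphenotyped."""
        fam = self.phenotypes.family_of()
        return np.array([fam.get(l, "") for l in self.markers.line_ids])


def load_dataset(genotype_path: str | Path, phenotype_path: str | Path) -> Dataset:
    """Load and validate a genotype + phenotype CSV pair.

    Monomorphic markers are dropped with a logged warning; dosages outside
    {0, 1, 2} or missing cells raise :class:`ValidationError` naming the
    offending row and column.
    """
    genotype_path = Path(genotype_path)
    phenotype_path = Path(phenotype_path)
    geno = pd.read_csv(genotype_path, dtype={0: str})
    if geno.shape[1] < 2:
        raise ValidationError(f"{genotype_path}: no marker columns found")
    line_col = geno.columns[0]
    line_ids = geno[line_col].tolist()
    marker_ids = [str(c) for c in geno.columns[1:]]
    body = geno.iloc[:, 1:]
    values = body.to_numpy(dtype=float, na_value=np.nan)
    bad = ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = values[i, j]
        what = "missing" if np.isnan(cell) else f"value {cell!r}"
        raise ValidationError(
            f"{genotype_path}: {what} dosage at line {line_ids[i]!r}, "
            f"marker {marker_ids[j]!r} (dosages must be 0, 1 or 2)"
        )
    markers = MarkerMatrix.from_dosage(values, line_ids, marker_ids)
    pheno = PhenotypeTable(pd.read_csv(phenotype_path, dtype=str))
    return Dataset(markers, pheno)


def write_dataset(
    dataset: Dataset, genotype_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write a Dataset back to the genotype/phenotype CSV dialect."""
    geno = pd.DataFrame(
        dataset.markers.X.astype(int),
        columns=dataset.markers.marker_ids,
    )
    geno.insert(0, "line", dataset.markers.line_ids)
    geno.to_csv(genotype_path, index=False)
    dataset.phenotypes.records.to_csv(phenotype_path, index=False)
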