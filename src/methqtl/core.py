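"""Shared containers for genotype and methylation data.

Orientation conventions used throughout the package:

* methylation matrices (beta values or normalized values) are pandas
  DataFrames with **samples as rows** and **probes as columns**;
* genotype dosages are DataFrames with samples as rows and SNPs as columns,
  values in [0, 2] counting copies of the minor-tagged allele;
* probe manifests are DataFrames indexed by probe id with columns
  ``chrom``, ``pos`` (0-based CpG cytosine coordinate) and optional
  ``annotation`` / ``in_gene_body`` / ``mappable`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "NormalizedMethylation", "validate_manifest"]


@dataclass
class GenotypeTable:
    """Per-sample allelic dosages plus SNP coordinates.

    Parameters
    ----------
    dosages
        samples x SNPs DataFrame with values in [0, 2].
    snps
        DataFrame indexed by SNP id with columns ``chrom`` and ``pos``.
        A ``maf`` column is (re)computed from the dosages on construction:
        ``maf = min(f, 1 - f)`` with ``f = mean(dosage) / 2``.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage columns and SNP table rows do not match")
        if not self.dosages.columns.equals(self.snps.index):
            raise ValueError("dosage columns must equal the SNP table index")
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        f = vals.mean(axis=0) / 2.0 if vals.size else np.empty(0)
        self.snps = self.snps.copy()
        self.snps["maf"] = np.minimum(f, 1.0 - f)

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        return GenotypeTable(self.dosages.loc[sample_ids], self.snps.drop(columns="maf"))


@dataclass
class NormalizedMethylation:
    """Methylation on the standard-normal scale after quantile normalization.

    ``values`` is samples x probes; ``strategy`` records which normalization
    produced it and ``n_pcs_removed`` how many principal components were
    regressed out afterwards (0 if none).
    """

    values: pd.DataFrame
    strategy: str = "two_stage"
    n_pcs_removed: int = 0

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns


_MANIFEST_REQUIRED = ("chrom", "pos")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check a probe manifest for required columns, unique ids, pos >= 0."""
    for col in _MANIFEST_REQUIRED:
        if col not in manifest.columns:
            raise ValueError(f"probe manifest lacks required column {col!r}")
    if manifest.index.has_duplicates:
        raise ValueError("probe ids must be unique")
    if (manifest["pos"] < 0).any():
        raise ValueError("probe positions must be non-negative")
    return manifest
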