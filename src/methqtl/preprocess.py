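"""Probe filtering, quantile normalization and PCA confounder removal.

Array beta values are bounded, bimodal and non-Gaussian, so association
testing works on rank-normalized data: each value is replaced by the standard
normal quantile of its (rank - 0.5) / n position.  The two-stage scheme
normalizes across probes within each individual first (removing array-wide
intensity differences between individuals) and then across individuals at
each probe (making every probe marginally standard normal).  Hidden
confounders that load broadly across probes are then removed by regressing
each probe on the leading sample-space principal components; the number of
components is chosen to maximize meQTL yield.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, NormalizedMethylation, validate_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "filter_probes",
    "quantile_normalize",
    "remove_pcs",
    "select_num_pcs",
    "pc_confounder_report",
]

_STRATEGIES = ("two_stage", "by_individual", "by_probe", "none")
_AUTOSOME_OK = tuple(f"chr{i}" for i in range(1, 23)) + tuple(str(i) for i in range(1, 23))
_SEX_DEFAULT = frozenset({"chrX", "chrY", "X", "Y"})


def filter_probes(
    manifest: pd.DataFrame,
    snp_positions: pd.DataFrame | None = None,
    sex_chroms=_SEX_DEFAULT,
    mappability_flags=None,
    probe_interval: int = 50,
) -> pd.DataFrame:
    """Apply the three probe exclusion rules, in order, first-rule-wins.

    1. non-uniquely-mapped probes (``mappability_flags`` is the set of probe
       ids that failed unique mapping and are removed);
    2. probes on sex chromosomes;
    3. probes whose target interval — the ``probe_interval`` bases ending at
       the CpG, i.e. positions in (pos - probe_interval, pos] — contains a
       panel SNP (``snp_positions``: DataFrame with ``chrom`` and ``pos``).

    Returns the retained manifest; per-rule removal counts are attached as
    ``result.attrs['removed']``.  Unknown chromosome names pass through with
    a logged warning.
    """
    validate_manifest(manifest)
    sex_chroms = set(sex_chroms)
    unknown = set(manifest["chrom"]) - set(_AUTOSOME_OK) - sex_chroms
    if unknown:
        logger.warning("unknown chromosome names pass through unfiltered: %s", sorted(unknown))

    removed = {"non_unique": 0, "sex_chrom": 0, "snp_overlap": 0}
    keep = np.ones(len(manifest), dtype=bool)

    if mappability_flags:
        bad = manifest.index.isin(set(mappability_flags))
        removed["non_unique"] = int(bad.sum())
        keep &= ~bad

    sex = manifest["chrom"].isin(sex_chroms).to_numpy() & keep
    removed["sex_chrom"] = int(sex.sum())
    keep &= ~sex

    if snp_positions is not None and len(snp_positions):
        hit = np.zeros(len(manifest), dtype=bool)
        for chrom, grp in snp_positions.groupby("chrom"):
            pos_sorted = np.sort(grp["pos"].to_numpy())
            on = manifest["chrom"].to_numpy() == chrom
            probe_pos = manifest["pos"].to_numpy()[on]
            # SNP in (pos - probe_interval, pos]
            lo = np.searchsorted(pos_sorted, probe_pos - probe_interval, side="right")
            hi = np.searchsorted(pos_sorted, probe_pos, side="right")
            hit[on] = hi > lo
        hit &= keep
        removed["snp_overlap"] = int(hit.sum())
        keep &= ~hit

    out = manifest.loc[keep].copy()
    out.attrs["removed"] = removed
    return out


def _rank_normal(a: np.ndarray, axis: int) -> np.ndarray:
    """Phi^-1((rank - 0.5) / n) along an axis; ties get average ranks."""
    n = a.shape[axis]
    ranks = np.apply_along_axis(stats.rankdata, axis, a)
    return stats.norm.ppf((ranks - 0.5) / n)


def quantile_normalize(beta: pd.DataFrame, strategy: str = "two_stage") -> NormalizedMethylation:
    """Rank-normalize beta values to a standard normal.

    Strategies: ``two_stage`` — across probes within each individual, then
    across individuals at each probe; ``by_individual`` / ``by_probe`` — only
    the respective stage; ``none`` — identity.  Missing values are rejected.
    The transform preserves order within each normalized axis; a constant
    vector (all ties) maps to all zeros.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {_STRATEGIES}")
    vals = beta.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("beta matrix contains missing values; impute or drop before normalizing")
    if strategy == "none":
        out = vals.copy()
    else:
        out = vals
        if strategy in ("two_stage", "by_individual"):
            out = _rank_normal(out, axis=1)  # across probes, within each sample
        if strategy in ("two_stage", "by_probe"):
            if np.any(np.ptp(out, axis=0) == 0):
                logger.warning("constant probe column(s): all-tie ranks map to 0")
            out = _rank_normal(out, axis=0)  # across samples, within each probe
        elif strategy == "by_individual" and np.any(np.ptp(vals, axis=1) == 0):
            logger.warning("constant sample row(s): all-tie ranks map to 0")
    return NormalizedMethylation(
        pd.DataFrame(out, index=beta.index, columns=beta.columns), strategy=strategy
    )


def remove_pcs(norm: NormalizedMethylation, k: int) -> NormalizedMethylation:
    """Regress each probe on the top-k sample-space PCs; return residuals.

    ``k = 0`` returns the input unchanged.  The regression includes an
    intercept, so residual columns are exactly orthogonal to each removed
    component (and centered).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = norm.values.shape[0]
    if k >= n:
        raise ValueError(f"cannot remove {k} PCs from {n} samples")
    if k == 0:
        return NormalizedMethylation(norm.values.copy(), norm.strategy, norm.n_pcs_removed)
    x = norm.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    uk = u[:, :k]
    resid = xc - uk @ (uk.T @ xc)
    return NormalizedMethylation(
        pd.DataFrame(resid, index=norm.values.index, columns=norm.values.columns),
        norm.strategy,
        norm.n_pcs_removed + k,
    )


def select_num_pcs(
    norm: NormalizedMethylation,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    k_grid=(0, 1, 2, 3, 4, 5, 6),
    fdr: float = 0.10,
    window: int = 3000,
    maf_min: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Pick the number of removed PCs that maximizes meQTL yield.

    Runs the cis scan for every k in ``k_grid`` and counts probes with at
    least one association at ``q <= fdr``; ties break toward smaller k.
    Returns ``(k_star, table)`` with one row per k.
    """
    from .mapping import cis_scan

    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    rows = []
    for k in k_grid:
        assoc = cis_scan(remove_pcs(norm, k), geno, manifest, window=window, maf_min=maf_min)
        if assoc.empty:
            count = 0
        else:
            count = int((assoc.groupby("probe_id")["q_value"].min() <= fdr).sum())
        rows.append({"k": k, "n_meqtl_probes": count})
    table = pd.DataFrame(rows)
    k_star = int(table.sort_values(["n_meqtl_probes", "k"], ascending=[False, True]).iloc[0]["k"])
    return k_star, table


def pc_confounder_report(
    norm: NormalizedMethylation, covariates: pd.DataFrame, n_pcs: int = 10
) -> pd.DataFrame:
    """Test whether known factors associate with the leading PCs.

    Continuous covariates get a Pearson correlation test against each PC
    score vector; categorical covariates a one-way ANOVA F-test.  Covariates
    with a single level are skipped with a warning.  The output carries one
    row per (PC, covariate) with the statistic, p-value and that PC's
    variance explained.
    """
    if not covariates.index.equals(norm.values.index):
        covariates = covariates.reindex(norm.values.index)
        if covariates.isna().any().any():
            raise ValueError("covariates are not aligned to the methylation samples")
    x = norm.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var_explained = s**2 / np.sum(s**2)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]

    rows = []
    for name in covariates.columns:
        col = covariates[name]
        numeric = pd.api.types.is_numeric_dtype(col)
        if col.nunique() < 2:
            logger.warning("covariate %s has a single level; skipped", name)
            continue
        for i in range(n_pcs):
            pc = scores[:, i]
            if numeric:
                r, p = stats.pearsonr(col.to_numpy(dtype=float), pc)
                stat = r
            else:
                groups = [pc[(col == lev).to_numpy()] for lev in col.unique()]
                stat, p = stats.f_oneway(*groups)
            rows.append(
                {
                    "pc": i + 1,
                    "covariate": name,
                    "stat": float(stat),
                    "p_value": float(p),
                    "var_explained": float(var_explained[i]),
                }
            )
    return pd.DataFrame(rows)
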