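"""Cross-phenotype QTL sharing: foreground testing against a matched null.

Given SNPs already known to be QTLs for another regulatory phenotype
(expression, DNase I sensitivity, histone marks, PolII, GWAS hits), this
module asks how often they are also associated with methylation at probes
within 3 kb, and whether that proportion exceeds what matched random SNP
sets achieve.  "Matched" means matching only the count and the
within-window-of-a-probe constraint: B random draws of the same size from
the testable SNP universe give the null distribution, and the empirical
p-value uses the add-one (b + 1) / (B + 1) estimator so it is never zero.
Each foreground receives its own FDR computed over its own tests only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, NormalizedMethylation
from .mapping import cis_scan, estimate_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ContingencyResult",
    "test_foreground",
    "matched_permutation_null",
    "enrichment_analysis",
    "classify_direction",
    "annotation_enrichment",
    "snp_universe",
]


@dataclass
class EnrichmentResult:
    """Foreground proportion significant, its permutation null, directions."""

    label: str
    n_tested: int
    prop_significant: float
    n_positive: int
    n_negative: int
    per_snp: pd.DataFrame
    null_mean: float | None = None
    empirical_p: float | None = None
    B: int | None = None
    null: np.ndarray | None = None


@dataclass
class ContingencyResult:
    """2x2 chi-square test of meQTL CpGs against an annotation feature."""

    feature: str
    a: int  # meQTL CpGs in feature
    b: int  # other probes in feature
    c: int  # meQTL CpGs outside
    d: int  # other probes outside
    chi_square: float
    p_value: float
    direction: str  # "enriched" or "depleted"


def _foreground_scan(fg_snps, meth, geno: GenotypeTable, manifest, window: int) -> pd.DataFrame:
    missing = [s for s in fg_snps if s not in geno.snp_ids]
    if missing:
        raise ValueError(f"foreground SNPs missing from genotype table: {missing[:5]}")
    sub = GenotypeTable(geno.dosages[list(fg_snps)], geno.snps.loc[list(fg_snps)].drop(columns="maf"))
    return cis_scan(meth, sub, manifest, window=window, maf_min=0.0, qvalues=False)


def test_foreground(
    fg_snps,
    meth,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    window: int = 3000,
    fdr: float = 0.10,
    fg_direction: pd.Series | dict | None = None,
    label: str = "",
    pi0: float | None = 1.0,
) -> EnrichmentResult:
    """Test each foreground SNP against all probes within ``window`` bp.

    q-values are computed over this foreground's tests only; a SNP counts as
    significant when any of its probes reaches ``q <= fdr``.  Direction
    counts use the sign of each significant SNP's most significant slope,
    multiplied by the foreground phenotype's effect sign when provided.
    SNPs with no probe in the window are dropped (and not counted in
    ``n_tested``), with a warning.
    """
    fg_snps = list(dict.fromkeys(fg_snps))
    assoc = _foreground_scan(fg_snps, meth, geno, manifest, window)
    tested = assoc["snp_id"].unique()
    dropped = set(fg_snps) - set(tested)
    if dropped:
        logger.warning("%d foreground SNPs have no probe within %d bp; dropped", len(dropped), window)
    if assoc.empty:
        return EnrichmentResult(label, 0, np.nan, 0, 0, assoc)
    assoc = assoc.copy()
    assoc["q_value"], _ = estimate_qvalues(assoc["p_value"].to_numpy(), pi0=pi0)
    per_snp = assoc.loc[assoc.groupby("snp_id")["p_value"].idxmin()].set_index("snp_id")
    per_snp["min_q"] = assoc.groupby("snp_id")["q_value"].min()
    per_snp["significant"] = per_snp["min_q"] <= fdr
    sig = per_snp[per_snp["significant"]]
    n_pos, n_neg = classify_direction(sig, fg_direction)
    return EnrichmentResult(
        label=label,
        n_tested=len(per_snp),
        prop_significant=float(per_snp["significant"].mean()),
        n_positive=n_pos,
        n_negative=n_neg,
        per_snp=per_snp.reset_index(),
    )


def snp_universe(
    geno: GenotypeTable, manifest: pd.DataFrame, window: int = 3000, maf_min: float = 0.05
) -> list[str]:
    """SNPs passing the MAF filter that lie within ``window`` of >= 1 probe."""
    keep = []
    snps = geno.snps[geno.snps["maf"] > maf_min]
    for chrom, grp in snps.groupby("chrom"):
        ppos = np.sort(manifest.loc[manifest["chrom"] == chrom, "pos"].to_numpy())
        if ppos.size == 0:
            continue
        spos = grp["pos"].to_numpy()
        idx = np.clip(np.searchsorted(ppos, spos), 1, len(ppos) - 1)
        near = np.minimum(np.abs(spos - ppos[idx - 1]), np.abs(spos - ppos[np.minimum(idx, len(ppos) - 1)]))
        keep.extend(grp.index[near <= window])
    return keep


def matched_permutation_null(
    n_fg: int,
    universe,
    meth,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    window: int = 3000,
    fdr: float = 0.10,
    B: int = 999,
    seed: int = 0,
    observed_prop: float | None = None,
    pi0: float | None = 1.0,
) -> tuple[np.ndarray, float, float | None]:
    """Null distribution of the foreground proportion under matched sampling.

    Draws ``B`` samples of ``n_fg`` SNPs without replacement from
    ``universe``, recomputes the per-draw proportion significant (each draw
    gets its own q-values over its own tests), and returns
    ``(null, null_mean, empirical_p)`` with
    ``empirical_p = (#{null >= observed} + 1) / (B + 1)``.

    One scan over the whole universe is cached; the B resamples only regroup
    its p-values, which is exactly equivalent to rescanning each draw.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    universe = list(dict.fromkeys(universe))
    if n_fg > len(universe):
        raise ValueError("n_fg exceeds the universe size")
    assoc = _foreground_scan(universe, meth, geno, manifest, window)
    # cache: per-SNP p-value arrays from the single scan
    p_by_snp = {s: grp["p_value"].to_numpy() for s, grp in assoc.groupby("snp_id")}
    testable = [s for s in universe if s in p_by_snp]
    if len(testable) < len(universe):
        logger.warning(
            "%d universe SNPs have no probe within the window; excluded from resampling",
            len(universe) - len(testable),
        )
    if n_fg > len(testable):
        raise ValueError("n_fg exceeds the testable universe size")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    arrs = [p_by_snp[s] for s in testable]
    sizes = np.array([a.size for a in arrs])
    for b in range(B):
        take = rng.choice(len(testable), size=n_fg, replace=False)
        p_cat = np.concatenate([arrs[i] for i in take])
        q, _ = estimate_qvalues(p_cat, pi0=pi0)
        bounds = np.concatenate([[0], np.cumsum(sizes[take])])
        min_q = np.minimum.reduceat(q, bounds[:-1])
        null[b] = np.mean(min_q <= fdr)
    null_mean = float(null.mean())
    emp = None
    if observed_prop is not None:
        emp = float((np.sum(null >= observed_prop) + 1) / (B + 1))
    return null, null_mean, emp


def enrichment_analysis(
    fg_snps,
    meth,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    window: int = 3000,
    fdr: float = 0.10,
    B: int = 999,
    seed: int = 0,
    fg_direction=None,
    label: str = "",
    universe=None,
    maf_min: float = 0.05,
    pi0: float | None = 1.0,
) -> EnrichmentResult:
    """Foreground test plus matched-permutation null in one call."""
    res = test_foreground(
        fg_snps, meth, geno, manifest, window=window, fdr=fdr,
        fg_direction=fg_direction, label=label, pi0=pi0,
    )
    if universe is None:
        universe = snp_universe(geno, manifest, window=window, maf_min=maf_min)
    null, null_mean, emp = matched_permutation_null(
        res.n_tested, universe, meth, geno, manifest,
        window=window, fdr=fdr, B=B, seed=seed,
        observed_prop=res.prop_significant, pi0=pi0,
    )
    res.null, res.null_mean, res.empirical_p, res.B = null, null_mean, emp, B
    return res


def classify_direction(lead_rows: pd.DataFrame, fg_direction=None) -> tuple[int, int]:
    """Count positive and negative effect directions among lead associations.

    The per-SNP sign is sign(methylation slope), multiplied by the sign of
    the foreground phenotype effect when ``fg_direction`` (a per-SNP mapping
    or Series) is supplied.  Zero slopes count as neither.
    """
    if lead_rows.empty:
        return 0, 0
    signs = np.sign(lead_rows["effect"].to_numpy())
    if fg_direction is not None:
        fg = pd.Series(fg_direction)
        snp_ids = (
            lead_rows["snp_id"] if "snp_id" in lead_rows.columns else pd.Series(lead_rows.index)
        )
        signs = signs * np.sign(fg.reindex(snp_ids).fillna(1.0).to_numpy())
    return int((signs > 0).sum()), int((signs < 0).sum())


def annotation_enrichment(meqtl_probes, manifest: pd.DataFrame, feature: str) -> ContingencyResult:
    """Chi-square test of meQTL CpGs for enrichment in an annotation class.

    Builds the 2x2 table (meQTL probes in/out of ``feature`` against all
    other probes) and applies Pearson's chi-square without continuity
    correction, 1 df.  Any expected cell below 1 raises (an exact test would
    be needed).
    """
    if "annotation" not in manifest.columns:
        raise ValueError("manifest has no 'annotation' column")
    meqtl_probes = set(meqtl_probes)
    is_meqtl = manifest.index.isin(meqtl_probes)
    in_feat = (manifest["annotation"] == feature).to_numpy()
    a = int(np.sum(is_meqtl & in_feat))
    b = int(np.sum(~is_meqtl & in_feat))
    c = int(np.sum(is_meqtl & ~in_feat))
    d = int(np.sum(~is_meqtl & ~in_feat))
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise ValueError("degenerate contingency table")
    expected_min = min(row1 * col1, row1 * col2, row2 * col1, row2 * col2) / n
    if expected_min < 1:
        raise ValueError("expected cell count below 1; use an exact test")
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    expected_a = col1 * row1 / n
    direction = "enriched" if a > expected_a else "depleted"
    return ContingencyResult(feature, a, b, c, d, float(chi2), p, direction)
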