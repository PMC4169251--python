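"""Cis meQTL mapping: association scan, FDR, lead SNPs, candidate causal SNPs.

The scan regresses rank-normalized methylation at each CpG probe on allelic
dosage at every SNP within a window (default 3 kb on each side, i.e. a 6 kb
region centered on the probe), restricted to SNPs with minor allele frequency
strictly above 5%.  Multiple testing is controlled with Storey q-values
computed once over all cis tests; a probe is an meQTL probe when its best
association reaches q <= 0.10, and only the single most significant SNP per
probe (the lead SNP) is counted.  Because LD blurs which SNP is causal, a
candidate-causal subset is defined by requiring the best p-value to beat the
second best by at least two orders of magnitude within a widened window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import paired_ols
from .core import GenotypeTable, NormalizedMethylation, validate_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "cis_scan",
    "estimate_qvalues",
    "call_meqtls",
    "find_candidate_causal",
    "probe_pair_correlation",
]

ASSOC_COLUMNS = [
    "probe_id",
    "snp_id",
    "snp_pos",
    "distance",
    "effect",
    "se",
    "t_stat",
    "p_value",
    "q_value",
    "direction",
]


def cis_scan(
    meth,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    window: int = 3000,
    maf_min: float = 0.05,
    qvalues: bool = True,
) -> pd.DataFrame:
    """OLS scan of methylation on dosage for all cis (probe, SNP) pairs.

    Pairs satisfy ``|snp_pos - cpg_pos| <= window`` (inclusive) and
    ``maf > maf_min`` (strict).  Two-sided p-values come from the t
    distribution with n - 2 df; zero-dosage-variance pairs are skipped and
    logged.  With ``qvalues=True`` Storey q-values are computed once over all
    tests in the scan.
    """
    values = meth.values if isinstance(meth, NormalizedMethylation) else meth
    validate_manifest(manifest)
    if window <= 0:
        raise ValueError("window must be positive")
    n = values.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not geno.dosages.index.equals(values.index):
        if set(geno.sample_ids) != set(values.index):
            raise ValueError("methylation and genotype sample sets differ")
        geno = GenotypeTable(geno.dosages.loc[values.index], geno.snps.drop(columns="maf"))

    snps = geno.snps[geno.snps["maf"] > maf_min]
    if snps.empty:
        logger.warning("no SNPs pass the MAF filter; returning an empty table")
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    dos = geno.dosages[snps.index].to_numpy(dtype=float)
    snp_ids = snps.index.to_numpy()

    probe_rows, snp_rows = [], []
    manifest = manifest.loc[manifest.index.intersection(values.columns)]
    for chrom, msub in manifest.groupby("chrom", sort=False):
        on = snps["chrom"].to_numpy() == chrom
        if not on.any():
            continue
        order = np.argsort(snps["pos"].to_numpy()[on], kind="stable")
        local = np.flatnonzero(on)[order]
        pos_sorted = snps["pos"].to_numpy()[local]
        for probe, ppos in msub["pos"].items():
            lo = np.searchsorted(pos_sorted, ppos - window, side="left")
            hi = np.searchsorted(pos_sorted, ppos + window, side="right")
            for j in local[lo:hi]:
                probe_rows.append(probe)
                snp_rows.append(j)
    if not probe_rows:
        return pd.DataFrame(columns=ASSOC_COLUMNS)

    probe_loc = {p: i for i, p in enumerate(values.columns)}
    y_all = values.to_numpy(dtype=float)
    x = dos[:, snp_rows]
    y = y_all[:, [probe_loc[p] for p in probe_rows]]
    slope, se, t, p = paired_ols(x, y)

    snp_pos = snps["pos"].to_numpy()[snp_rows]
    assoc = pd.DataFrame(
        {
            "probe_id": probe_rows,
            "snp_id": snp_ids[snp_rows],
            "snp_pos": snp_pos,
            "distance": np.abs(snp_pos - manifest["pos"].reindex(probe_rows).to_numpy()),
            "effect": slope,
            "se": se,
            "t_stat": t,
            "p_value": p,
        }
    )
    skipped = assoc["p_value"].isna()
    if skipped.any():
        logger.info("skipped %d zero-variance (probe, SNP) pairs", int(skipped.sum()))
        assoc = assoc.loc[~skipped].reset_index(drop=True)
    if qvalues and len(assoc):
        assoc["q_value"], _ = estimate_qvalues(assoc["p_value"].to_numpy())
    else:
        assoc["q_value"] = np.nan
    assoc["direction"] = np.sign(assoc["effect"]).astype(int)
    return assoc[ASSOC_COLUMNS]


def estimate_qvalues(p_values, pi0: float | None = None, lambdas=None) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on a lambda grid (0.05 ... 0.95, step 0.05) by fitting a
    cubic polynomial to pi0(lambda) and evaluating it at the largest lambda
    (the lambda -> 1 extrapolation), clipped to (0, 1].  Passing ``pi0=1``
    reduces the result to Benjamini-Hochberg adjusted p-values.

    Returns ``(q_values, pi0)``; q-values keep the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), 1.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size >= 4 and m > 1:
            pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        else:
            pi0 = 1.0
        pi0 = min(pi0, 1.0)
        if pi0 <= 0:
            logger.warning("pi0 estimate non-positive; clipping to 1/m")
            pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def call_meqtls(assoc: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Call meQTL probes and their lead SNPs at a q-value threshold.

    A probe qualifies when its minimum q-value is <= ``fdr``; the lead SNP is
    the one with the smallest p-value, ties broken by smaller distance then
    smaller position.  Returns one row per significant probe with columns
    ``probe_id, lead_snp, lead_p, lead_q, effect, distance, snp_pos``.
    """
    if assoc.empty:
        return pd.DataFrame(
            columns=["probe_id", "lead_snp", "lead_p", "lead_q", "effect", "distance", "snp_pos"]
        )
    if assoc["q_value"].isna().any():
        raise ValueError("q_values must be populated before calling meQTLs")
    sig_probes = assoc.groupby("probe_id")["q_value"].min()
    sig_probes = sig_probes[sig_probes <= fdr].index
    sub = assoc[assoc["probe_id"].isin(sig_probes)]
    sub = sub.sort_values(["probe_id", "p_value", "distance", "snp_pos"], kind="stable")
    lead = sub.groupby("probe_id", sort=True).head(1)
    return (
        lead.rename(columns={"snp_id": "lead_snp", "p_value": "lead_p", "q_value": "lead_q"})[
            ["probe_id", "lead_snp", "lead_p", "lead_q", "effect", "distance", "snp_pos"]
        ].reset_index(drop=True)
    )


def find_candidate_causal(
    assoc_wide: pd.DataFrame, gap_orders: float = 2.0, wide_window: int = 10000
) -> tuple[pd.DataFrame, dict]:
    """Flag probes whose best SNP beats the runner-up by >= ``gap_orders``
    orders of magnitude in p-value, within the widened window.

    ``assoc_wide`` must come from a scan with ``window = wide_window / 2``.
    Probes with a single tested SNP are excluded (no second p to compare) and
    logged.  Returns ``(candidates, summary)`` where summary reports the
    median lead-SNP distance and the fraction of candidates beyond 3 kb.
    """
    ratio = 10.0 ** (-gap_orders)
    rows = []
    n_single = 0
    for probe, grp in assoc_wide.groupby("probe_id", sort=True):
        if len(grp) < 2:
            n_single += 1
            continue
        grp = grp.sort_values(["p_value", "distance", "snp_pos"], kind="stable")
        best, second = grp.iloc[0], grp.iloc[1]
        if best["p_value"] <= second["p_value"] * ratio:  # inclusive boundary
            with np.errstate(divide="ignore"):
                gap = np.log10(second["p_value"]) - np.log10(max(best["p_value"], 5e-324))
            rows.append(
                {
                    "probe_id": probe,
                    "snp_id": best["snp_id"],
                    "log10_gap": float(gap),
                    "distance": int(best["distance"]),
                }
            )
    if n_single:
        logger.info("excluded %d probes with a single tested SNP in the wide window", n_single)
    cands = pd.DataFrame(rows, columns=["probe_id", "snp_id", "log10_gap", "distance"])
    summary = {
        "n_candidates": len(cands),
        "median_distance": float(cands["distance"].median()) if len(cands) else np.nan,
        "frac_beyond_3kb": float((cands["distance"] > 3000).mean()) if len(cands) else np.nan,
    }
    return cands, summary


def probe_pair_correlation(
    normalized: pd.DataFrame | None,
    untransformed: pd.DataFrame | None,
    meqtls: pd.DataFrame,
    manifest: pd.DataFrame,
    max_dist: int = 5000,
    alpha: float = 0.05,
) -> dict:
    """Audit whether nearby meQTL probes carry correlated data.

    For every pair of meQTL probes within ``max_dist`` of each other,
    computes the Pearson correlation across samples and its t-test p-value,
    on the normalized and/or untransformed matrix.  Reports, per matrix, the
    number of pairs tested, significant pairs at ``alpha``, and probes
    appearing in at least one significant pair.
    """
    from scipy import stats

    probes = meqtls["probe_id"].tolist()
    if len(probes) < 2:
        raise ValueError("need at least two meQTL probes")
    sub = manifest.loc[manifest.index.isin(probes)]
    pairs = []
    for chrom, grp in sub.groupby("chrom"):
        ids = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        ids, pos = ids[order], pos[order]
        for i in range(len(ids)):
            j = i + 1
            while j < len(ids) and pos[j] - pos[i] <= max_dist:
                pairs.append((ids[i], ids[j]))
                j += 1
    out: dict = {"n_pairs": len(pairs)}
    for label, mat in (("normalized", normalized), ("untransformed", untransformed)):
        if mat is None:
            continue
        vals = mat.values if isinstance(mat, NormalizedMethylation) else mat
        n_sig = 0
        probes_in_sig: set = set()
        records = []
        for a, b in pairs:
            r, p = stats.pearsonr(vals[a], vals[b])
            records.append((a, b, r, p))
            if p < alpha:
                n_sig += 1
                probes_in_sig.update((a, b))
        out[label] = {
            "n_significant_pairs": n_sig,
            "n_probes_in_significant_pair": len(probes_in_sig),
            "pairs": pd.DataFrame(records, columns=["probe_a", "probe_b", "r", "p_value"]),
        }
    return out
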