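"""Bisulfite-read methylation estimates and genotype-stratified aggregation.

Low-coverage whole-genome bisulfite data (median 2.4x in the emulated study
design) cannot validate individual meQTLs, but pooling reads across
individuals and loci can.  The aggregation separates sequenced individuals
into three genotype classes at each meQTL — oriented so "high" is the
homozygote associated with higher array methylation — counts methylated and
total reads in 51 bp windows sliding across a 5 kb region centered on the
associated CpG, pools within (meQTL, class, window) as sum-of-methylated
over sum-of-total, and finally averages the pooled levels across meQTLs
(unweighted; windows with no reads at a given meQTL are omitted from that
mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateCurve",
    "validate_counts",
    "site_methylation",
    "array_seq_concordance",
    "genotype_stratified_aggregate",
]

CLASSES = ("low", "het", "high")


@dataclass
class AggregateCurve:
    """Genotype-class mean methylation by window offset around meQTL CpGs.

    ``levels`` has one row per window (index = window-center offset relative
    to the CpG, negative = upstream) and one column per genotype class;
    ``n_meqtls`` counts the meQTLs contributing to each (window, class) mean.
    """

    levels: pd.DataFrame
    n_meqtls: pd.DataFrame
    span: int
    window: int
    step: int

    @property
    def offsets(self) -> np.ndarray:
        return self.levels.index.to_numpy()


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample", "chrom", "pos", "n_meth", "n_total"):
        if col not in counts.columns:
            raise ValueError(f"bisulfite counts lack required column {col!r}")
    if (counts["n_meth"] > counts["n_total"]).any() or (counts["n_meth"] < 0).any():
        raise ValueError("corrupt counts: n_meth must satisfy 0 <= n_meth <= n_total")
    return counts


def site_methylation(counts: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Per-(sample, site) methylation level = n_meth / n_total.

    Sites with coverage below ``min_reads`` get a missing level.
    """
    validate_counts(counts)
    out = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        level = out["n_meth"] / out["n_total"]
    level[out["n_total"] < min_reads] = np.nan
    out["level"] = level
    return out


def array_seq_concordance(
    beta: pd.DataFrame,
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    min_reads: int = 5,
) -> tuple[float, int]:
    """Spearman correlation between array and sequencing methylation per site.

    Per shared site: the array value is the mean untransformed beta across
    all samples; the sequencing value is the mean of per-sample levels over
    samples with at least ``min_reads`` reads.  Sites where no sample reaches
    the threshold are excluded.  Spearman is used because the levels are
    bounded and bimodal, not normal.
    """
    lev = site_methylation(counts, min_reads=min_reads)
    seq = (
        lev.dropna(subset=["level"])
        .groupby(["chrom", "pos"])["level"]
        .mean()
    )
    array_mean = beta.mean(axis=0)
    key = pd.MultiIndex.from_frame(manifest.reset_index()[["chrom", "pos"]])
    array_by_site = (
        pd.Series(array_mean.reindex(manifest.index).to_numpy(), index=key)
        .groupby(level=[0, 1])
        .mean()  # co-located probes collapse to one site
    )
    shared = seq.index.intersection(array_by_site.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared sites between array and sequencing")
    rho, _ = stats.spearmanr(array_by_site.loc[shared], seq.loc[shared])
    return float(rho), int(len(shared))


def genotype_stratified_aggregate(
    counts: pd.DataFrame,
    meqtls: pd.DataFrame,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    span: int = 5000,
    window: int = 51,
    step: int = 25,
) -> AggregateCurve:
    """Pooled methylation by genotype class in sliding windows around meQTLs.

    ``meqtls`` is the lead-SNP table from :func:`methqtl.mapping.call_meqtls`
    (columns ``probe_id, lead_snp, effect``).  Continuous dosages are rounded
    to hard calls for class assignment only; classes are oriented by the sign
    of the array effect so that "high" always means the homozygote with
    higher array methylation (flipping allele labels leaves the curves
    unchanged).  Window accounting: floor((span - window) / step) + 1
    positions, window i covering offsets [-span/2 + i*step, ... + window).
    """
    validate_counts(counts)
    if span <= window:
        raise ValueError("span must exceed the window size")
    n_windows = (span - window) // step + 1
    starts = -span // 2 + np.arange(n_windows) * step
    centers = starts + window // 2

    seq_samples = counts["sample"].unique()
    usable = [s for s in seq_samples if s in geno.sample_ids]
    if not usable:
        raise ValueError("no sequenced individuals present in the genotype table")

    sum_level = np.zeros((n_windows, 3))
    n_contrib = np.zeros((n_windows, 3), dtype=int)
    counts_by_chrom = {c: g for c, g in counts.groupby("chrom")}
    probe_pos = manifest["pos"]

    n_one_class = 0
    for _, row in meqtls.iterrows():
        probe = row["probe_id"]
        if probe not in probe_pos.index:
            continue
        cpos = int(probe_pos.loc[probe])
        chrom = manifest.loc[probe, "chrom"]
        snp = row["lead_snp"]
        if snp not in geno.snp_ids:
            continue
        dos = geno.dosages.loc[usable, snp].round().clip(0, 2).astype(int)
        # orient: positive array effect -> dosage 2 is the high-methylation class
        if row["effect"] >= 0:
            cls_of_dosage = {0: 0, 1: 1, 2: 2}
        else:
            cls_of_dosage = {0: 2, 1: 1, 2: 0}
        sample_class = {s: cls_of_dosage[g] for s, g in dos.items()}
        if len(set(sample_class.values())) < 2:
            n_one_class += 1
        sub = counts_by_chrom.get(chrom)
        if sub is None:
            continue
        rel = sub["pos"].to_numpy() - cpos
        inside = (rel >= starts[0]) & (rel < starts[-1] + window)
        if not inside.any():
            continue
        sub = sub.loc[inside]
        rel = rel[inside]
        cls = np.array([sample_class.get(s, -1) for s in sub["sample"]])
        ok = cls >= 0
        if not ok.any():
            continue
        sub, rel, cls = sub.loc[ok], rel[ok], cls[ok]
        meth = sub["n_meth"].to_numpy()
        total = sub["n_total"].to_numpy()

        m_acc = np.zeros((n_windows, 3))
        t_acc = np.zeros((n_windows, 3))
        # window i contains offset r iff starts[i] <= r < starts[i] + window
        i_min = np.ceil((rel - window + 1 - starts[0]) / step).astype(int)
        i_max = np.floor((rel - starts[0]) / step).astype(int)
        i_min = np.clip(i_min, 0, n_windows - 1)
        i_max = np.clip(i_max, -1, n_windows - 1)
        width = int((i_max - i_min).max(initial=0)) + 1
        for k in range(width):
            idx = i_min + k
            sel = idx <= i_max
            if not sel.any():
                continue
            np.add.at(m_acc, (idx[sel], cls[sel]), meth[sel])
            np.add.at(t_acc, (idx[sel], cls[sel]), total[sel])
        covered = t_acc > 0
        level = np.zeros_like(m_acc)
        level[covered] = m_acc[covered] / t_acc[covered]
        sum_level[covered] += level[covered]
        n_contrib += covered

    if n_one_class:
        logger.info("%d meQTLs had sequenced individuals in a single genotype class", n_one_class)
    with np.errstate(invalid="ignore"):
        mean_level = np.where(n_contrib > 0, sum_level / np.maximum(n_contrib, 1), np.nan)
    levels = pd.DataFrame(mean_level, index=pd.Index(centers, name="offset"), columns=CLASSES)
    n_meqtls = pd.DataFrame(n_contrib, index=levels.index, columns=CLASSES)
    return AggregateCurve(levels, n_meqtls, span=span, window=window, step=step)
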