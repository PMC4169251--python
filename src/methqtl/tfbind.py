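"""PWM allele scoring and TF binding / expression associations with methylation.

A position weight matrix (PWM) summarizes a TF's sequence preference as
per-position base probabilities; a sequence is scored as the sum of log2
odds against a background composition.  For a SNP inside a motif instance the
two alleles generally score differently, and the per-individual predicted
binding affinity is additive in dosage:

    affinity(g) = score_ref + (g / 2) * (score_alt - score_ref)

Regressing nearby methylation on this covariate asks whether genetically
encoded changes in predicted binding track methylation changes.  A second,
complementary analysis correlates a TF's expression level with methylation
near that TF's ChIP-seq binding sites, with significance bands from
permutation of the expression vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import paired_ols
from .core import GenotypeTable, NormalizedMethylation

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "BindingSiteSNP",
    "BASES",
    "pwm_score",
    "allele_scores",
    "score_sites",
    "reverse_complement",
    "binding_snp_meth_assoc",
    "tf_expression_meth_assoc",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities, order ACGT.

    A pseudocount is mixed into each column and the columns renormalized, so
    log-odds scores stay finite even for zero-probability entries; pass
    ``pseudocount=0`` to score a matrix exactly as given.
    """

    name: str
    probs: np.ndarray  # width x 4
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        row = self.probs.sum(axis=1, keepdims=True)
        if (row == 0).any():
            raise ValueError("PWM column with zero total probability")
        self.probs = (self.probs / row + self.pseudocount) / (1.0 + 4 * self.pseudocount)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def pwm_score(pwm: PWM, sequence: str) -> float:
    """Log2-odds score of a sequence of exactly the motif width.

    score = sum_i log2( p(b_i, i) / background(b_i) ).  Ambiguous bases are
    rejected; callers mask such sites.
    """
    if len(sequence) != pwm.width:
        raise ValueError(f"sequence length {len(sequence)} != motif width {pwm.width}")
    idx = []
    for b in sequence.upper():
        if b not in _BASE_INDEX:
            raise ValueError(f"ambiguous or invalid base {b!r} in motif window")
        idx.append(_BASE_INDEX[b])
    cols = np.arange(pwm.width)
    with np.errstate(divide="ignore"):
        terms = np.log2(pwm.probs[cols, idx] / pwm.background[idx])
    return float(terms.sum())


@dataclass
class BindingSiteSNP:
    """A SNP inside a TF motif instance with both alleles scored."""

    chrom: str
    start: int
    end: int
    strand: str
    tf: str
    snp_id: str
    offset: int  # genomic offset of the SNP within [start, end)
    ref: str
    alt: str
    score_ref: float
    score_alt: float

    @property
    def delta(self) -> float:
        return self.score_alt - self.score_ref


def allele_scores(site, pwm: PWM, ref_context: str) -> BindingSiteSNP:
    """Score both alleles of a SNP within a motif window.

    ``site`` is a mapping (or DataFrame row) with fields ``chrom, start, end,
    strand, tf, snp_id, offset, ref, alt``; ``offset`` and ``ref_context``
    are on the plus strand (``ref_context`` covers [start, end)).  For a
    minus-strand site the window and alleles are reverse-complemented before
    scoring, so the annotated motif strand is the one scored.
    """
    ref, alt = site["ref"].upper(), site["alt"].upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only SNVs can be scored (indel alleles rejected)")
    offset = int(site["offset"])
    if not (0 <= offset < pwm.width):
        raise ValueError("SNP offset outside the motif window")
    if len(ref_context) != pwm.width:
        raise ValueError("ref_context must cover exactly the motif window")
    if ref_context[offset].upper() != ref:
        raise ValueError("ref allele does not match ref_context at the SNP offset")
    if site["strand"] == "-":
        window = reverse_complement(ref_context)
        m_off = pwm.width - 1 - offset
        ref_m, alt_m = reverse_complement(ref), reverse_complement(alt)
    else:
        window, m_off, ref_m, alt_m = ref_context, offset, ref, alt
    s_ref = pwm_score(pwm, window[:m_off] + ref_m + window[m_off + 1 :])
    s_alt = pwm_score(pwm, window[:m_off] + alt_m + window[m_off + 1 :])
    return BindingSiteSNP(
        chrom=site["chrom"],
        start=int(site["start"]),
        end=int(site["end"]),
        strand=site["strand"],
        tf=site["tf"],
        snp_id=site["snp_id"],
        offset=offset,
        ref=ref,
        alt=alt,
        score_ref=s_ref,
        score_alt=s_alt,
    )


def score_sites(sites: pd.DataFrame, pwm: PWM) -> pd.DataFrame:
    """Apply :func:`allele_scores` to every row of a site table.

    Expects a ``ref_context`` column; returns the table with ``score_ref``,
    ``score_alt`` and ``delta`` columns appended.
    """
    recs = [allele_scores(row, pwm, row["ref_context"]) for _, row in sites.iterrows()]
    out = sites.copy()
    out["score_ref"] = [r.score_ref for r in recs]
    out["score_alt"] = [r.score_alt for r in recs]
    out["delta"] = [r.delta for r in recs]
    return out


def binding_snp_meth_assoc(
    sites: pd.DataFrame,
    meth,
    geno: GenotypeTable,
    manifest: pd.DataFrame,
    window: int = 500,
    fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associate allelic binding-score differences with nearby methylation.

    For each scored site, the per-individual covariate is
    ``score_ref + (dosage / 2) * delta`` and every probe within ``window`` bp
    of the site interval is regressed on it.  Sign convention: a positive
    effect means higher predicted PWM score goes with higher methylation.

    q-values are computed per TF over that TF's tests, and a SNP counts as
    significant when any of its probes reaches ``q <= fdr``.

    Returns ``(associations, per-TF summary)``.
    """
    from .mapping import estimate_qvalues

    values = meth.values if isinstance(meth, NormalizedMethylation) else meth
    required = {"score_ref", "delta", "snp_id", "tf"}
    if not required.issubset(sites.columns):
        raise ValueError("sites must be scored first (see score_sites)")

    probe_pos = manifest["pos"].to_numpy()
    probe_chrom = manifest["chrom"].to_numpy()
    probe_ids = manifest.index.to_numpy()
    rows = []
    x_cols, y_cols = [], []
    y_arr = values.to_numpy()
    probe_loc = {p: i for i, p in enumerate(values.columns)}
    for _, site in sites.iterrows():
        snp = site["snp_id"]
        if snp not in geno.snp_ids:
            raise ValueError(f"site SNP {snp} missing from genotype table")
        dos = geno.dosages[snp].reindex(values.index).to_numpy()
        covariate = site["score_ref"] + dos / 2.0 * site["delta"]
        # distance from probe to the site interval (0 inside)
        d = np.maximum(site["start"] - probe_pos, probe_pos - (site["end"] - 1))
        near = (probe_chrom == site["chrom"]) & (np.maximum(d, 0) <= window)
        for p in probe_ids[near]:
            if p not in probe_loc:
                continue
            rows.append((site["tf"], snp, p))
            x_cols.append(covariate)
            y_cols.append(y_arr[:, probe_loc[p]])
    if not rows:
        return (
            pd.DataFrame(columns=["tf", "snp_id", "probe_id", "effect", "t_stat", "p_value", "q_value"]),
            pd.DataFrame(columns=["tf", "n_snps", "prop_significant", "n_positive", "n_negative"]),
        )
    slope, se, t, p = paired_ols(np.column_stack(x_cols), np.column_stack(y_cols))
    assoc = pd.DataFrame(rows, columns=["tf", "snp_id", "probe_id"])
    assoc["effect"] = slope
    assoc["se"] = se
    assoc["t_stat"] = t
    assoc["p_value"] = p
    skipped = assoc["p_value"].isna()
    if skipped.any():
        logger.info("dropped %d zero-variance covariate tests", int(skipped.sum()))
        assoc = assoc[~skipped].reset_index(drop=True)
    assoc["q_value"] = np.nan
    summaries = []
    for tf, grp in assoc.groupby("tf", sort=False):
        q, _ = estimate_qvalues(grp["p_value"].to_numpy(), pi0=1.0)
        assoc.loc[grp.index, "q_value"] = q
        per_snp = assoc.loc[grp.index].groupby("snp_id", sort=False)
        sig = per_snp["q_value"].min() <= fdr
        lead = assoc.loc[grp.index].loc[per_snp["p_value"].idxmin()]
        signs = np.sign(lead.set_index("snp_id")["effect"])[sig[sig].index]
        summaries.append(
            {
                "tf": tf,
                "n_snps": int(per_snp.ngroups),
                "prop_significant": float(sig.mean()),
                "n_positive": int((signs > 0).sum()),
                "n_negative": int((signs < 0).sum()),
            }
        )
    return assoc, pd.DataFrame(summaries)


def tf_expression_meth_assoc(
    expr: pd.Series,
    meth,
    sites: pd.DataFrame,
    manifest: pd.DataFrame,
    window: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate TF expression with methylation near the TF's binding sites.

    ``meth`` should be the quantile-normalized matrix *without* PC removal: a
    TF acting in trans shifts methylation genome-wide, and the shift would be
    absorbed by the leading PCs.  ``sites`` are binding-site intervals
    (``chrom, start, end``).  Each probe within ``window`` bp of any site is
    tested with a Pearson correlation; the null band comes from ``n_perm``
    permutations of the expression vector with methylation held fixed.

    Returns ``(per-probe table, band)`` where ``band`` has one row per order
    statistic of -log10 p (descending) with pointwise 2.5% / 97.5% null
    quantiles.
    """
    values = meth.values if isinstance(meth, NormalizedMethylation) else meth
    e = expr.reindex(values.index).to_numpy(dtype=float)
    if np.std(e) == 0:
        raise ValueError("expression vector has zero variance")
    probe_pos = manifest["pos"].to_numpy()
    probe_chrom = manifest["chrom"].to_numpy()
    near = np.zeros(len(manifest), dtype=bool)
    for _, s in sites.iterrows():
        d = np.maximum(s["start"] - probe_pos, probe_pos - (s["end"] - 1))
        near |= (probe_chrom == s["chrom"]) & (np.maximum(d, 0) <= window)
    probes = manifest.index[near]
    probes = probes[probes.isin(values.columns)]
    if len(probes) == 0:
        raise ValueError("no probes within the window of any binding site")
    y = values[probes].to_numpy()
    n = len(e)

    def _pearson_p(x):
        xz = (x - x.mean()) / x.std()
        yz = (y - y.mean(axis=0)) / y.std(axis=0)
        r = xz @ yz / n
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1 - r**2))
        t = np.where(np.abs(r) == 1.0, np.sign(r) * np.inf, t)
        return r, 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    r, p = _pearson_p(e)
    table = pd.DataFrame({"probe_id": probes, "r": r, "p_value": p}).reset_index(drop=True)

    rng = np.random.default_rng(seed)
    null_sorted = np.empty((n_perm, len(probes)))
    for b in range(n_perm):
        _, pp = _pearson_p(rng.permutation(e))
        null_sorted[b] = np.sort(-np.log10(np.maximum(pp, 1e-300)))[::-1]
    band = pd.DataFrame(
        {
            "rank": np.arange(1, len(probes) + 1),
            "lo": np.percentile(null_sorted, 2.5, axis=0),
            "hi": np.percentile(null_sorted, 97.5, axis=0),
            "expected": null_sorted.mean(axis=0),
        }
    )
    return table, band
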