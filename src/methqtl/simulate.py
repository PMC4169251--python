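"""Synthetic genotypes, array methylation, bisulfite reads and motif fixtures.

The generator reproduces the statistical structure the downstream analyses
assume: LD among nearby SNPs (haplotype-block draws), a bimodal marginal
distribution of array beta values, cis effects that shift methylation over a
regional span of correlated CpGs, hidden confounders loading on principal
components, low-coverage binomial bisulfite reads, and secondary quantitative
phenotypes that share QTLs with methylation.  Every planted signal is recorded
in a :class:`TruthTable` so parameter-recovery tests have ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import GenotypeTable
from .tfbind import PWM, BASES, pwm_score, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthTable",
    "PhenotypeTable",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_bisulfite_reads",
    "simulate_linked_phenotype",
    "simulate_binding_fixture",
]

# per-allele flip rate applied on top of the two haplotype pools of a block;
# keeps within-block LD strong (dosage r ~ (1-2*eps)^2) but imperfect, so a
# causal SNP remains statistically separable from its LD partners
_HAPLOTYPE_FLIP_RATE = 0.05


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the scale of the study design the package targets:
    64 lymphoblastoid cell lines, cis effects on the latent (logit) scale of
    1.5 residual standard deviations, and a regional effect span of 1.5 kb on
    each side of the causal CpG.
    """

    n_samples: int = 64
    n_probes: int = 400
    n_snps: int = 400
    region_length: int = 1_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 2_000
    causal_fraction: float = 0.25
    effect_size: float = 1.5
    regional_effect_span: int = 1_500
    n_confounders: int = 0
    confounder_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.regional_effect_span < 0:
            raise ValueError("regional_effect_span must be non-negative")
        if not (0 <= self.causal_fraction <= 1):
            raise ValueError("causal_fraction must lie in [0, 1]")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be non-negative")


@dataclass
class TruthTable:
    """Ground truth of the planted structure.

    ``causal_pairs`` maps every probe that receives a planted latent shift
    (the causal CpG and all probes within the regional effect span of it) to
    its driving SNP and signed latent effect.  ``seed_probes`` is the subset
    at which the effects were originally planted.
    """

    causal_pairs: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed_probes: set[str] = field(default_factory=set)
    confounder_loadings: pd.DataFrame | None = None
    shared_qtl_snps: set[str] = field(default_factory=set)

    def validate(self, geno: GenotypeTable) -> None:
        for probe, (snp, eff) in self.causal_pairs.items():
            if snp not in geno.snp_ids:
                raise ValueError(f"causal SNP {snp} missing from genotype table")
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for probe {probe}")


@dataclass
class PhenotypeTable:
    """Secondary quantitative traits sharing QTLs with methylation.

    One trait per shared-QTL SNP; ``snp_of_trait`` maps trait id to the
    driving SNP and ``effect_of_trait`` records the signed planted effect,
    giving direction-classification tests their truth.
    """

    values: pd.DataFrame  # samples x traits
    snp_of_trait: dict[str, str]
    effect_of_trait: dict[str, float]


def simulate_genotypes(cfg: SimConfig) -> GenotypeTable:
    """Draw integer dosages with haplotype-block LD.

    SNP positions are uniform on [0, region_length).  Within each
    ``ld_block_size`` stretch, haplotypes are drawn from two complementary
    pools (one carrying the minor allele at every SNP of the block, one
    carrying none) at a block-specific frequency sampled from ``maf_range``,
    then each allele is flipped with a small fixed rate.  Adjacent SNPs are
    therefore strongly but not perfectly correlated.
    """
    cfg.validate()
    if cfg.n_snps == 0:
        raise ValueError("n_snps must be positive: refusing to build an empty table")
    rng = np.random.default_rng(cfg.seed)
    pos = np.sort(rng.integers(0, cfg.region_length, size=cfg.n_snps))
    block = pos // cfg.ld_block_size
    n_hap = 2 * cfg.n_samples

    alleles = np.empty((n_hap, cfg.n_snps), dtype=np.int8)
    for b in np.unique(block):
        cols = np.flatnonzero(block == b)
        f = rng.uniform(*cfg.maf_range)
        pool = rng.random(n_hap) < f  # True -> minor-allele pool
        base = np.repeat(pool[:, None], len(cols), axis=1)
        flips = rng.random((n_hap, len(cols))) < _HAPLOTYPE_FLIP_RATE
        alleles[:, cols] = (base ^ flips).astype(np.int8)

    dosage = alleles[0::2] + alleles[1::2]
    snp_ids = [f"snp{i:05d}" for i in range(cfg.n_snps)]
    sample_ids = [f"NA{i:05d}" for i in range(cfg.n_samples)]
    dosages = pd.DataFrame(dosage, index=sample_ids, columns=snp_ids, dtype=float)
    snps = pd.DataFrame({"chrom": "chr1", "pos": pos}, index=pd.Index(snp_ids, name="snp_id"))
    return GenotypeTable(dosages, snps)


def simulate_methylation(
    geno: GenotypeTable,
    cfg: SimConfig,
    decay: str = "boxcar",
    cis_window: int = 3_000,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate beta values with planted cis effects and confounders.

    The latent value per (sample, probe) is
    ``baseline + dosage * effect + confounders + N(0, 1)`` mapped through the
    inverse logit.  Baselines come from a two-component mixture (latent means
    -2 and +2) so the marginal beta distribution is bimodal.  A causal probe's
    latent shift is shared by every probe within ``regional_effect_span`` of
    it (``decay='boxcar'``), or attenuated by a Gaussian kernel with sigma =
    span / 2 (``decay='gaussian'``).

    Returns ``(beta, manifest, truth)``: the samples x probes beta matrix, a
    probe manifest (chrom / pos), and the :class:`TruthTable`.
    """
    cfg.validate()
    if geno.dosages.shape[1] == 0:
        raise ValueError("genotype table is empty")
    if decay not in ("boxcar", "gaussian"):
        raise ValueError("decay must be 'boxcar' or 'gaussian'")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n, m = cfg.n_samples, cfg.n_probes
    if n != geno.n_samples:
        raise ValueError("cfg.n_samples must match the genotype table")

    probe_pos = np.sort(rng.integers(0, cfg.region_length, size=m))
    probe_ids = [f"cg{i:06d}" for i in range(m)]
    manifest = pd.DataFrame(
        {"chrom": "chr1", "pos": probe_pos}, index=pd.Index(probe_ids, name="probe_id")
    )

    # bimodal baselines: mostly-unmethylated and mostly-methylated components
    comp = rng.random(m) < 0.5
    baseline = np.where(comp, 2.0, -2.0) + rng.normal(0.0, 0.5, size=m)

    latent = np.tile(baseline, (n, 1))

    truth = TruthTable()
    snp_pos = geno.snps["pos"].to_numpy()
    snp_ids = geno.snp_ids.to_numpy()
    dos = geno.dosages.to_numpy()

    n_causal = int(round(cfg.causal_fraction * m))
    causal_idx = rng.choice(m, size=n_causal, replace=False) if n_causal else np.empty(0, int)
    affected_any = np.zeros(m, dtype=bool)
    for j in np.sort(causal_idx):
        # nearest SNP within the cis window drives the probe; probes with no
        # SNP in range are left null
        k = int(np.argmin(np.abs(snp_pos - probe_pos[j])))
        if abs(snp_pos[k] - probe_pos[j]) > cis_window:
            continue
        d = np.abs(probe_pos - probe_pos[j])
        if decay == "boxcar":
            weight = (d <= cfg.regional_effect_span).astype(float)
        else:
            sigma = max(cfg.regional_effect_span / 2.0, 1.0)
            weight = np.exp(-0.5 * (d / sigma) ** 2)
            weight[d > 3 * cfg.regional_effect_span] = 0.0
        affected = np.flatnonzero(weight > 0)
        # keep planted regions disjoint: overlapping shifts of opposite sign
        # would cancel and leave recorded "causal" probes without signal
        if affected_any[affected].any():
            continue
        eff = cfg.effect_size * rng.choice([-1.0, 1.0])
        truth.seed_probes.add(probe_ids[j])
        affected_any[affected] = True
        latent[:, affected] += np.outer(dos[:, k], eff * weight[affected])
        for a in affected:
            truth.causal_pairs[probe_ids[a]] = (snp_ids[k], eff * weight[a])
        truth.shared_qtl_snps.add(snp_ids[k])

    if cfg.n_confounders > 0:
        loadings = rng.normal(0.0, 1.0, size=(n, cfg.n_confounders))
        weights = rng.normal(0.0, cfg.confounder_sd, size=(cfg.n_confounders, m))
        latent += loadings @ weights
        truth.confounder_loadings = pd.DataFrame(
            loadings, index=geno.sample_ids, columns=[f"conf{i}" for i in range(cfg.n_confounders)]
        )

    latent += rng.normal(0.0, 1.0, size=(n, m))
    beta = pd.DataFrame(expit(latent), index=geno.sample_ids, columns=probe_ids)
    truth.validate(geno)
    return beta, manifest, truth


def simulate_bisulfite_reads(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    mean_coverage: float = 2.4,
    conversion_efficiency: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample per-CpG read counts from the array methylation truth.

    Totals are Poisson(``mean_coverage``); methylated counts are binomial with
    success probability ``beta + (1 - beta) * (1 - conversion_efficiency)``:
    conversion failure makes unmethylated cytosines read as methylated, never
    the reverse.  Returns a long DataFrame with columns
    ``sample, chrom, pos, n_meth, n_total`` (rows with zero coverage kept).
    """
    if not (0 < conversion_efficiency <= 1):
        raise ValueError("conversion_efficiency must lie in (0, 1]")
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be non-negative")
    rng = np.random.default_rng(seed)
    b = beta.to_numpy()
    n, m = b.shape
    total = rng.poisson(mean_coverage, size=(n, m))
    p_obs = b + (1.0 - b) * (1.0 - conversion_efficiency)
    meth = rng.binomial(total, p_obs)
    out = pd.DataFrame(
        {
            "sample": np.repeat(beta.index.to_numpy(), m),
            "chrom": np.tile(manifest["chrom"].to_numpy(), n),
            "pos": np.tile(manifest["pos"].to_numpy(), n),
            "n_meth": meth.ravel(),
            "n_total": total.ravel(),
        }
    )
    return out


def simulate_linked_phenotype(
    geno: GenotypeTable,
    truth: TruthTable,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PhenotypeTable:
    """One quantitative trait per shared-QTL SNP: dosage * effect + noise.

    The sign of each trait's effect is drawn at random and recorded, so
    direction-classification tests know the truth.
    """
    rng = np.random.default_rng(seed)
    snps = sorted(truth.shared_qtl_snps)
    values = {}
    snp_of_trait: dict[str, str] = {}
    effect_of_trait: dict[str, float] = {}
    for i, snp in enumerate(snps):
        trait = f"trait{i:04d}"
        sign = rng.choice([-1.0, 1.0])
        eff = sign * effect
        y = geno.dosages[snp].to_numpy() * eff
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(y))
        values[trait] = y
        snp_of_trait[trait] = snp
        effect_of_trait[trait] = eff
    df = pd.DataFrame(values, index=geno.sample_ids)
    return PhenotypeTable(df, snp_of_trait, effect_of_trait)


def simulate_binding_fixture(
    pwm: PWM,
    geno: GenotypeTable,
    n_sites: int = 50,
    coupling: float = -1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant TF binding sites whose allelic PWM-score difference drives
    methylation at a nearby probe.

    Each site overlaps one SNP; the two alleles receive distinct PWM column
    probabilities (sites where no distinct pair exists at the chosen offset
    are excluded).  The probe's latent methylation is ``coupling`` times the
    standardized per-individual mean allele score plus Gaussian noise, so
    ``coupling < 0`` couples higher predicted binding to lower methylation.

    Returns ``(sites, beta, manifest)``.  ``sites`` has one row per retained
    site with plus-strand ``ref_context`` and genomic SNP ``offset``; the
    motif-orientation conventions match :func:`methqtl.tfbind.allele_scores`.
    """
    if pwm.width == 0:
        raise ValueError("PWM has zero width")
    rng = np.random.default_rng(seed)
    w = pwm.width
    snp_idx = rng.choice(len(geno.snp_ids), size=min(n_sites, len(geno.snp_ids)), replace=False)
    probs = pwm.probs

    rows = []
    latents = []
    for i, k in enumerate(np.sort(snp_idx)):
        snp = geno.snp_ids[k]
        snp_pos = int(geno.snps["pos"].iloc[k])
        chrom = geno.snps["chrom"].iloc[k]
        mo = int(rng.integers(0, w))  # SNP offset in motif orientation
        col = probs[mo]
        order = np.argsort(col)[::-1]
        ref_b, alt_b = BASES[order[0]], BASES[order[1]]
        if col[order[0]] == col[order[1]]:
            continue  # both alleles score identically: excluded
        # motif-orientation sequence sampled from the PWM, ref at the offset
        mseq = "".join(BASES[rng.choice(4, p=probs[i_] / probs[i_].sum())] for i_ in range(w))
        mseq = mseq[:mo] + ref_b + mseq[mo + 1 :]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            context, offset = mseq, mo
            ref, alt = ref_b, alt_b
        else:
            context, offset = reverse_complement(mseq), w - 1 - mo
            ref, alt = reverse_complement(ref_b), reverse_complement(alt_b)
        start = snp_pos - offset
        score_ref = pwm_score(pwm, mseq)
        score_alt = pwm_score(pwm, mseq[:mo] + alt_b + mseq[mo + 1 :])
        delta = score_alt - score_ref
        dos = geno.dosages.iloc[:, k].to_numpy()
        covariate = score_ref + dos / 2.0 * delta
        sd = covariate.std()
        if sd == 0:
            continue
        z = (covariate - covariate.mean()) / sd
        latents.append(coupling * z + rng.normal(0.0, noise_sd, size=len(z)))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + w,
                "strand": strand,
                "tf": pwm.name,
                "snp_id": snp,
                "offset": offset,
                "ref": ref,
                "alt": alt,
                "ref_context": context,
                "probe_id": f"cgTF{i:04d}",
                "probe_pos": snp_pos + int(rng.integers(-200, 201)),
            }
        )
    sites = pd.DataFrame(rows)
    if sites.empty:
        return sites, pd.DataFrame(index=geno.sample_ids), pd.DataFrame(columns=["chrom", "pos"])
    beta = pd.DataFrame(
        expit(np.column_stack(latents)), index=geno.sample_ids, columns=sites["probe_id"].tolist()
    )
    manifest = pd.DataFrame(
        {"chrom": sites["chrom"].to_numpy(), "pos": sites["probe_pos"].to_numpy()},
        index=pd.Index(sites["probe_id"], name="probe_id"),
    )
    return sites, beta, manifest
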