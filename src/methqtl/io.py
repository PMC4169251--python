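"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: matrices are tab-delimited with samples as columns (probes or
SNPs as rows), manifests are BED (0-based half-open, the CpG as a 1 bp
interval), bisulfite counts follow the Bismark-coverage layout
``chrom  start  end  n_meth  n_unmeth`` per sample, and PWMs are accepted in
JASPAR or MEME minimal format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeTable
from .tfbind import PWM

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
    "write_manifest_bed",
    "read_manifest_bed",
    "write_bismark_coverage",
    "read_bismark_coverage",
    "read_pwm_jaspar",
    "read_pwm_meme",
    "read_snp_list",
]


def write_matrix(values: pd.DataFrame, path) -> None:
    """Write a samples x features matrix as TSV with samples as columns."""
    values.T.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_genotypes(geno: GenotypeTable, prefix) -> None:
    """Write ``<prefix>.dosage.tsv`` (SNPs x samples, with chrom/pos) ."""
    prefix = Path(prefix)
    out = geno.snps[["chrom", "pos"]].join(geno.dosages.T)
    out.to_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_label="snp_id")


def read_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    snps = df[["chrom", "pos"]]
    dosages = df.drop(columns=["chrom", "pos"]).T
    return GenotypeTable(dosages, snps)


def write_vcf(geno: GenotypeTable, path) -> None:
    """Minimal unphased-genotype VCF from integer dosages."""
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(geno.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for snp, row in geno.snps.iterrows():
            g = geno.dosages[snp].round().clip(0, 2).astype(int)
            calls = "\t".join(code[v] for v in g)
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def write_manifest_bed(manifest: pd.DataFrame, path) -> None:
    cols = {"chrom": manifest["chrom"], "start": manifest["pos"], "end": manifest["pos"] + 1,
            "name": manifest.index}
    bed = pd.DataFrame(cols)
    if "annotation" in manifest.columns:
        bed["annotation"] = manifest["annotation"].to_numpy()
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_manifest_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None)
    manifest = pd.DataFrame(
        {"chrom": bed[0].to_numpy(), "pos": bed[1].to_numpy()},
        index=pd.Index(bed[3].to_numpy(), name="probe_id"),
    )
    if bed.shape[1] > 4:
        manifest["annotation"] = bed[4].to_numpy()
    return manifest


def write_bismark_coverage(counts: pd.DataFrame, out_dir) -> list[Path]:
    """One ``<sample>.cov`` file per sample: chrom, start, end, meth, unmeth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, grp in counts.groupby("sample"):
        covered = grp[grp["n_total"] > 0]
        df = pd.DataFrame(
            {
                "chrom": covered["chrom"],
                "start": covered["pos"],
                "end": covered["pos"] + 1,
                "n_meth": covered["n_meth"],
                "n_unmeth": covered["n_total"] - covered["n_meth"],
            }
        )
        path = out_dir / f"{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def read_bismark_coverage(paths) -> pd.DataFrame:
    frames = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "n_meth", "n_unmeth"],
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample": path.stem,
                    "chrom": df["chrom"],
                    "pos": df["start"],
                    "n_meth": df["n_meth"],
                    "n_total": df["n_meth"] + df["n_unmeth"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_pwm_jaspar(path, pseudocount: float = 1e-3) -> PWM:
    """Parse a JASPAR-format count/frequency matrix.

    Expected layout: a ``>`` header line, then four lines ``A [ ... ]`` etc.
    Counts are normalized per column before the pseudocount is applied.
    """
    name = Path(path).stem
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[-1]
                continue
            base = line[0].upper()
            nums = line.split("[")[-1].rstrip("]").replace("]", "").split()
            rows[base] = [float(v) for v in nums]
    if set(rows) != set("ACGT"):
        raise ValueError("JASPAR matrix must have A, C, G and T rows")
    mat = np.array([rows[b] for b in "ACGT"]).T  # width x 4
    return PWM(name=name, probs=mat / mat.sum(axis=1, keepdims=True), pseudocount=pseudocount)


def read_pwm_meme(path, pseudocount: float = 1e-3) -> list[PWM]:
    """Parse MEME minimal format; returns every motif in the file."""
    pwms = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name=name, probs=np.array(rows), pseudocount=pseudocount))
                name = s.split()[1]
                rows = []
                in_matrix = False
            elif s.startswith("letter-probability"):
                in_matrix = True
            elif in_matrix and s and s[0].isdigit() or (in_matrix and s.startswith("0")):
                parts = s.split()
                if len(parts) >= 4:
                    rows.append([float(v) for v in parts[:4]])
            elif in_matrix and not s:
                in_matrix = False
    if name is not None and rows:
        pwms.append(PWM(name=name, probs=np.array(rows), pseudocount=pseudocount))
    if not pwms:
        raise ValueError("no motifs found in MEME file")
    return pwms


def read_snp_list(path) -> tuple[list[str], pd.Series | None]:
    """Foreground SNP list: one id per line, optional second column of signs."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    ids = df[0].astype(str).tolist()
    signs = None
    if df.shape[1] > 1:
        signs = pd.Series(df[1].to_numpy(dtype=float), index=ids)
    return ids, signs
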