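"""Import/export of genotypes, phenotypes and solutions.

Genotype matrices travel as TSV (rows = individuals, first column ``id``,
remaining columns = allele-1 dosages 0/1/2) or VCF.  Phenotype tables are
TSV with columns ``id``, ``sex`` (M/F or 0/1), ``strain``, ``phenotype``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome_sim import FEMALE, MALE, GenomeSpec, PopulationState


def write_genotypes_tsv(
    path: str | Path, pop: PopulationState, loci: np.ndarray | None = None
) -> None:
    dos = pop.dosages(loci)
    cols = [f"locus_{i}" for i in (loci if loci is not None else range(dos.shape[1]))]
    df = pd.DataFrame(dos, columns=cols)
    df.insert(0, "id", pop.ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids, dosage matrix)."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError("genotype TSV needs an 'id' column")
    ids = df["id"].to_numpy()
    dos = df.drop(columns="id").to_numpy(dtype=np.int16)
    if dos.min() < 0 or dos.max() > 2:
        raise ValueError("dosages must lie in {0, 1, 2}")
    return ids, dos


def read_genotypes_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a biallelic VCF into (sample ids, dosage matrix)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    rows = []
    for var in vcf:
        gt = np.array(var.gt_types, copy=True)  # cyvcf2 reuses its buffers
        if np.any(gt == 3):
            raise ValueError("missing genotypes are not supported")
        rows.append(gt)
    if not rows:
        raise ValueError("no variants in VCF")
    return samples, np.array(rows, dtype=np.int16).T


def read_genotypes(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    p = Path(path)
    if p.suffix in (".vcf", ".gz", ".bcf"):
        return read_genotypes_vcf(p)
    return read_genotypes_tsv(p)


_SEX_CODES = {"M": MALE, "F": FEMALE, "0": MALE, "1": FEMALE, 0: MALE, 1: FEMALE}


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "sex", "strain", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype TSV missing columns: {sorted(missing)}")
    df = df.copy()
    df["sex"] = df["sex"].map(lambda v: _SEX_CODES.get(v, _SEX_CODES.get(str(v).upper())))
    if df["sex"].isna().any():
        raise ValueError("unrecognised sex codes (use M/F or 0/1)")
    return df


def write_phenotypes_tsv(path: str | Path, pop: PopulationState) -> None:
    if pop.phenotype is None:
        raise ValueError("population carries no phenotypes")
    pd.DataFrame(
        {
            "id": pop.ids,
            "sex": np.where(pop.sex == MALE, "M", "F"),
            "strain": pop.strain,
            "phenotype": pop.phenotype,
            "true_bv": pop.bv,
        }
    ).to_csv(path, sep="\t", index=False)


def write_markers_vcf(
    path: str | Path, pop: PopulationState, spec: GenomeSpec
) -> None:
    """Export the marker loci as a phased VCF (CHROM = chromosome index,
    POS = 1-based rank within the chromosome)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=basepop")
    for c in range(spec.n_chromosomes):
        header.contigs.add(f"chr{c + 1}", length=spec.n_loci_per_chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for i in pop.ids:
        header.add_sample(str(int(i)))
    t = spec.n_loci_per_chrom
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for locus in spec.marker_indices:
            chrom, rank = divmod(int(locus), t)
            rec = vf.new_record(
                contig=f"chr{chrom + 1}",
                start=rank,
                stop=rank + 1,
                alleles=("A", "G"),
            )
            for k, i in enumerate(pop.ids):
                rec.samples[k]["GT"] = (
                    int(pop.haplotypes[k, 0, locus]),
                    int(pop.haplotypes[k, 1, locus]),
                )
                rec.samples[k].phased = True
            vf.write(rec)
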