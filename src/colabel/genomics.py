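"""VCF reduction to a samples x SNPs genotype dosage matrix.

Cohort VCFs are merged on exact (chromosome, position, ref, alt) identity;
retained sites are biallelic SNPs present in every input, with no missing
genotype in any sample and a merged-cohort minor-allele frequency at or above
the floor (1% by default). Genotypes are recoded additively in the minor
allele: 0 = homozygous major, 1 = heterozygous, 2 = homozygous minor, with
the reference allele taken as major at frequency ties.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import LabeledDataset, ValidationError

__all__ = ["GenotypeMatrix", "vcf_to_matrix", "matrix_to_dataset"]

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class GenotypeMatrix:
    values: np.ndarray  # samples x SNPs, int8 in {0, 1, 2}
    sample_ids: list[str]
    records: pd.DataFrame  # chrom, pos, ref, alt, id, maf

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be 2-D")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValidationError("genotype codes must be 0, 1 or 2")
        if self.values.shape != (len(self.sample_ids), len(self.records)):
            raise ValidationError("genotype matrix shape mismatch")

    @property
    def maf(self) -> np.ndarray:
        return self.records["maf"].to_numpy()

    def to_csv(self, matrix_path, records_path=None) -> None:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.records["id"]
        )
        df.index.name = "sample"
        df.to_csv(matrix_path)
        if records_path is not None:
            self.records.to_csv(records_path, index=False)


def _site_key(variant) -> tuple[str, int, str, str]:
    return (variant.CHROM, variant.POS, variant.REF, variant.ALT[0])


def _read_cohort(path) -> tuple[list[str], dict, Counter]:
    """Per-file pass: sample ids, {site key: alt-dosage vector}, drop counts."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: dict = {}
    drops: Counter = Counter()
    for variant in vcf:
        if len(variant.ALT) != 1:
            drops["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1 or not (
            {variant.REF, variant.ALT[0]} <= _BASES
        ):
            drops["not_snp"] += 1
            continue
        gts = variant.genotypes  # [a0, a1, phased] per sample
        alleles = np.array([[g[0], g[1]] for g in gts])
        if (alleles < 0).any():
            drops["missing"] += 1
            continue
        sites[_site_key(variant)] = alleles.sum(axis=1).astype(np.int8)
    vcf.close()
    for reason, count in drops.items():
        logger.info("%s: dropped %d sites (%s)", path, count, reason)
    return samples, sites, drops


def vcf_to_matrix(paths, maf_floor: float = 0.01) -> GenotypeMatrix:
    """Merge one or more cohort VCFs into a filtered 0/1/2 dosage matrix."""
    if isinstance(paths, (str, bytes)) or not hasattr(paths, "__iter__"):
        paths = [paths]
    paths = list(paths)
    cohorts = [_read_cohort(p) for p in paths]

    all_samples: list[str] = []
    for samples, _, _ in cohorts:
        dup = set(samples) & set(all_samples)
        if dup:
            raise ValidationError(f"duplicate sample ids across files: {sorted(dup)}")
        all_samples.extend(samples)

    shared = set(cohorts[0][1])
    for _, sites, _ in cohorts[1:]:
        shared &= set(sites)
    if len(cohorts) > 1:
        union = set().union(*(set(s) for _, s, _ in cohorts))
        logger.info("shared sites: %d of %d union", len(shared), len(union))

    keys = sorted(shared)
    kept_cols, kept_records = [], []
    n_chrom = 2 * len(all_samples)
    for chrom, pos, ref, alt in keys:
        dosage = np.concatenate([sites[(chrom, pos, ref, alt)] for _, sites, _ in cohorts])
        alt_freq = dosage.sum() / n_chrom
        maf = min(alt_freq, 1.0 - alt_freq)
        if maf < maf_floor:
            logger.info("%s:%d %s>%s dropped (maf %.4f < floor)", chrom, pos, ref, alt, maf)
            continue
        # ties: reference allele counts as major
        minor_is_alt = alt_freq <= 0.5
        codes = dosage if minor_is_alt else 2 - dosage
        kept_cols.append(codes.astype(np.int8))
        kept_records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "id": f"{chrom}:{pos}:{ref}:{alt}",
                "maf": maf,
            }
        )
    if not kept_records:
        raise ValidationError("no sites retained after filtering")
    values = np.column_stack(kept_cols)
    return GenotypeMatrix(values, all_samples, pd.DataFrame(kept_records))


def matrix_to_dataset(
    gmatrix: GenotypeMatrix,
    labels: dict[str, str],
    groups: dict[str, int] | None = None,
    label_names: list[str] | None = None,
) -> LabeledDataset:
    """Attach per-sample labels (and optional group codes) to the genotype
    matrix, yielding a model-ready dataset with SNP identifiers as feature
    names."""
    unmatched = [s for s in gmatrix.sample_ids if s not in labels]
    if unmatched:
        raise ValidationError(f"samples without labels: {unmatched}")
    names = label_names or sorted({str(v) for v in labels.values()})
    code_of = {v: k + 1 for k, v in enumerate(names)}
    try:
        y = np.array([code_of[str(labels[s])] for s in gmatrix.sample_ids])
    except KeyError as err:
        raise ValidationError(f"label value {err} outside label_names") from err
    if groups is None:
        g = np.ones(len(gmatrix.sample_ids), dtype=int)
    else:
        missing = [s for s in gmatrix.sample_ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        g = np.array([int(groups[s]) for s in gmatrix.sample_ids])
    return LabeledDataset(
        gmatrix.values.astype(float),
        y,
        g,
        list(gmatrix.records["id"]),
        list(names),
    )
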