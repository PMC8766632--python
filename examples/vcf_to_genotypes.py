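"""Reduce cohort VCFs to a model-ready genotype matrix.

Writes two tiny single-chromosome VCFs (a 'case' and a 'control' cohort),
merges them on exact (chrom, pos, ref, alt) identity, applies the standard
filters — biallelic SNPs only, no missing genotypes, minor-allele frequency
at least 1% in the merged cohort — and recodes genotypes additively in the
minor allele (0 = hom-major, 1 = het, 2 = hom-minor). The matrix is then
attached to per-sample labels for co-inference.
"""

import tempfile
from pathlib import Path

from colabel import matrix_to_dataset, vcf_to_matrix

HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)

CASES = HEADER + "C1\tC2\tC3\n" + "\n".join(
    [
        "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0",
        "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0",
        "1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/0\t0/0",  # missing: dropped
    ]
) + "\n"

CONTROLS = HEADER + "K1\tK2\tK3\n" + "\n".join(
    [
        "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1",
        "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0",
        "1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0",  # only here: dropped
    ]
) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    a = Path(tmp) / "cases.vcf"
    b = Path(tmp) / "controls.vcf"
    a.write_text(CASES)
    b.write_text(CONTROLS)

    gm = vcf_to_matrix([a, b], maf_floor=0.01)
    print("samples:", gm.sample_ids)
    print(gm.records[["chrom", "pos", "ref", "alt", "maf"]].to_string(index=False))
    print("genotype codes (rows = samples):")
    print(gm.values)

    labels = {s: ("case" if s.startswith("C") else "control") for s in gm.sample_ids}
    ds = matrix_to_dataset(gm, labels, label_names=["case", "control"])
    print("dataset:", ds.n_rows, "samples x", ds.n_features, "SNPs,", ds.label_names)
# Sites 300 (missing call) and 400 (absent from one cohort) are dropped; the
# two shared SNPs survive with their merged-cohort minor-allele frequencies.
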