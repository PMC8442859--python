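"""VCFv4.2 round-trip for synthetic genotype matrices.

Genotypes are written as unphased diploid GT fields (0/0, 0/1, 1/1, ./.) on a
single synthetic contig with 1-based positions. Cohort labels travel in a
sidecar tab-separated sample-metadata table with columns ``sample_id`` and
``cohort``. Reading goes through cyvcf2; multiallelic records are rejected
explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import DataError, VcfFormatError
from .genotypes import MISSING, GenotypeMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
# fixed arbitrary alleles for a purely synthetic biallelic panel
_REF, _ALT = "A", "T"


def default_meta_path(vcf_path) -> Path:
    return Path(str(vcf_path) + ".samples.tsv")


def write_vcf(gm: GenotypeMatrix, path, meta_path=None) -> Path:
    """Write genotypes as plain-text VCFv4.2 plus a sample-metadata TSV."""
    path = Path(path)
    meta_path = default_meta_path(path) if meta_path is None else Path(meta_path)
    max_pos = int(gm.positions.max()) if gm.n_loci else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.contig},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_loci):
            gts = "\t".join(_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{gm.contig}\t{gm.positions[j]}\tsnp{j}\t{_REF}\t{_ALT}\t.\tPASS\t.\tGT\t{gts}\n")
    pd.DataFrame({"sample_id": gm.samples, "cohort": [str(c) for c in gm.cohorts]}).to_csv(
        meta_path, sep="\t", index=False
    )
    return path


def read_sample_metadata(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if not {"sample_id", "cohort"} <= set(meta.columns):
        raise DataError(f"{meta_path}: metadata must have columns sample_id, cohort")
    if meta["cohort"].isna().any() or (meta["cohort"].str.len() == 0).any():
        bad = meta.loc[meta["cohort"].isna() | (meta["cohort"].str.len() == 0), "sample_id"]
        raise DataError(f"empty cohort label for sample(s): {', '.join(bad)}")
    return meta


def read_vcf(path, meta_path=None) -> GenotypeMatrix:
    """Read a diploid biallelic VCF and its sample-metadata sidecar.

    Raises :class:`VcfFormatError` (naming the record) on multiallelic sites
    and :class:`DataError` when a VCF sample lacks a cohort label.
    """
    path = Path(path)
    meta_path = default_meta_path(path) if meta_path is None else Path(meta_path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    contig = "chrS"
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfFormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} ({rec.ID}) is not biallelic "
                f"(ALT={','.join(rec.ALT) or '.'})"
            )
        contig = rec.CHROM
        positions.append(rec.POS)
        gt = rec.gt_types.astype(np.int8)  # 0=hom-ref 1=het 2=hom-alt 3=unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if not rows:
        raise VcfFormatError(f"{path}: no variant records")

    meta = read_sample_metadata(meta_path).set_index("sample_id")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise DataError(f"no cohort metadata for sample(s): {', '.join(missing)}")
    cohorts = np.array([meta.loc[s, "cohort"] for s in samples], dtype=object)
    return GenotypeMatrix(
        dosages=np.array(rows, dtype=np.int8).T,
        samples=samples,
        cohorts=cohorts,
        positions=np.array(positions, dtype=np.int64),
        contig=contig,
    )
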