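"""Reading and writing the genotype-call VCFs the pipeline starts from.

The pipeline consumes the product of an upstream variant caller: a multi-sample
VCF with ``GT`` and ``DP`` per-sample fields, sites called against a unigene
reference (the unigene identifier is the CHROM column).  Reading uses cyvcf2;
writing emits the same minimal VCF subset as text, which is sufficient for
round-tripping calls and depths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .calls import Call, CallMatrix, ConfigError, FormatError, PanelKind


def read_genotype_vcf(
    path: str,
    sample_roles: dict[str, str],
    panel_kind: PanelKind,
    multiallelic: str = "error",
) -> CallMatrix:
    """Load a VCF into a :class:`CallMatrix`.

    GT is mapped 0/0 -> REF_HOM, 0/1 or 1/0 -> HET, 1/1 -> ALT_HOM,
    ./. -> MISSING; phased separators are treated as unphased.  Records with
    more than one ALT allele are rejected (``multiallelic="error"``, the
    default — the genotype classes are defined for two alleles only) or
    silently dropped (``multiallelic="drop"``).
    """
    if multiallelic not in ("error", "drop"):
        raise ConfigError("multiallelic must be 'error' or 'drop'")
    vcf = VCF(str(path), gts012=True)
    header = vcf.raw_header
    for fmt in ("GT", "DP"):
        if f"##FORMAT=<ID={fmt}," not in header:
            raise FormatError(f"VCF lacks required per-sample field {fmt}")
    samples = list(vcf.samples)
    missing_roles = set(sample_roles) - set(samples)
    if missing_roles:
        raise ConfigError(f"role sample(s) not in VCF header: {sorted(missing_roles)}")

    unigenes, positions, calls_rows, depth_rows = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) > 1:
            if multiallelic == "error":
                raise FormatError(
                    f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                    "(pass multiallelic='drop' to skip such records)"
                )
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        calls = np.where(gt == 3, np.int8(Call.MISSING), gt)
        dp = variant.format("DP")
        if dp is None:
            raise FormatError(f"record at {variant.CHROM}:{variant.POS} lacks DP")
        dp = np.asarray(dp, dtype=np.int64).reshape(-1)
        dp = np.where(dp < 0, 0, dp)  # htslib encodes missing DP as a negative sentinel
        unigenes.append(variant.CHROM)
        positions.append(variant.POS)
        calls_rows.append(calls)
        depth_rows.append(dp)
    vcf.close()

    sites = pd.DataFrame({"unigene": unigenes, "position": positions})
    n = len(samples)
    calls = np.array(calls_rows, dtype=np.int8).reshape(len(sites), n)
    depths = np.array(depth_rows, dtype=np.int32).reshape(len(sites), n)
    return CallMatrix(samples, dict(sample_roles), sites, calls, depths, panel_kind)


_GT_STRINGS = {int(Call.REF_HOM): "0/0", int(Call.HET): "0/1",
               int(Call.ALT_HOM): "1/1", int(Call.MISSING): "./."}


def write_genotype_vcf(matrix: CallMatrix, path: str) -> None:
    """Write a CallMatrix as a minimal VCFv4.2 file (GT:DP per sample).

    Allele identities are not tracked by the pipeline, so REF/ALT are written
    as placeholder A/G; ``read_genotype_vcf`` recovers calls and depths
    exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=maplink\n")
        for unigene in dict.fromkeys(matrix.sites["unigene"]):
            fh.write(f"##contig=<ID={unigene}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            cells = [f"{_GT_STRINGS[int(c)]}:{int(d)}"
                     for c, d in zip(matrix.calls[i], matrix.depths[i])]
            fh.write(f"{row['unigene']}\t{int(row['position'])}\t.\tA\tG\t.\tPASS\t.\tGT:DP\t"
                     + "\t".join(cells) + "\n")
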