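#!/usr/bin/env python
"""Generate the synthetic study: a ground-truth genome, an F2 mapping panel
and a MAL anchoring panel, written as VCFs plus a truth table.

The scenario mirrors the study conditions: 8 chromosomes totalling 936.6 cM,
800 unigene loci (~0.4 single-SNP), 96 F2 lines at mean read depth 20, a MAL
panel at mean depth 30 with 2% spurious-heterozygote and 2% carrier-dropout
noise.  Downstream drivers (02..05) start from these files.
"""

from pathlib import Path

from maplink.simulate import (
    DEFAULT_N_LINES,
    DEFAULT_TOTAL_CM,
    ErrorModel,
    simulate_f2_genotypes,
    simulate_mal_panel,
    simulate_read_calls,
    simulate_true_map,
    write_truth_table,
)
from maplink.vcfio import write_genotype_vcf

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    true_map = simulate_true_map(n_unigenes=800, total_cM=DEFAULT_TOTAL_CM, seed=SEED)
    geno = simulate_f2_genotypes(true_map, DEFAULT_N_LINES, seed=SEED + 1)
    f2 = simulate_read_calls(geno, true_map, ErrorModel(mean_depth=20), seed=SEED + 2)
    mal = simulate_mal_panel(
        true_map,
        ErrorModel(mean_depth=30, mal_spurious_het_rate=0.02, mal_dropout_rate=0.02),
        seed=SEED + 3)

    write_genotype_vcf(f2, str(OUT / "f2_panel.vcf"))
    write_genotype_vcf(mal, str(OUT / "mal_panel.vcf"))
    write_truth_table(true_map, geno, str(OUT / "truth.tsv"))

    n_sites = f2.n_sites
    print(f"simulated {true_map.n_unigenes} unigenes on 8 chromosomes "
          f"({DEFAULT_TOTAL_CM} cM), {n_sites} F2 SNP sites, "
          f"{DEFAULT_N_LINES} lines")
    print(f"wrote {OUT}/f2_panel.vcf, mal_panel.vcf, truth.tsv")


if __name__ == "__main__":
    main()
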