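#!/usr/bin/env python
"""Consolidate the F2 panel's SNP sites into S/O/R unigene markers.

Reads results/synthetic/f2_panel.vcf, applies the co-dominance and
depth >= 2 filters, collapses each unigene's sites into one marker, and
reports the class split — the solid (S) markers are the mapping input."""

from pathlib import Path

from maplink.calls import PanelKind, ROLE_F2, ROLE_PARENT_ALT, ROLE_PARENT_REF, Thresholds
from maplink.markers import build_markers
from maplink.tables import write_marker_table
from maplink.vcfio import read_genotype_vcf

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    path = RESULTS / "synthetic" / "f2_panel.vcf"
    # roles: two parents, everything else is an F2 line
    from cyvcf2 import VCF
    samples = VCF(str(path)).samples
    roles = {"DHA": ROLE_PARENT_REF, "DHC": ROLE_PARENT_ALT}
    roles.update({s: ROLE_F2 for s in samples if s not in roles})

    panel = read_genotype_vcf(str(path), roles, PanelKind.F2)
    markers, summary, dropped = build_markers(panel, Thresholds())
    line_names = [panel.samples[i] for i in panel.f2_indices]
    write_marker_table(markers, str(RESULTS / "markers.tsv"), line_names)

    print(f"sites in: {panel.n_sites}; dropped: {dict(dropped)}; "
          f"retained: {summary['retained_sites']}")
    print(f"unigenes retained: {summary['retained_unigenes']} "
          f"(one-SNP {summary['one_snp_unigenes']}, "
          f"multi-SNP {summary['multi_snp_unigenes']})")
    print(f"marker classes: S={summary['S']}  O={summary['O']}  R={summary['R']}")
    print(f"wrote {RESULTS}/markers.tsv")


if __name__ == "__main__":
    main()
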