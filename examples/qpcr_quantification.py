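"""Calibrate synthetic qPCR runs and compute denitrifier gene ratios.

Generates a dilution-series + sample run table at a known amplification
efficiency, refits the standard curve, quantifies each gene and prints the
ratio proxies that track the community's N2O-accumulation potential.
"""

from denitcath.qpcr import average_replicates, fit_standard_curve, gene_ratios, quantify
from denitcath.synthetic import DEFAULT_GENE_ABUNDANCES, gen_qpcr

true_copies = {
    gene: {p: DEFAULT_GENE_ABUNDANCES[p][gene] for p in DEFAULT_GENE_ABUNDANCES}
    for gene in ("narG", "napA", "nirS", "nirK", "nosZ", "16S")
}
runs = gen_qpcr(true_copies, efficiency=0.95, sigma_ct=0.05, seed=42)

curves = {
    gene: fit_standard_curve(grp.copies, grp.ct, gene=gene)
    for gene, grp in runs[runs.role == "standard"].groupby("gene")
}
print("standard curves (true efficiency 95 %):")
for gene, curve in sorted(curves.items()):
    print(f"  {gene:8s} slope {curve.slope:7.3f}  E {100 * curve.efficiency:5.1f} %"
          f"  r2 {curve.r2:.4f}")

for period in sorted(DEFAULT_GENE_ABUNDANCES):
    abundances = {}
    for gene, grp in runs[(runs.role == "sample")
                          & (runs.sample_id == period)].groupby("gene"):
        mean_ct, _ = average_replicates(grp.ct.to_numpy())
        abundances[gene] = quantify(
            mean_ct, curves[gene], float(grp.dna_ng.iloc[0])
        ).copies_per_ng
    ratios = gene_ratios(abundances)
    print(f"{period}: (qnirK+qnirS)/qnosZ = {ratios.nir_over_nosz:6.2f}, "
          f"qnosZ/q16S (x100) = {ratios.nosz_16s:5.2f}")

# A high nitrite-reductase to nitrous-oxide-reductase ratio means more N
# can reach N2O than can be reduced onward to N2 - the community-level
# fingerprint of N2O accumulation.
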