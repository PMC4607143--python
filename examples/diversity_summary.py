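"""Diversity statistics: HWE, heterozygosity and amplicon haplotypes.

Computes per-locus stats (MAF, observed/expected heterozygosity, exact HWE
p-value), the per-individual heterozygosity distribution with its < 30
typed-loci exclusion guard, and EM haplotype frequencies for one amplicon.
"""

import numpy as np

from ampliped import (FacilitySpec, SimPanelSpec, SimPopSpec,
                      apply_observation_model, diversity_report,
                      em_haplotypes, generate_panel,
                      individual_heterozygosity, locus_stats,
                      simulate_population)

panel, pools = generate_panel(
    SimPanelSpec(n_amplicons=6, snps_per_amplicon=(3, 10),
                 haplotypes_per_amplicon=(2, 5)), seed=11)
pop = SimPopSpec(n_founders=120,
                 facilities=[FacilitySpec("pen", 2, True, 0, 2)],
                 missing_rate=0.25, error_rate=0.0, rng_seed=12)
truth, records, registry = simulate_population(panel, pools, pop)
observed = apply_observation_model(truth, pop, seed=13)

stats = locus_stats(observed, panel, alpha=0.05)
out_of_hwe = [s for s in stats if not s.in_hwe]
print(f"{len(stats)} biallelic loci; {len(out_of_hwe)} deviate from HWE "
      f"at alpha=0.05 (exact two-sided test)")

records_het, (edges, counts) = individual_heterozygosity(observed, min_loci=30)
included = [r for r in records_het if r.included]
fracs = [r.het_fraction for r in included]
print(f"{len(included)} individuals with >= 30 typed loci; "
      f"median heterozygosity {np.median(fracs):.3f}, "
      f"{np.mean([f < 0.25 for f in fracs]):.0%} below 0.25")
print("histogram (bin width 0.05):",
      " ".join(str(c) for c in counts[:10]), "...")

amp = panel.amplicons[0]
table = em_haplotypes(observed, amp)
print(f"\nEM haplotype frequencies for {amp.amplicon_id} "
      f"({amp.n_loci} linked SNPs, {table.n_samples_used} complete samples, "
      f"{table.n_iterations} iterations):")
for hap, freq in table.haplotypes[:6]:
    print(f"  {hap}: {freq:.3f}")
true_pool = pools[amp.amplicon_id]
print(f"generator truth: {len(true_pool.frequencies)} founder haplotypes — "
      "the EM estimate recovers the pool when genotyping is complete.")

print("\nper-amplicon report (SNPs, loci out of HWE, haplotype count):")
print(diversity_report(observed, panel)
      .to_string(index=False))
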