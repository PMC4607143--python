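"""Likelihood parentage assignment with simulation-calibrated confidence.

Simulates breeding groups with a known dam and candidate sires, runs the
trio-LOD analysis against the generator's ground truth, and shows how the
Monte-Carlo critical delta grades each assignment.
"""

import warnings

import numpy as np

from ampliped import (FacilitySpec, ParentageConfig, SimPanelSpec, SimPopSpec,
                      apply_observation_model, assign_parentage,
                      generate_panel, simulate_population)

warnings.filterwarnings("ignore")

panel, pools = generate_panel(
    SimPanelSpec(n_amplicons=12, snps_per_amplicon=(8, 20),
                 haplotypes_per_amplicon=(3, 6)), seed=21)
pop = SimPopSpec(
    n_founders=40,
    facilities=[FacilitySpec(f"pen{i}", 2, known_dam=True,
                             n_candidate_dams=0, n_candidate_sires=3)
                for i in range(5)],
    missing_rate=0.35, error_rate=0.01, rng_seed=22)
truth, records, registry = simulate_population(panel, pools, pop)
observed = apply_observation_model(truth, pop, seed=23)

cfg = ParentageConfig(error_rate=0.01, min_shared_loci=20,
                      sim_cycles=3000, rng_seed=24)
results = assign_parentage(registry, observed, panel, cfg, records)

hits = sum(r.assignment == truth.pedigree[r.offspring_id][1] for r in results)
print(f"{hits} of {len(results)} offspring assigned their true sire\n")
print(f"{'offspring':<12} {'assigned':<12} {'conf':<10} {'delta':>7} "
      f"{'crit(95%)':>9}  top candidates (LOD, shared, exclusions)")
for r in results[:6]:
    ranking = "; ".join(
        f"{s.candidate_id}({s.lod:.1f}, {s.shared_loci}, {s.exclusions})"
        for s in r.candidates[:2])
    crit = r.critical_delta.get("strict", float("nan"))
    print(f"{r.offspring_id:<12} {str(r.assignment):<12} {r.confidence:<10} "
          f"{r.delta:>7.2f} {crit:>9.3f}  {ranking}")

print("\nA positive LOD says the candidate explains the offspring better than")
print("a random animal at the facility's allele frequencies; delta (gap to")
print("the runner-up) must exceed the simulated critical value for a strict")
print("(95%) assignment. Mendelian exclusions are opposing-homozygote loci.")
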