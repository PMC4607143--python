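"""Variant-call filtering and panel QC on a synthetic dataset.

Shows the three QC layers: the read-support filter on pileup sites
(depth >= 4 quality reads, alternate support >= max(2 reads, 20% of depth)),
the minor-allele-frequency exclusion (MAF < 0.03 removed), and per-amplicon
call-rate / informativeness flags.
"""

import numpy as np

from ampliped import (FacilitySpec, FilterConfig, PileupSite, SimPanelSpec,
                      SimPopSpec, amplicon_qc, apply_maf_filter,
                      apply_observation_model, filter_variant_call,
                      generate_panel, simulate_population)

# 1. the read-support rule on a few pileup summaries
print("read-support filter (depth_q, alt_count) -> verdict")
for depth, alt in [(3, 3), (4, 2), (20, 3), (20, 4), (200, 45)]:
    res = filter_variant_call(PileupSite("chr1", 1000, depth, alt))
    verdict = "PASS" if res.passed else f"FAIL({res.reason})"
    print(f"  depth={depth:>3} alt={alt:>2}: {verdict}")
print("The 2-read floor governs below 10x; the 20% rule above it.\n")

# 2. MAF filter on simulated genotypes
panel, pools = generate_panel(
    SimPanelSpec(n_amplicons=8, snps_per_amplicon=(4, 15)), seed=3)
pop = SimPopSpec(n_founders=60,
                 facilities=[FacilitySpec("pen", 2, True, 0, 2)],
                 missing_rate=0.3, rng_seed=4)
truth, records, registry = simulate_population(panel, pools, pop)
observed = apply_observation_model(truth, pop, seed=5)

filtered, removed = apply_maf_filter(observed, FilterConfig(maf_threshold=0.03))
print(f"MAF filter: {len(removed)} of {observed.n_loci} loci removed "
      f"(minor allele below 3%), {filtered.n_loci} retained")

# 3. per-amplicon QC
qc = amplicon_qc(filtered, panel)
flagged = qc[qc.qc_flags != ""]
print(f"amplicon QC: {len(flagged)} of {len(qc)} amplicons flagged")
print(qc.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print("\n'low_information' marks amplicons left with <= 2 usable SNPs;")
print("'dropout_suspect' marks call rates below 50% (amplification failure).")
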