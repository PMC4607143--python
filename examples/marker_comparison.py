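"""Compare the discriminating power of a SNP panel and a small
microsatellite set for parentage.

Uses the likelihood machinery directly: the mean trio LOD of the true sire
(and the delta to an unrelated candidate) under a 192-SNP biallelic panel
versus 12 low-diversity multi-allelic loci.
"""

import numpy as np

from ampliped.parentage import ParentageModel, simulate_trials

rng = np.random.default_rng(31)


def summarise(freqs, label):
    model = ParentageModel(freqs, error_rate=0.01)
    deltas, correct = simulate_trials(model, n_candidates=2, cycles=800,
                                      typed_p=1.0, prop_candidates_sampled=1.0,
                                      mode="trio", rng=rng, min_shared_loci=1)
    print(f"{label:<28} mean delta {deltas.mean():7.2f}   "
          f"true sire top-ranked {correct.mean():6.1%}")
    return deltas.mean()


snp_freqs = [np.array([0.75, 0.25])] * 192
msat_freqs = [np.array([0.8, 0.15, 0.05])] * 12  # one dominant allele each

print("trio analysis, known dam + 2 candidate sires, no missingness:\n")
snp = summarise(snp_freqs, "192 SNPs (MAF 0.25)")
msat = summarise(msat_freqs, "12 microsatellites (3 alleles)")
print(f"\nThe SNP panel's mean LOD gap is {snp / msat:.1f}x the microsatellite")
print("set's: many biallelic loci beat a handful of low-diversity")
print("multi-allelic markers for discriminating close candidates.")
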