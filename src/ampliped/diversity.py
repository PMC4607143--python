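"""Per-locus and per-individual diversity statistics and amplicon haplotypes.

* Exact two-sided Hardy-Weinberg test on biallelic genotype counts,
  conditioning on the observed allele counts.
* Observed vs expected heterozygosity, with the small-sample
  2p(1-p) * n/(n-1) estimator for H_exp.
* Per-individual heterozygous fraction with a minimum-typed-loci guard.
* Expectation-maximisation of within-amplicon haplotype frequencies from
  unphased multi-locus genotypes (gene-counting / Excoffier-Slatkin style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix
from .panel import Amplicon, AmpliconPanel


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value for one biallelic locus.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count (same parity as the minor-allele count) is

        P(h) = n! / (n_hom1! h! n_hom2!) * 2**h / [ (2n)! / (n1! n2!) ]

    and the p-value sums P over all heterozygote counts whose probability
    does not exceed that of the observed table.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n1 = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice irrelevant
    n1 = min(n1, 2 * n - n1)
    if n1 == 0:
        return 1.0
    hets = np.arange(n1 % 2, n1 + 1, 2)
    hom_rare = (n1 - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(np.nonzero(hets == n_Aa)[0][0])
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

@dataclass
class LocusStats:
    locus_id: str
    amplicon_id: str
    n_typed: int
    maf: float
    h_obs: float
    h_exp: float
    hwe_p: float
    in_hwe: bool


def observed_expected_het(matrix: GenotypeMatrix, locus_id: str):
    """(H_obs, H_exp, n_typed) at one biallelic locus.

    H_exp carries the unbiased n/(n-1) small-sample correction (0 when n < 2).
    """
    j = matrix.locus_index(locus_id)
    col = matrix.pairs[:, j, :]
    typed = col[:, 0] >= 0
    n = int(typed.sum())
    if n == 0:
        return 0.0, 0.0, 0
    het = col[typed, 0] != col[typed, 1]
    h_obs = float(het.mean())
    counts = matrix.allele_counts(locus_id)
    p = counts[1] / counts.sum() if counts.sum() else 0.0
    h_exp = 2.0 * p * (1.0 - p) * n / (n - 1) if n > 1 else 0.0
    return h_obs, float(min(h_exp, 1.0)), n


def genotype_counts(matrix: GenotypeMatrix, locus_id: str) -> tuple[int, int, int]:
    """(n_homref, n_het, n_homalt) at a biallelic locus."""
    j = matrix.locus_index(locus_id)
    col = matrix.pairs[:, j, :]
    typed = col[col[:, 0] >= 0]
    dosage = typed.sum(axis=1)
    return int((dosage == 0).sum()), int((dosage == 1).sum()), int((dosage == 2).sum())


def locus_stats(
    matrix: GenotypeMatrix,
    panel: AmpliconPanel | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[LocusStats]:
    """Per-locus MAF, heterozygosities and exact HWE test.

    ``in_hwe`` is hwe_p >= alpha (no multiple-testing correction by default;
    ``bonferroni=True`` divides alpha by the number of testable loci).
    """
    from .filtering import compute_maf

    thr = alpha / max(matrix.n_loci, 1) if bonferroni else alpha
    out = []
    for locus in matrix.loci:
        if not locus.is_biallelic:
            continue
        n_rr, n_ra, n_aa = genotype_counts(matrix, locus.locus_id)
        n = n_rr + n_ra + n_aa
        h_obs, h_exp, _ = observed_expected_het(matrix, locus.locus_id)
        maf = compute_maf(matrix, locus.locus_id)
        p = hwe_exact_test(n_rr, n_ra, n_aa) if n >= 1 else 1.0
        out.append(LocusStats(
            locus_id=locus.locus_id,
            amplicon_id=locus.amplicon_id,
            n_typed=n,
            maf=maf if maf is not None else float("nan"),
            h_obs=h_obs,
            h_exp=h_exp,
            hwe_p=p,
            in_hwe=bool(p >= thr),
        ))
    return out


# ---------------------------------------------------------------------------
# per-individual heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class IndividualHet:
    sample_id: str
    n_typed: int
    het_fraction: float
    included: bool


def individual_heterozygosity(
    matrix: GenotypeMatrix, min_loci: int = 30, bin_width: float = 0.05
):
    """Heterozygous fraction per sample, plus a histogram over included samples.

    Samples typed at fewer than ``min_loci`` loci are marked excluded (their
    fraction is still reported). Returns (records, (bin_edges, counts)).
    """
    typed = matrix.pairs[:, :, 0] >= 0
    het = typed & (matrix.pairs[:, :, 0] != matrix.pairs[:, :, 1])
    n_typed = typed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_typed > 0, het.sum(axis=1) / np.maximum(n_typed, 1), 0.0)
    records = [
        IndividualHet(s, int(n), float(f), bool(n >= min_loci))
        for s, n, f in zip(matrix.samples, n_typed, frac)
    ]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    included = frac[n_typed >= min_loci]
    counts, _ = np.histogram(included, bins=edges)
    return records, (edges, counts)


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    amplicon_id: str
    haplotypes: list[tuple[str, float]]
    loglik: float
    n_iterations: int
    n_samples_used: int = 0
    n_samples_dropped: int = 0

    @property
    def frequencies(self) -> dict[str, float]:
        return dict(self.haplotypes)


_MAX_HET_SITES = 16  # 2**(h-1) compatible phasings; beyond this an individual is dropped


def _compatible_pairs(geno: np.ndarray) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with one unphased genotype.

    ``geno`` is (n_loci, 2) sorted allele indices, no missing entries.
    """
    het_sites = np.nonzero(geno[:, 0] != geno[:, 1])[0]
    base_a = geno[:, 0].copy()
    base_b = geno[:, 1].copy()
    if len(het_sites) == 0:
        h = tuple(base_a)
        return [(h, h)]
    pairs = []
    # fix the first het site's phase to avoid double-counting mirror pairs
    for bits in product((0, 1), repeat=len(het_sites) - 1):
        a = base_a.copy()
        b = base_b.copy()
        for site, bit in zip(het_sites[1:], bits):
            if bit:
                a[site], b[site] = geno[site, 1], geno[site, 0]
        pairs.append((tuple(a), tuple(b)))
    return pairs


def em_haplotypes(
    matrix: GenotypeMatrix,
    amplicon: Amplicon,
    tol: float = 1e-6,
    max_iter: int = 1000,
    prune: float = 1e-6,
) -> HaplotypeTable:
    """EM estimate of haplotype frequencies within one amplicon.

    Samples with any missing call inside the amplicon are dropped from the
    estimation (counted in the result). The E-step distributes each genotype
    over its compatible haplotype pairs proportional to f_j * f_k (x2 when
    j != k); the M-step re-estimates frequencies from the expected counts.
    Initialisation is the product of single-locus allele frequencies, making
    the fit deterministic.
    """
    ids = [l.locus_id for l in amplicon.loci if l.locus_id in matrix._locus_idx]
    if not ids:
        warnings.warn(f"{amplicon.amplicon_id}: no loci present in matrix")
        return HaplotypeTable(amplicon.amplicon_id, [], float("nan"), 0)
    sub = matrix.subset(loci=ids)
    complete = ~sub.is_missing().any(axis=1)
    genos = sub.pairs[complete]
    n_dropped = int((~complete).sum())
    too_het = np.array([
        (g[:, 0] != g[:, 1]).sum() > _MAX_HET_SITES for g in genos
    ])
    if too_het.any():
        warnings.warn(
            f"{amplicon.amplicon_id}: {int(too_het.sum())} individuals with "
            f"> {_MAX_HET_SITES} heterozygous sites dropped from EM"
        )
        n_dropped += int(too_het.sum())
        genos = genos[~too_het]
    if len(genos) == 0:
        warnings.warn(f"{amplicon.amplicon_id}: no complete individuals; "
                      "haplotype frequencies undefined")
        return HaplotypeTable(amplicon.amplicon_id, [], float("nan"), 0,
                              n_samples_dropped=n_dropped)

    pair_lists = [_compatible_pairs(g) for g in genos]
    hap_index: dict[tuple, int] = {}
    for pairs in pair_lists:
        for a, b in pairs:
            for h in (a, b):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    H = len(hap_index)
    pair_idx = [
        np.array([[hap_index[a], hap_index[b]] for a, b in pairs])
        for pairs in pair_lists
    ]

    # initial frequencies: product of single-locus allele frequencies
    n_loci = genos.shape[1]
    allele_freqs = []
    for j in range(n_loci):
        counts = np.bincount(genos[:, j, :].ravel(),
                             minlength=sub.loci[j].n_alleles).astype(float)
        allele_freqs.append(counts / counts.sum())
    f = np.empty(H)
    for hap, k in hap_index.items():
        f[k] = np.prod([allele_freqs[j][a] for j, a in enumerate(hap)])
    if f.sum() <= 0:
        f[:] = 1.0
    f /= f.sum()

    n_ind = len(genos)
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(H)
        loglik = 0.0
        for pairs in pair_idx:
            w = f[pairs[:, 0]] * f[pairs[:, 1]]
            w = np.where(pairs[:, 0] != pairs[:, 1], 2.0 * w, w)
            total = w.sum()
            if total <= 0:
                # genotype momentarily unexplained; fall back to uniform weights
                w = np.ones(len(pairs))
                total = w.sum()
                loglik += -np.inf
            else:
                loglik += np.log(total)
            w /= total
            np.add.at(expected, pairs[:, 0], w)
            np.add.at(expected, pairs[:, 1], w)
        f_new = expected / (2.0 * n_ind)
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break

    order = np.argsort(-f)
    loci = sub.loci
    sep = "" if all(len(a) == 1 for l in loci for a in l.alleles) else "|"
    haps = []
    for k in order:
        if f[k] < prune:
            continue
        hap_alleles = next(h for h, idx in hap_index.items() if idx == k)
        hap_str = sep.join(loci[j].alleles[a] for j, a in enumerate(hap_alleles))
        haps.append((hap_str, float(f[k])))
    total = sum(fr for _, fr in haps)
    haps = [(h, fr / total) for h, fr in haps]
    return HaplotypeTable(
        amplicon_id=amplicon.amplicon_id,
        haplotypes=haps,
        loglik=float(loglik),
        n_iterations=it,
        n_samples_used=n_ind,
        n_samples_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

def diversity_report(
    matrix: GenotypeMatrix,
    panel: AmpliconPanel,
    alpha: float = 0.05,
    hap_threshold: float = 1e-3,
) -> pd.DataFrame:
    """One row per amplicon: target class, chromosome, SNP count, loci out of
    HWE (count and percentage), haplotype count above ``hap_threshold``;
    plus a totals row."""
    stats = {s.locus_id: s for s in locus_stats(matrix, panel, alpha=alpha)}
    present = set(matrix.locus_ids)
    rows = []
    for amp in panel.amplicons:
        ids = [l.locus_id for l in amp.loci if l.locus_id in present]
        n_snps = len(ids)
        not_hwe = sum(1 for i in ids if i in stats and not stats[i].in_hwe)
        pct = round(100.0 * not_hwe / n_snps) if n_snps else 0
        table = em_haplotypes(matrix, amp) if ids else None
        n_haps = (sum(1 for _, fr in table.haplotypes if fr > hap_threshold)
                  if table is not None else 0)
        chroms = sorted({l.chromosome for l in amp.loci})
        rows.append({
            "amplicon_id": amp.amplicon_id,
            "target_class": amp.target_class,
            "chromosome": ",".join(chroms),
            "n_snps": n_snps,
            "n_not_in_hwe": not_hwe,
            "not_in_hwe": f"{not_hwe} ({pct} %)",
            "n_haplotypes": n_haps,
        })
    totals = {
        "amplicon_id": "Total",
        "target_class": "",
        "chromosome": "",
        "n_snps": sum(r["n_snps"] for r in rows),
        "n_not_in_hwe": sum(r["n_not_in_hwe"] for r in rows),
        "not_in_hwe": str(sum(r["n_not_in_hwe"] for r in rows)),
        "n_haplotypes": sum(r["n_haplotypes"] for r in rows),
    }
    return pd.DataFrame(rows + [totals])
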