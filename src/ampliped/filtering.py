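"""Variant-call filtering and panel QC.

The call filter requires a site to be covered by at least ``min_depth_q``
quality reads, with alternate support of at least ``min_alt_reads`` reads or
``min_alt_fraction`` of the depth, whichever is larger — the absolute read
floor governs low-coverage sites (depth < min_alt_reads / min_alt_fraction),
the fractional rule governs well-covered ones.

Locus-level QC covers minor-allele-frequency exclusion (strict ``< maf_threshold``),
replicate-control discordance, excess-heterozygosity flags for collapsed
segmental duplications, and amplicon-level dropout / low-information flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleRecord
from .panel import AmpliconPanel, PileupSite


@dataclass
class FilterConfig:
    min_depth_q: int = 4
    min_alt_reads: int = 2
    min_alt_fraction: float = 0.20
    maf_threshold: float = 0.03
    qmin: int = 20

    def __post_init__(self) -> None:
        if min(self.min_depth_q, self.min_alt_reads, self.qmin) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_alt_fraction <= 1:
            raise ValueError("min_alt_fraction must be in [0, 1]")
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")


@dataclass
class FilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class LocusQCFlags:
    locus_id: str
    maf_fail: bool = False
    duplication_suspect: bool = False
    call_rate: float = 1.0
    notes: str = ""


def filter_variant_call(site: PileupSite, cfg: FilterConfig | None = None) -> FilterResult:
    """PASS iff depth_q >= min_depth_q and alt support meets the larger of the
    absolute-read and fractional rules. FAIL carries the first violated
    criterion (depth checked first)."""
    cfg = cfg or FilterConfig()
    if site.depth_q < cfg.min_depth_q:
        return FilterResult(False, "depth")
    required = max(cfg.min_alt_reads, math.ceil(cfg.min_alt_fraction * site.depth_q))
    if site.alt_count < required:
        return FilterResult(False, "alt_support")
    return FilterResult(True)


def compute_maf(matrix: GenotypeMatrix, locus_id: str) -> float | None:
    """Minor-allele frequency over non-missing calls; None when all missing.

    For a biallelic locus this is min(p, 1-p); for multi-allelic markers the
    frequency of the second most common allele is returned.
    """
    counts = matrix.allele_counts(locus_id)
    total = counts.sum()
    if total == 0:
        return None
    freqs = np.sort(counts / total)[::-1]
    return float(freqs[1]) if len(freqs) > 1 else 0.0


def apply_maf_filter(
    matrix: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove loci with MAF strictly below the threshold (or undefined).

    Loci at exactly the threshold are retained. Returns the filtered matrix
    and the removed locus ids.
    """
    cfg = cfg or FilterConfig()
    removed, kept = [], []
    for locus in matrix.loci:
        maf = compute_maf(matrix, locus.locus_id)
        if maf is None or maf < cfg.maf_threshold:
            removed.append(locus.locus_id)
        else:
            kept.append(locus.locus_id)
    return matrix.subset(loci=kept), removed


def replicate_discordance(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    locus_subset: list[str] | None = None,
) -> tuple[float | None, pd.DataFrame]:
    """Genotype-calling error rate from replicate control samples.

    Pools discordant / shared non-missing calls over all replicate pairs
    (call-weighted, not per-pair averaged). Returns (rate, per-pair detail);
    rate is None when no pair shares a typed locus.
    """
    groups: dict[str, list[str]] = {}
    for rec in samples:
        if rec.replicate_group and rec.sample_id in matrix._sample_idx:
            groups.setdefault(rec.replicate_group, []).append(rec.sample_id)
    groups = {g: m for g, m in groups.items() if len(m) >= 2}
    if not groups:
        raise ValueError("no replicate group with >= 2 genotyped members")

    cols = (list(range(matrix.n_loci)) if locus_subset is None
            else [matrix.locus_index(l) for l in locus_subset])
    pairs_arr = matrix.pairs[:, cols, :]
    detail = []
    shared_total = discord_total = 0
    for group, members in sorted(groups.items()):
        for s1, s2 in combinations(sorted(members), 2):
            g1 = pairs_arr[matrix.sample_index(s1)]
            g2 = pairs_arr[matrix.sample_index(s2)]
            both = (g1[:, 0] >= 0) & (g2[:, 0] >= 0)
            shared = int(both.sum())
            discordant = int((both & ((g1[:, 0] != g2[:, 0]) | (g1[:, 1] != g2[:, 1]))).sum())
            detail.append({
                "replicate_group": group, "sample_1": s1, "sample_2": s2,
                "shared_calls": shared, "discordant_calls": discordant,
                "rate": discordant / shared if shared else np.nan,
            })
            shared_total += shared
            discord_total += discordant
    if shared_total == 0:
        warnings.warn("replicate pairs share no typed loci; error rate undefined")
        return None, pd.DataFrame(detail)
    return discord_total / shared_total, pd.DataFrame(detail)


def flag_duplication_suspects(
    matrix: GenotypeMatrix,
    panel: AmpliconPanel | None = None,
    hobs_threshold: float = 0.6,
    excess_threshold: float = 0.2,
    maf_threshold: float = 0.03,
) -> list[LocusQCFlags]:
    """Annotate loci whose heterozygosity excess suggests a collapsed duplication.

    A segmental duplication collapsed onto one locus makes nearly every sample
    look heterozygous; loci with H_obs > ``hobs_threshold`` and
    H_obs - H_exp > ``excess_threshold`` are flagged. Flags annotate, they
    never remove data.
    """
    from .diversity import observed_expected_het

    flags = []
    call_rates = matrix.call_rate_per_locus()
    for j, locus in enumerate(matrix.loci):
        h_obs, h_exp, n_typed = observed_expected_het(matrix, locus.locus_id)
        maf = compute_maf(matrix, locus.locus_id)
        suspect = (
            n_typed > 0
            and h_obs > hobs_threshold
            and (h_obs - h_exp) > excess_threshold
        )
        notes = []
        if suspect:
            notes.append(
                f"H_obs={h_obs:.3f} exceeds H_exp={h_exp:.3f} beyond excess threshold"
            )
        flags.append(LocusQCFlags(
            locus_id=locus.locus_id,
            maf_fail=(maf is None or maf < maf_threshold),
            duplication_suspect=bool(suspect),
            call_rate=float(call_rates[j]),
            notes="; ".join(notes),
        ))
    return flags


def amplicon_qc(
    matrix: GenotypeMatrix,
    panel: AmpliconPanel,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Per-amplicon call rate, informative SNP count and QC flags.

    Flags ``dropout_suspect`` when the amplicon's call rate falls below
    1 - max_missing (ascertainment/amplification failure) and
    ``low_information`` when <= 2 of its loci survive in the matrix.
    Sorted by amplicon_id.
    """
    present = set(matrix.locus_ids)
    rows = []
    for amp in panel.amplicons:
        ids = [l.locus_id for l in amp.loci if l.locus_id in present]
        n_retained = len(ids)
        if ids:
            cols = [matrix.locus_index(l) for l in ids]
            call_rate = float(1.0 - matrix.is_missing()[:, cols].mean())
        else:
            call_rate = 0.0
        flags = []
        if call_rate < 1.0 - max_missing:
            flags.append("dropout_suspect")
        if n_retained <= 2:
            flags.append("low_information")
        rows.append({
            "amplicon_id": amp.amplicon_id,
            "target_class": amp.target_class,
            "call_rate": call_rate,
            "informative_snp_count": n_retained,
            "qc_flags": ";".join(flags),
        })
    return (pd.DataFrame(rows)
            .sort_values("amplicon_id")
            .reset_index(drop=True))
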