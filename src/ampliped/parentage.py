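"""Likelihood-based parentage assignment with simulation-calibrated confidence.

For each locus the LOD score compares the likelihood that a candidate is a
parent of the offspring against the likelihood that the candidate is an
unrelated member of the population, integrating a genotyping-error model over
the unobserved true genotypes:

    P(g_obs | g_true) = (1 - eps) * 1[g_obs = g_true] + eps * P_HW(g_obs)

i.e. with probability eps a call is replaced by a random Hardy-Weinberg
genotype. Single-parent LODs integrate the unknown second parent over the
population allele frequencies; trio LODs condition on a known parent.

Delta — the gap between the two highest positive LODs — is graded against a
critical value estimated by Monte-Carlo simulation of the candidate pool at
the facility's allele frequencies (observed missingness and error applied),
following the standard likelihood parentage methodology of Marshall and
colleagues. Loci are treated as independent in the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleRecord, genotype_pair_list
from .panel import AmpliconPanel
from .pedigree import PedigreeRegistry


@dataclass
class ParentageConfig:
    error_rate: float = 0.01
    min_shared_loci: int = 20
    confidence_levels: dict = field(
        default_factory=lambda: {"strict": 0.95, "relaxed": 0.80}
    )
    sim_cycles: int = 10000
    prop_loci_typed: float | None = None  # None: estimated from the data
    prop_candidates_sampled: float = 1.0
    min_facility_n: int = 10  # fewer genotyped animals -> global allele frequencies
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for name, level in self.confidence_levels.items():
            if not 0.5 < level < 1:
                raise ValueError(f"confidence level {name}={level} must be in (0.5, 1)")
        if self.sim_cycles < 1000:
            raise ValueError("sim_cycles must be >= 1000")


# ---------------------------------------------------------------------------
# single-locus building blocks
# ---------------------------------------------------------------------------

def _as_freq_vector(freqs) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.ndim == 0:  # scalar alt-allele frequency of a biallelic locus
        f = np.array([1.0 - float(f), float(f)])
    if f.min() < 0 or not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError(f"allele frequencies must be a simplex vector, got {f}")
    return f / f.sum()


def hw_genotype_probs(freqs) -> np.ndarray:
    """Hardy-Weinberg probabilities over canonical genotype codes."""
    f = _as_freq_vector(freqs)
    k = len(f)
    return np.array([
        f[i] * f[j] if i == j else 2.0 * f[i] * f[j]
        for (i, j) in genotype_pair_list(k)
    ])


def mendelian_trio_prob(g_off, g_dam, g_sire, n_alleles: int = 2) -> float:
    """P(offspring genotype | dam, sire) under Mendelian segregation.

    Genotypes are unordered allele-index pairs. Sums to 1 over all offspring
    genotypes for fixed parents.
    """
    for g in (g_off, g_dam, g_sire):
        a, b = g
        if not (0 <= a < n_alleles and 0 <= b < n_alleles):
            raise ValueError(f"genotype {g} uses an allele outside 0..{n_alleles - 1}")

    def trans(parent, allele):
        return 0.5 * ((parent[0] == allele) + (parent[1] == allele))

    x, y = min(g_off), max(g_off)
    if x == y:
        return trans(g_dam, x) * trans(g_sire, x)
    return trans(g_dam, x) * trans(g_sire, y) + trans(g_dam, y) * trans(g_sire, x)


def obs_given_true(g_obs_code: int, g_true_code: int, eps: float, freqs) -> float:
    """Replacement-error model P(observed | true genotype)."""
    hw = hw_genotype_probs(freqs)
    return (1.0 - eps) * (g_obs_code == g_true_code) + eps * hw[g_obs_code]


@dataclass
class _LocusTables:
    """Per-locus observed-genotype lookup tables for LOD terms."""

    hw: np.ndarray          # (G,) HW genotype probabilities
    lod1: np.ndarray        # (G, G) single-parent log-likelihood ratio [off_obs, cand_obs]
    excl1: np.ndarray       # (G, G) Mendelian impossibility at eps=0
    lod2: np.ndarray        # (G, G, G) trio log ratio [off_obs, known_obs, cand_obs]
    excl2: np.ndarray       # (G, G, G)
    n_alleles: int


def _build_locus_tables(freqs, eps: float) -> _LocusTables:
    f = _as_freq_vector(freqs)
    k = len(f)
    pairs = genotype_pair_list(k)
    G = len(pairs)
    hw = hw_genotype_probs(f)
    E = (1.0 - eps) * np.eye(G) + eps * np.tile(hw[:, None], (1, G))
    p_obs = E @ hw
    M = np.empty((G, G, G))
    for o, go in enumerate(pairs):
        for d, gd in enumerate(pairs):
            for s, gs in enumerate(pairs):
                M[o, d, s] = mendelian_trio_prob(go, gd, gs, n_alleles=k)
    T = M @ hw  # (o, p): offspring prob given one parent, mate from HW
    num1 = np.einsum("ao,bc,oc,c->ab", E, E, T, hw)
    den1 = np.outer(p_obs, p_obs)
    num2 = np.einsum("ao,bd,cs,ods,d,s->abc", E, E, E, M, hw, hw)
    den2 = np.einsum("ao,bd,od,d->ab", E, E, T, hw)[:, :, None] * p_obs[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lod1 = np.log(num1) - np.log(den1)
        lod2 = np.log(num2) - np.log(den2)
    # 0/0 arises at eps=0 when the offspring/known-parent pair is itself
    # Mendelian-impossible; such a locus says nothing about the candidate
    lod1 = np.where(np.isnan(lod1), 0.0, lod1)
    lod2 = np.where(np.isnan(lod2), 0.0, lod2)
    return _LocusTables(
        hw=hw, lod1=lod1, excl1=(T == 0), lod2=lod2, excl2=(M == 0), n_alleles=k
    )


class ParentageModel:
    """LOD evaluation over a locus set at fixed allele frequencies and error rate."""

    def __init__(self, freqs_per_locus, error_rate: float):
        self.error_rate = float(error_rate)
        self.freqs = [_as_freq_vector(f) for f in freqs_per_locus]
        self.tables = [_build_locus_tables(f, self.error_rate) for f in self.freqs]

    @property
    def n_loci(self) -> int:
        return len(self.tables)

    def lod_single(self, off: np.ndarray, cand: np.ndarray):
        lods, shared, excl = self.lod_single_many(off[None, :], cand[None, :])
        return float(lods[0]), int(shared[0]), int(excl[0])

    def lod_single_many(self, off: np.ndarray, cand: np.ndarray):
        """Batched single-parent LODs; genotype codes (N, L), -1 missing."""
        n = off.shape[0]
        lod = np.zeros(n)
        shared = np.zeros(n, dtype=int)
        excl = np.zeros(n, dtype=int)
        for l, t in enumerate(self.tables):
            m = (off[:, l] >= 0) & (cand[:, l] >= 0)
            if not m.any():
                continue
            o, c = off[m, l], cand[m, l]
            lod[m] += t.lod1[o, c]
            shared += m
            excl[m] += t.excl1[o, c]
        return lod, shared, excl

    def lod_trio(self, off: np.ndarray, known: np.ndarray, cand: np.ndarray):
        lods, shared, excl = self.lod_trio_many(off[None, :], known[None, :], cand[None, :])
        return float(lods[0]), int(shared[0]), int(excl[0])

    def lod_trio_many(self, off: np.ndarray, known: np.ndarray, cand: np.ndarray):
        """Batched trio LODs over loci typed in all three individuals."""
        n = off.shape[0]
        lod = np.zeros(n)
        shared = np.zeros(n, dtype=int)
        excl = np.zeros(n, dtype=int)
        for l, t in enumerate(self.tables):
            m = (off[:, l] >= 0) & (known[:, l] >= 0) & (cand[:, l] >= 0)
            if not m.any():
                continue
            o, d, c = off[m, l], known[m, l], cand[m, l]
            lod[m] += t.lod2[o, d, c]
            shared += m
            excl[m] += t.excl2[o, d, c]
        return lod, shared, excl


def lod_single_parent(off_codes, cand_codes, freqs_per_locus, error_rate: float):
    """(LOD, shared_loci, mendelian_exclusions) for one offspring-candidate pair.

    ``off_codes``/``cand_codes`` are canonical genotype codes per locus, -1 for
    missing. Exclusions count loci Mendelian-impossible at eps = 0; with
    eps = 0 those loci contribute -inf.
    """
    model = ParentageModel(freqs_per_locus, error_rate)
    off = np.asarray(off_codes)
    cand = np.asarray(cand_codes)
    lod, shared, excl = model.lod_single(off, cand)
    if shared == 0:
        return float("nan"), 0, 0
    return lod, shared, excl


def lod_trio(off_codes, known_codes, cand_codes, freqs_per_locus, error_rate: float):
    """(LOD, shared_loci, exclusions) conditioning on a known co-parent."""
    model = ParentageModel(freqs_per_locus, error_rate)
    lod, shared, excl = model.lod_trio(
        np.asarray(off_codes), np.asarray(known_codes), np.asarray(cand_codes)
    )
    if shared == 0:
        return float("nan"), 0, 0
    return lod, shared, excl


def delta_statistic(lods) -> float:
    """Gap between the two highest positive LODs.

    Only positive LODs enter: with >= 2 positive scores delta is top minus
    second, with exactly one it is that score, with none it is 0 (no
    assignment possible).
    """
    pos = sorted((x for x in lods if np.isfinite(x) and x > 0), reverse=True)
    if not pos:
        return 0.0
    if len(pos) == 1:
        return float(pos[0])
    return float(pos[0] - pos[1])


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of critical delta
# ---------------------------------------------------------------------------

@dataclass
class CriticalDelta:
    thresholds: dict[str, float]
    n_trials: int
    n_positive_delta: int
    assignment_rate: dict[str, float]
    deltas: np.ndarray = field(repr=False, default=None)
    correct: np.ndarray = field(repr=False, default=None)


def _draw_parent_genotypes(freqs, n, rng):
    """(alleles (n,2), codes (n,)) for unrelated HW individuals at one locus."""
    k = len(freqs)
    alleles = rng.choice(k, size=(n, 2), p=freqs)
    lo = np.minimum(alleles[:, 0], alleles[:, 1])
    hi = np.maximum(alleles[:, 0], alleles[:, 1])
    return alleles, hi * (hi + 1) // 2 + lo


def _observe(codes: np.ndarray, hw_list, typed_p: float, eps: float, rng) -> np.ndarray:
    """Apply the genotyping error and missingness model to true codes (N, L)."""
    obs = codes.copy()
    n, L = codes.shape
    for l in range(L):
        hw = hw_list[l]
        err = rng.random(n) < eps
        if err.any():
            obs[err, l] = rng.choice(len(hw), size=int(err.sum()), p=hw)
    miss = rng.random(codes.shape) > typed_p
    obs[miss] = -1
    return obs


def simulate_trials(
    model: ParentageModel,
    n_candidates: int,
    cycles: int,
    typed_p: float,
    prop_candidates_sampled: float,
    mode: str,
    rng: np.random.Generator,
    min_shared_loci: int = 20,
):
    """Simulate parentage trials; returns (delta, top_is_true_parent) arrays.

    Each trial draws a dam and sire from HW at the model's frequencies,
    creates the offspring by Mendelian transmission, builds
    ``n_candidates - 1`` unrelated candidates, applies the observation model
    to everyone, and evaluates candidate LODs in the requested mode
    (``"single"``: candidate alone; ``"trio"``: conditioned on the observed
    other parent). The true parent is in the pool with probability
    ``prop_candidates_sampled``.
    """
    if mode not in ("single", "trio"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    L = model.n_loci
    hw_list = [t.hw for t in model.tables]
    eps = model.error_rate

    dam_alleles = np.empty((cycles, L, 2), dtype=np.int16)
    sire_alleles = np.empty((cycles, L, 2), dtype=np.int16)
    dam_codes = np.empty((cycles, L), dtype=np.int16)
    sire_codes = np.empty((cycles, L), dtype=np.int16)
    off_codes = np.empty((cycles, L), dtype=np.int16)
    for l, f in enumerate(model.freqs):
        da, dc = _draw_parent_genotypes(f, cycles, rng)
        sa, sc = _draw_parent_genotypes(f, cycles, rng)
        dam_alleles[:, l], dam_codes[:, l] = da, dc
        sire_alleles[:, l], sire_codes[:, l] = sa, sc
        from_dam = da[np.arange(cycles), rng.integers(0, 2, cycles)]
        from_sire = sa[np.arange(cycles), rng.integers(0, 2, cycles)]
        lo = np.minimum(from_dam, from_sire)
        hi = np.maximum(from_dam, from_sire)
        off_codes[:, l] = hi * (hi + 1) // 2 + lo

    off_obs = _observe(off_codes, hw_list, typed_p, eps, rng)
    dam_obs = _observe(dam_codes, hw_list, typed_p, eps, rng)
    true_obs = _observe(sire_codes, hw_list, typed_p, eps, rng)
    true_present = rng.random(cycles) < prop_candidates_sampled

    def cand_lod(cand_obs):
        if mode == "single":
            lod, shared, _ = model.lod_single_many(off_obs, cand_obs)
        else:
            lod, shared, _ = model.lod_trio_many(off_obs, dam_obs, cand_obs)
        lod[shared < min_shared_loci] = np.nan
        return lod

    lods = [cand_lod(true_obs)]
    for _ in range(n_candidates - 1):
        unrel = np.empty((cycles, L), dtype=np.int16)
        for l, f in enumerate(model.freqs):
            _, unrel[:, l] = _draw_parent_genotypes(f, cycles, rng)
        lods.append(cand_lod(_observe(unrel, hw_list, typed_p, eps, rng)))
    lod_arr = np.column_stack(lods)  # (cycles, n_candidates); column 0 = true parent
    lod_arr[~true_present, 0] = np.nan

    deltas = np.empty(cycles)
    top_true = np.zeros(cycles, dtype=bool)
    for i in range(cycles):
        row = lod_arr[i]
        finite = np.isfinite(row) | np.isneginf(row)
        deltas[i] = delta_statistic(row[finite])
        if finite.any() and deltas[i] > 0:
            valid = np.where(finite)[0]
            top = valid[np.argmax(row[valid])]
            top_true[i] = (top == 0) and true_present[i]
    return deltas, top_true


def critical_from_trials(deltas, correct, levels: dict[str, float],
                         min_positive: int = 100) -> CriticalDelta:
    """Critical delta per confidence level from simulated trials.

    The threshold at level c is the smallest t on the achieved-delta grid such
    that among trials with delta > t the proportion with the true parent
    top-ranked is >= c; +inf when no threshold (or too few positive-delta
    trials) achieves it.
    """
    deltas = np.asarray(deltas, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    n = len(deltas)
    n_pos = int((deltas > 0).sum())
    thresholds: dict[str, float] = {}
    rates: dict[str, float] = {}
    if n_pos < min_positive:
        warnings.warn(
            f"only {n_pos} positive-delta trials (< {min_positive}); "
            "critical delta set to +inf"
        )
        for name in levels:
            thresholds[name] = float("inf")
            rates[name] = 0.0
        return CriticalDelta(thresholds, n, n_pos, rates, deltas, correct)

    order = np.argsort(deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order].astype(float)
    suffix_n = np.arange(n, 0, -1)
    suffix_correct = np.cumsum(c_sorted[::-1])[::-1]
    grid = np.concatenate([[0.0], np.unique(d_sorted)])
    for name, level in sorted(levels.items(), key=lambda kv: kv[1]):
        t_star = float("inf")
        for t in grid:
            start = np.searchsorted(d_sorted, t, side="right")
            if start >= n:
                break
            if suffix_correct[start] / suffix_n[start] >= level:
                t_star = float(t)
                break
        thresholds[name] = t_star
        rates[name] = float((deltas > t_star).mean()) if np.isfinite(t_star) else 0.0
    return CriticalDelta(thresholds, n, n_pos, rates, deltas, correct)


def simulate_critical_delta(
    cfg: ParentageConfig,
    freqs_per_locus,
    mode: str = "single",
    n_candidates: int = 5,
    rng: np.random.Generator | None = None,
) -> CriticalDelta:
    """Monte-Carlo critical delta for one facility / analysis mode."""
    rng = rng or np.random.default_rng(cfg.rng_seed)
    model = ParentageModel(freqs_per_locus, cfg.error_rate)
    typed_p = cfg.prop_loci_typed if cfg.prop_loci_typed is not None else 1.0
    deltas, correct = simulate_trials(
        model, n_candidates, cfg.sim_cycles, typed_p,
        cfg.prop_candidates_sampled, mode, rng,
        min_shared_loci=cfg.min_shared_loci,
    )
    return critical_from_trials(deltas, correct, cfg.confidence_levels)


# ---------------------------------------------------------------------------
# full assignment over a registry
# ---------------------------------------------------------------------------

@dataclass
class CandidateScore:
    candidate_id: str
    lod: float
    shared_loci: int
    exclusions: int
    eligible: bool = True


@dataclass
class ParentageResult:
    offspring_id: str
    mode: str  # single_parent_dam | single_parent_sire | parent_pair
    candidates: list[CandidateScore]
    delta: float
    critical_delta: dict[str, float]
    assignment: str | None
    confidence: str  # strict | relaxed | most_likely_only | excluded_only | insufficient_data
    notes: str = ""


def allele_frequencies(
    matrix: GenotypeMatrix, sample_ids=None, floor: float = 1e-4
) -> list[np.ndarray]:
    """Per-locus allele-frequency vectors, floored and renormalised so that a
    genotype never has exactly zero likelihood under the error model."""
    sub = matrix if sample_ids is None else matrix.subset(samples=list(sample_ids))
    freqs = []
    for locus in sub.loci:
        counts = sub.allele_counts(locus.locus_id).astype(float)
        if counts.sum() == 0:
            f = np.full(locus.n_alleles, 1.0 / locus.n_alleles)
        else:
            f = np.maximum(counts / counts.sum(), floor)
            f /= f.sum()
        freqs.append(f)
    return freqs


class _DeltaCache:
    def __init__(self):
        self._store: dict = {}

    def get(self, key, compute):
        if key not in self._store:
            self._store[key] = compute()
        return self._store[key]


def _grade(scores, crit: CriticalDelta, levels: dict[str, float]):
    """(delta, assignment, confidence, note) from ranked candidate scores."""
    eligible = [s for s in scores if s.eligible]
    if not eligible:
        return 0.0, None, "excluded_only", "no candidate shares enough typed loci"
    lods = [s.lod for s in eligible]
    delta = delta_statistic(lods)
    finite = sorted(
        (s for s in eligible if np.isfinite(s.lod) or np.isneginf(s.lod)),
        key=lambda s: -s.lod if np.isfinite(s.lod) else np.inf,
    )
    top = max(eligible, key=lambda s: s.lod if np.isfinite(s.lod) else -np.inf)
    ties = [s for s in eligible
            if s is not top and np.isfinite(s.lod) and abs(s.lod - top.lod) < 1e-9]
    if np.isfinite(top.lod) and top.lod > 0 and ties:
        ids = ", ".join([top.candidate_id] + [s.candidate_id for s in ties])
        return delta, None, "most_likely_only", f"tie in LOD between {ids}"
    if not np.isfinite(top.lod) or top.lod <= 0:
        return delta, None, "excluded_only", "no candidate with positive LOD"
    for name, _level in sorted(levels.items(), key=lambda kv: -kv[1]):
        t = crit.thresholds.get(name, float("inf"))
        if np.isfinite(t) and delta >= t and delta > 0:
            return delta, top.candidate_id, name, ""
    return delta, top.candidate_id, "most_likely_only", "delta below critical value"


def assign_parentage(
    registry: PedigreeRegistry,
    matrix: GenotypeMatrix,
    panel: AmpliconPanel | None = None,
    cfg: ParentageConfig | None = None,
    samples: list[SampleRecord] | None = None,
) -> list[ParentageResult]:
    """Run the full per-offspring parentage analysis over a registry.

    Allele frequencies are computed per breeding facility (falling back to the
    whole matrix when a facility has fewer than ``min_facility_n`` genotyped
    animals). With one parent known the other is sought by trio LOD;
    with both unknown a single-parent dam analysis runs first, and if a dam is
    confidently assigned the sire analysis conditions on her (sequential
    pair scheme). Ungenotyped candidates lower the simulated probability that
    the true parent is in the sampled pool.
    """
    cfg = cfg or ParentageConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    cache = _DeltaCache()
    codes = matrix.genotype_codes()
    global_freqs = allele_frequencies(matrix)

    facility_members: dict[str, set[str]] = {}
    if samples is not None:
        for rec in samples:
            facility_members.setdefault(rec.facility_id, set()).add(rec.sample_id)
    else:
        for e in registry:
            ids = {e.offspring_id} | e.candidate_dams | e.candidate_sires
            ids |= {p for p in (e.known_dam, e.known_sire) if p}
            facility_members.setdefault(e.facility_id, set()).update(ids)

    def facility_freqs(facility_id: str):
        """(freqs, label) — label keys the critical-delta cache."""
        members = [s for s in facility_members.get(facility_id, set())
                   if s in matrix._sample_idx]
        typed = [s for s in members
                 if not matrix.is_missing()[matrix.sample_index(s)].all()]
        if len(typed) < cfg.min_facility_n:
            return global_freqs, "__global__"
        return allele_frequencies(matrix, typed), facility_id

    results: list[ParentageResult] = []
    for entry in registry:
        if entry.offspring_id not in matrix._sample_idx:
            results.append(ParentageResult(
                entry.offspring_id, "single_parent_dam", [], 0.0, {}, None,
                "insufficient_data", "offspring not genotyped"))
            continue
        off = codes[matrix.sample_index(entry.offspring_id)]
        if (off < 0).all():
            results.append(ParentageResult(
                entry.offspring_id, "single_parent_dam", [], 0.0, {}, None,
                "insufficient_data", "offspring genotype entirely missing"))
            continue
        freqs, freq_label = facility_freqs(entry.facility_id)
        model = ParentageModel(freqs, cfg.error_rate)

        def analyse(cand_ids, mode, known_id=None):
            genotyped = sorted(c for c in cand_ids if c in matrix._sample_idx)
            skipped = sorted(set(cand_ids) - set(genotyped))
            if skipped:
                warnings.warn(
                    f"{entry.offspring_id}: candidates not genotyped, treated as "
                    f"unsampled: {skipped}"
                )
            scores = []
            involved = [matrix.sample_index(entry.offspring_id)]
            known = None
            if known_id is not None and known_id in matrix._sample_idx:
                known = codes[matrix.sample_index(known_id)]
                involved.append(matrix.sample_index(known_id))
            for c in genotyped:
                cand = codes[matrix.sample_index(c)]
                involved.append(matrix.sample_index(c))
                if known is not None:
                    lod, shared, excl = model.lod_trio(off, known, cand)
                else:
                    lod, shared, excl = model.lod_single(off, cand)
                scores.append(CandidateScore(
                    c, lod, shared, excl, eligible=(shared >= cfg.min_shared_loci)
                ))
            scores.sort(key=lambda s: (s.lod if np.isfinite(s.lod) else -np.inf),
                        reverse=True)
            if not scores:
                return ParentageResult(
                    entry.offspring_id, mode, [], 0.0, {}, None,
                    "insufficient_data", "no genotyped candidates")
            typed_p = cfg.prop_loci_typed
            if typed_p is None:
                typed_p = float(1.0 - matrix.is_missing()[involved].mean())
            prop_sampled = cfg.prop_candidates_sampled * (
                len(genotyped) / max(len(cand_ids), 1)
            )
            sim_mode = "trio" if known is not None else "single"
            key = (freq_label, sim_mode, len(genotyped),
                   round(typed_p, 2), round(prop_sampled, 2))
            crit = cache.get(key, lambda: critical_from_trials(
                *simulate_trials(model, max(len(genotyped), 2), cfg.sim_cycles,
                                 typed_p, prop_sampled, sim_mode,
                                 np.random.default_rng(rng.integers(2**31)),
                                 min_shared_loci=cfg.min_shared_loci),
                cfg.confidence_levels,
            ))
            delta, assignment, confidence, note = _grade(
                scores, crit, cfg.confidence_levels)
            return ParentageResult(
                entry.offspring_id, mode, scores, delta, dict(crit.thresholds),
                assignment, confidence, note)

        if entry.known_dam and entry.known_sire:
            continue  # both parents already known; nothing to assign
        if entry.known_dam or entry.known_sire:
            known = entry.known_dam or entry.known_sire
            cands = entry.candidate_sires if entry.known_dam else entry.candidate_dams
            res = analyse(cands, "parent_pair", known_id=known)
            res.notes = (res.notes + "; " if res.notes else "") + \
                f"conditioned on known parent {known}"
            results.append(res)
        else:
            dam_res = analyse(entry.candidate_dams, "single_parent_dam")
            results.append(dam_res)
            if dam_res.assignment and dam_res.confidence in cfg.confidence_levels:
                sire_res = analyse(entry.candidate_sires, "parent_pair",
                                   known_id=dam_res.assignment)
                sire_res.notes = (sire_res.notes + "; " if sire_res.notes else "") + \
                    f"conditioned on assigned dam {dam_res.assignment}"
            else:
                sire_res = analyse(entry.candidate_sires, "single_parent_sire")
            results.append(sire_res)
    return results


def compare_marker_sets(
    results_a: list[ParentageResult], results_b: list[ParentageResult]
) -> pd.DataFrame:
    """Offspring-by-offspring comparison of two marker sets' assignments."""

    def index(results):
        out: dict[str, ParentageResult] = {}
        for r in results:
            out[r.offspring_id] = r  # last (final) analysis per offspring wins
        return out

    a, b = index(results_a), index(results_b)
    if set(a) != set(b):
        raise ValueError(
            f"offspring sets differ: only in a {sorted(set(a) - set(b))}, "
            f"only in b {sorted(set(b) - set(a))}"
        )
    rows = []
    for oid in sorted(a):
        ra, rb = a[oid], b[oid]

        def top_lod(r):
            el = [s.lod for s in r.candidates if s.eligible and np.isfinite(s.lod)]
            return max(el) if el else float("nan")

        rows.append({
            "offspring_id": oid,
            "assigned_a": ra.assignment or "",
            "assigned_b": rb.assignment or "",
            "confidence_a": ra.confidence,
            "confidence_b": rb.confidence,
            "lod_a": top_lod(ra),
            "lod_b": top_lod(rb),
            "delta_a": ra.delta,
            "delta_b": rb.delta,
            "agree": bool(ra.assignment == rb.assignment and ra.assignment),
        })
    return pd.DataFrame(rows)
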