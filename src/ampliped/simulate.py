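"""Ground-truthed synthetic datasets emulating a low-diversity captive
population genotyped on a long-amplicon SNP panel.

The generator produces (i) a panel of amplicons, each carrying a small pool
of founder haplotypes with Dirichlet-drawn frequencies and a skewed low-MAF
per-SNP spectrum; (ii) a two-generation population organised into breeding
facilities with known/candidate parents (optionally full- or half-sib
candidates); and (iii) an observation layer that injects missingness
(marker-level failure shared across individuals, whole-amplicon dropout for
long-amplicon PCR failure on degraded DNA, and a per-sample per-call
component) plus genotype-replacement error.

Within an amplicon there is no recombination — each offspring haplotype is
one parental haplotype verbatim — while amplicons segregate independently.
All randomness flows from explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, SampleRecord
from .panel import Amplicon, AmpliconPanel, Locus
from .pedigree import PedigreeEntry, PedigreeRegistry

_BASES = ("A", "C", "G", "T")


class SpecError(ValueError):
    pass


@dataclass
class SimPanelSpec:
    n_amplicons: int = 14
    snps_per_amplicon: tuple[int, int] = (1, 41)
    haplotypes_per_amplicon: tuple[int, int] = (2, 8)
    maf_beta: tuple[float, float] = (0.7, 2.8)  # Beta shape, scaled to (0, 0.5]
    amplicon_length_bp: tuple[int, int] = (7800, 10100)

    def __post_init__(self) -> None:
        for name in ("snps_per_amplicon", "haplotypes_per_amplicon", "amplicon_length_bp"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise SpecError(f"{name}: invalid range ({lo}, {hi})")
        if self.haplotypes_per_amplicon[0] < 2:
            raise SpecError("polymorphic amplicons need >= 2 haplotypes")


@dataclass
class FacilitySpec:
    facility_id: str
    n_offspring: int
    known_dam: bool
    n_candidate_dams: int
    n_candidate_sires: int
    sib_structure: str = "unrelated"  # unrelated | half_sibs | full_sibs

    def __post_init__(self) -> None:
        if self.sib_structure not in ("unrelated", "half_sibs", "full_sibs"):
            raise SpecError(f"unknown sib_structure {self.sib_structure!r}")


def insurance_breeding_groups() -> list[FacilitySpec]:
    """The eleven breeding-group structures of the genotyped insurance
    population: per group the offspring count, whether the dam was known from
    the studbook, candidate pool sizes, and whether candidates included sibs."""
    return [
        FacilitySpec("1/1", 2, True, 0, 2),
        FacilitySpec("1/2", 2, True, 0, 2),
        FacilitySpec("1/3", 4, True, 0, 4),
        FacilitySpec("1/4", 4, True, 0, 5),
        FacilitySpec("1/5", 7, False, 4, 4),
        FacilitySpec("1/6", 4, True, 0, 4),
        FacilitySpec("2/1", 8, False, 5, 8, "full_sibs"),
        FacilitySpec("2/2", 13, True, 0, 8, "half_sibs"),
        FacilitySpec("3/1", 5, False, 3, 5, "full_sibs"),
        FacilitySpec("4/1", 6, False, 3, 12, "half_sibs"),
        FacilitySpec("5/1", 11, False, 8, 6, "half_sibs"),
    ]


@dataclass
class SimPopSpec:
    """Population and observation-model parameters.

    Missingness has three components, consumed in order against the overall
    ``missing_rate`` budget: marker-level failure (a fixed fraction of loci
    amplify poorly in nearly all samples — ascertainment bias and primer
    failure make missingness strongly correlated between individuals, which
    is what keeps the shared-locus count of an offspring/dam/sire trio far
    above the independent-missingness expectation), whole-amplicon dropout
    per sample (long-amplicon PCR failure on degraded DNA), and a per-call
    component elevated for a low-quality subset of samples.
    """

    n_founders: int = 30
    facilities: list[FacilitySpec] = field(default_factory=insurance_breeding_groups)
    missing_rate: float = 0.44
    error_rate: float = 0.01
    low_quality_sample_fraction: float = 0.1
    locus_failure_rate: float = 0.40
    locus_failure_missing: float = 0.9
    amplicon_dropout_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "error_rate", "low_quality_sample_fraction",
                     "locus_failure_rate", "locus_failure_missing",
                     "amplicon_dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SpecError(f"{name} must be in [0, 1], got {v}")
        if not self.facilities:
            raise SpecError("at least one facility required")


@dataclass
class HaplotypePool:
    """Founder haplotypes of one amplicon: (H, S) allele-index matrix + frequencies."""
    amplicon_id: str
    haplotypes: np.ndarray
    frequencies: np.ndarray


@dataclass
class SimTruth:
    pedigree: dict[str, tuple[str, str]]            # offspring -> (dam, sire)
    phased_haplotypes: dict[str, dict[str, tuple[int, int]]]  # sample -> amp -> pool idx pair
    true_genotypes: GenotypeMatrix
    pools: dict[str, HaplotypePool]


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _assign_alleles(H, S, freqs, mafs, rng, tries: int = 100) -> np.ndarray:
    """(H, S) 0/1 matrix: which haplotypes carry the alternate base, aiming the
    pool-induced per-SNP alt frequency at the drawn MAF targets."""
    for _ in range(tries):
        mat = np.zeros((H, S), dtype=np.int8)
        for s in range(S):
            order = rng.permutation(H)
            cum = np.cumsum(freqs[order])
            # subset of haplotypes whose total frequency is closest to the target,
            # never empty and never all of them
            size = int(np.clip(np.argmin(np.abs(cum - mafs[s])) + 1, 1, H - 1))
            mat[order[:size], s] = 1
        if len({tuple(row) for row in mat}) == H:
            return mat
    # fall back to distinct random bit patterns (spectrum no longer targeted)
    patterns = rng.choice(2 ** S, size=H, replace=False)
    return np.array(
        [[(p >> s) & 1 for s in range(S)] for p in patterns], dtype=np.int8
    )


def generate_panel(
    spec: SimPanelSpec, seed: int
) -> tuple[AmpliconPanel, dict[str, HaplotypePool]]:
    """Draw a panel and its founder haplotype pools; deterministic given seed."""
    rng = np.random.default_rng(seed)
    amps, pools = [], {}
    for a in range(spec.n_amplicons):
        amp_id = f"AMP{a + 1:02d}"
        chrom = f"chr{a % 6 + 1}"
        start = 1 + a * 1_000_000
        length = int(rng.integers(spec.amplicon_length_bp[0],
                                  spec.amplicon_length_bp[1] + 1))
        S = int(rng.integers(spec.snps_per_amplicon[0], spec.snps_per_amplicon[1] + 1))
        feasible = 2 ** S if S < 32 else 2 ** 31
        if spec.haplotypes_per_amplicon[0] > feasible:
            raise SpecError(
                f"{amp_id}: {spec.haplotypes_per_amplicon[0]} haplotypes requested "
                f"but only {feasible} are possible with {S} SNPs"
            )
        H = int(rng.integers(spec.haplotypes_per_amplicon[0],
                             spec.haplotypes_per_amplicon[1] + 1))
        H = min(H, feasible)
        freqs = rng.dirichlet(np.full(H, 0.8))
        freqs = np.maximum(freqs, 1e-3)
        freqs /= freqs.sum()
        a_beta, b_beta = spec.maf_beta
        mafs = 0.5 * rng.beta(a_beta, b_beta, size=S)
        hap_mat = _assign_alleles(H, S, freqs, mafs, rng)
        offsets = np.sort(rng.choice(length, size=S, replace=False))
        loci = []
        for s in range(S):
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            loci.append(Locus(
                locus_id=f"{amp_id}_S{s + 1:02d}",
                amplicon_id=amp_id,
                chromosome=chrom,
                position=int(start + offsets[s]),
                ref_allele=_BASES[ref],
                alt_alleles=(_BASES[alt],),
            ))
        if a == 2:
            target = "behavioural"  # one behaviour-linked amplicon, like a dopamine receptor
        else:
            target = "neutral" if a % 2 == 0 else "immune"
        amps.append(Amplicon(amp_id, target, loci))
        pools[amp_id] = HaplotypePool(amp_id, hap_mat, freqs)
    return AmpliconPanel(amps), pools


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

class _Genomes:
    """Tracks each sample's haplotype-pool indices per amplicon."""

    def __init__(self, panel: AmpliconPanel, pools: dict[str, HaplotypePool],
                 rng: np.random.Generator):
        self.panel = panel
        self.pools = pools
        self.rng = rng
        self.haps: dict[str, dict[str, tuple[int, int]]] = {}

    def new_founder(self, sample_id: str) -> None:
        self.haps[sample_id] = {
            amp_id: tuple(self.rng.choice(len(pool.frequencies), size=2,
                                          p=pool.frequencies))
            for amp_id, pool in self.pools.items()
        }

    def new_offspring(self, sample_id: str, dam_id: str, sire_id: str) -> None:
        self.haps[sample_id] = {
            amp_id: (
                self.haps[dam_id][amp_id][self.rng.integers(2)],
                self.haps[sire_id][amp_id][self.rng.integers(2)],
            )
            for amp_id in self.pools
        }

    def genotype_matrix(self) -> GenotypeMatrix:
        samples = list(self.haps)
        loci = self.panel.loci
        pairs = np.empty((len(samples), len(loci), 2), dtype=np.int16)
        col = 0
        for amp in self.panel.amplicons:
            pool = self.pools[amp.amplicon_id]
            S = pool.haplotypes.shape[1]
            idx = np.array([self.haps[s][amp.amplicon_id] for s in samples])
            a = pool.haplotypes[idx[:, 0], :]  # (n, S) allele indices
            b = pool.haplotypes[idx[:, 1], :]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            pairs[:, col:col + S, 0] = lo
            pairs[:, col:col + S, 1] = hi
            col += S
        return GenotypeMatrix(samples, loci, pairs)


def simulate_population(
    panel: AmpliconPanel,
    pools: dict[str, HaplotypePool],
    pop: SimPopSpec,
) -> tuple[SimTruth, list[SampleRecord], PedigreeRegistry]:
    """Build founders, facility candidate pools (with sib structure), offspring
    and the pedigree registry; ground truth recorded."""
    rng = np.random.default_rng(pop.rng_seed)
    genomes = _Genomes(panel, pools, rng)
    records: list[SampleRecord] = []
    entries: list[PedigreeEntry] = []
    pedigree: dict[str, tuple[str, str]] = {}

    facility_ids = [f.facility_id for f in pop.facilities]
    for i in range(pop.n_founders):
        sid = f"F{i + 1:03d}"
        genomes.new_founder(sid)
        records.append(SampleRecord(
            sid, sex=("F" if i % 2 == 0 else "M"),
            facility_id=facility_ids[i % len(facility_ids)],
            role={"founder"},
        ))

    hidden = 0

    def _hidden_founder() -> str:
        nonlocal hidden
        hidden += 1
        sid = f"H{hidden:03d}"
        genomes.new_founder(sid)
        return sid

    def _make_candidates(prefix, n, sex, facility, sib_structure):
        ids = []
        if sib_structure == "unrelated" or n == 1:
            for i in range(n):
                sid = f"{prefix}{i + 1}"
                genomes.new_founder(sid)
                ids.append(sid)
        else:
            shared_dam = _hidden_founder()
            shared_sire = _hidden_founder()
            for i in range(n):
                sid = f"{prefix}{i + 1}"
                if sib_structure == "full_sibs":
                    genomes.new_offspring(sid, shared_dam, shared_sire)
                else:  # half_sibs: common sire, distinct dams
                    genomes.new_offspring(sid, _hidden_founder(), shared_sire)
                ids.append(sid)
        role = {"candidate_dam"} if sex == "F" else {"candidate_sire"}
        for sid in ids:
            records.append(SampleRecord(sid, sex=sex, facility_id=facility, role=role))
        return ids

    for fac in pop.facilities:
        tag = fac.facility_id.replace("/", "_")
        sires = _make_candidates(f"SIRE_{tag}_", fac.n_candidate_sires, "M",
                                 fac.facility_id, fac.sib_structure)
        if fac.known_dam:
            dam_id = f"DAM_{tag}_known"
            genomes.new_founder(dam_id)
            records.append(SampleRecord(dam_id, sex="F", facility_id=fac.facility_id,
                                        role={"candidate_dam"}))
            dams = [dam_id]
        else:
            dams = _make_candidates(f"DAM_{tag}_", fac.n_candidate_dams, "F",
                                    fac.facility_id, fac.sib_structure)
        for k in range(fac.n_offspring):
            oid = f"OFF_{tag}_{k + 1}"
            true_dam = dams[0] if fac.known_dam else dams[rng.integers(len(dams))]
            true_sire = sires[rng.integers(len(sires))]
            genomes.new_offspring(oid, true_dam, true_sire)
            pedigree[oid] = (true_dam, true_sire)
            records.append(SampleRecord(oid, sex=("F" if rng.integers(2) else "M"),
                                        facility_id=fac.facility_id,
                                        role={"offspring"}))
            entries.append(PedigreeEntry(
                offspring_id=oid,
                facility_id=fac.facility_id,
                known_dam=true_dam if fac.known_dam else None,
                candidate_dams=set() if fac.known_dam else set(dams),
                candidate_sires=set(sires),
            ))

    visible = {r.sample_id for r in records}
    matrix = genomes.genotype_matrix().subset(
        samples=[s for s in genomes.haps if s in visible])
    truth = SimTruth(
        pedigree=pedigree,
        phased_haplotypes={s: genomes.haps[s] for s in matrix.samples},
        true_genotypes=matrix,
        pools=pools,
    )
    return truth, records, PedigreeRegistry(entries)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def pool_allele_frequencies(panel: AmpliconPanel,
                            pools: dict[str, HaplotypePool]) -> list[np.ndarray]:
    """Per-locus allele frequencies induced by the founder haplotype pools."""
    freqs = []
    for amp in panel.amplicons:
        pool = pools[amp.amplicon_id]
        for s in range(pool.haplotypes.shape[1]):
            p_alt = float(pool.frequencies @ (pool.haplotypes[:, s] == 1))
            freqs.append(np.array([1.0 - p_alt, p_alt]))
    return freqs


def apply_observation_model(
    truth: SimTruth, pop: SimPopSpec, seed: int,
    records: list[SampleRecord] | None = None,
) -> GenotypeMatrix:
    """Overlay missingness and genotyping error on the true genotypes.

    Missingness is composed of a marker-level failure component (a quota of
    poorly-amplifying loci missing in nearly every sample, which makes
    missingness strongly correlated between individuals and keeps trio
    shared-locus counts high), a whole-amplicon dropout component
    (long-amplicon PCR failure per sample) and a per-call component elevated
    for a low-quality subset of samples. Component rates are solved so the
    expected overall missing fraction equals ``pop.missing_rate``; components
    beyond the budget are scaled down in that order. Surviving calls are
    replaced by a random Hardy-Weinberg genotype with probability
    ``pop.error_rate``.
    """
    rng = np.random.default_rng(seed)
    matrix = truth.true_genotypes
    n, L = matrix.n_samples, matrix.n_loci
    pairs = matrix.pairs.copy()

    # consume the overall missingness budget component by component:
    # marker-level failure first, then sample x amplicon dropout, then per-call
    target = pop.missing_rate
    q_loc = min(pop.locus_failure_rate,
                target / pop.locus_failure_missing
                if pop.locus_failure_missing > 0 else 0.0)
    c_loc = q_loc * pop.locus_failure_missing
    d = min(pop.amplicon_dropout_rate,
            (target - c_loc) / (1.0 - c_loc) if c_loc < 1 else 0.0)
    rest = target - c_loc - (1.0 - c_loc) * d
    per_call_mean = rest / ((1.0 - c_loc) * (1.0 - d)) if rest > 0 else 0.0
    q = pop.low_quality_sample_fraction
    base = per_call_mean / (1.0 + q)  # low-quality samples run at twice the base rate
    lowq = rng.random(n) < q
    rate = np.clip(np.where(lowq, 2.0 * base, base), 0.0, 0.95)

    # poorly-amplifying markers: a fixed quota of loci missing in nearly all
    # samples, so missingness is shared between individuals
    n_bad = int(round(q_loc * L))
    bad_loci = rng.choice(L, size=n_bad, replace=False) if n_bad else np.array([], int)

    # genotyping error: replace a call with a random HW genotype at the
    # pool-induced allele frequency (applied before missingness)
    amp_counter: dict[str, int] = {}
    for j, locus in enumerate(matrix.loci):
        pool = truth.pools[locus.amplicon_id]
        s = amp_counter.get(locus.amplicon_id, 0)
        amp_counter[locus.amplicon_id] = s + 1
        p_alt = float(pool.frequencies @ (pool.haplotypes[:, s] == 1))
        hw = np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt ** 2])
        err = rng.random(n) < pop.error_rate
        if err.any():
            g = rng.choice(3, size=int(err.sum()), p=hw / hw.sum())
            pairs[err, j, 0] = np.where(g == 2, 1, 0)
            pairs[err, j, 1] = np.where(g == 0, 0, 1)

    # marker-level failure, whole-amplicon dropout, then per-call missingness
    for j in bad_loci:
        fail = rng.random(n) < pop.locus_failure_missing
        pairs[fail, j, :] = -1
    for amp_id in dict.fromkeys(l.amplicon_id for l in matrix.loci):
        cols = [j for j, l in enumerate(matrix.loci) if l.amplicon_id == amp_id]
        drop = rng.random(n) < d
        pairs[np.ix_(drop, cols)] = -1
    miss = rng.random((n, L)) < rate[:, None]
    pairs[miss] = -1
    return GenotypeMatrix(matrix.samples, matrix.loci, pairs)


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def _spec_hash(spec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def generate_dataset(
    panel_spec: SimPanelSpec,
    pop_spec: SimPopSpec,
    out_dir,
    seed: int,
) -> dict:
    """Write a complete ground-truthed input bundle for the pipeline.

    Produces panel.csv, genotypes.csv (wide dialect), registry.csv,
    samples.csv, truth.json and manifest.json under ``out_dir``; returns the
    manifest. The truth JSON records the pedigree, the per-amplicon haplotype
    pools and every sample's phased pool indices.
    """
    from .io import (write_genotypes, write_panel_csv, write_registry_csv,
                     write_samples_csv)

    os.makedirs(out_dir, exist_ok=True)
    panel, pools = generate_panel(panel_spec, seed)
    truth, records, registry = simulate_population(panel, pools, pop_spec)
    observed = apply_observation_model(truth, pop_spec, seed + 1)

    paths = {
        "panel": os.path.join(out_dir, "panel.csv"),
        "genotypes": os.path.join(out_dir, "genotypes.csv"),
        "registry": os.path.join(out_dir, "registry.csv"),
        "samples": os.path.join(out_dir, "samples.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_panel_csv(panel, paths["panel"])
    write_genotypes(observed, paths["genotypes"], "wide_csv")
    write_registry_csv(registry, paths["registry"])
    write_samples_csv(records, paths["samples"])

    truth_doc = {
        "pedigree": {o: list(ps) for o, ps in truth.pedigree.items()},
        "phased_haplotypes": {
            s: {a: [int(x) for x in pair] for a, pair in amps.items()}
            for s, amps in truth.phased_haplotypes.items()
        },
        "pools": {
            a: {"haplotypes": p.haplotypes.tolist(),
                "frequencies": p.frequencies.tolist()}
            for a, p in truth.pools.items()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": seed,
        "pop_rng_seed": pop_spec.rng_seed,
        "panel_spec_hash": _spec_hash(panel_spec),
        "pop_spec_hash": _spec_hash(pop_spec),
        "files": {name: _file_hash(p) for name, p in paths.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
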