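"""Genotype containers: codominant calls for samples x loci, plus run merging.

Genotypes are unordered allele pairs (no phase). Internally each call is a
sorted pair of allele indices into the locus' declared allele list, with
(-1, -1) as the single MISSING sentinel; half-calls are coerced to MISSING.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import Locus

log = logging.getLogger(__name__)


class _Missing:
    """Singleton sentinel for a missing genotype call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

SEXES = ("F", "M", "unknown")
ROLES = ("founder", "offspring", "candidate_dam", "candidate_sire", "control_replicate")


@dataclass
class SampleRecord:
    sample_id: str
    sex: str = "unknown"
    facility_id: str = ""
    role: set[str] = field(default_factory=set)
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"{self.sample_id}: sex must be one of {SEXES}")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise ValueError(f"{self.sample_id}: unknown roles {sorted(bad)}")
        if "candidate_dam" in self.role and self.sex == "M":
            raise ValueError(f"{self.sample_id}: candidate_dam cannot be male")
        if "candidate_sire" in self.role and self.sex == "F":
            raise ValueError(f"{self.sample_id}: candidate_sire cannot be female")


def genotype_pair_list(n_alleles: int) -> list[tuple[int, int]]:
    """Unordered genotype pairs (i, j), i <= j, in canonical code order."""
    return [(i, j) for j in range(n_alleles) for i in range(j + 1)]


def pair_to_code(i: int, j: int) -> int:
    """Canonical genotype code for the unordered pair (i, j), i <= j."""
    if i > j:
        i, j = j, i
    return j * (j + 1) // 2 + i


class GenotypeMatrix:
    """Samples x loci matrix of unordered allele-pair calls."""

    def __init__(self, samples: list[str], loci: list[Locus], pairs: np.ndarray):
        samples = list(samples)
        loci = list(loci)
        pairs = np.asarray(pairs, dtype=np.int16)
        if pairs.shape != (len(samples), len(loci), 2):
            raise ValueError(
                f"pairs shape {pairs.shape} inconsistent with "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        # normalise: sort each pair, force any half-call to full MISSING
        pairs = np.sort(pairs, axis=2)
        half = (pairs[:, :, 0] < 0) ^ (pairs[:, :, 1] < 0)
        if half.any():
            warnings.warn(f"{int(half.sum())} half-typed calls coerced to MISSING")
        miss = (pairs[:, :, 0] < 0) | (pairs[:, :, 1] < 0)
        pairs[miss] = -1
        for k, locus in enumerate(loci):
            col = pairs[:, k, :]
            if col.max(initial=-1) >= locus.n_alleles:
                raise ValueError(
                    f"locus {locus.locus_id}: allele index out of range "
                    f"(declared {locus.n_alleles} alleles)"
                )
        self.samples = samples
        self.loci = loci
        self.pairs = pairs
        self._sample_idx = {s: i for i, s in enumerate(samples)}
        self._locus_idx = {l.locus_id: i for i, l in enumerate(loci)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_calls(cls, samples, loci, calls) -> "GenotypeMatrix":
        """Build from nested allele-string calls.

        ``calls[i][j]`` is a 2-tuple of allele strings, or MISSING/None.
        """
        loci = list(loci)
        pairs = np.full((len(samples), len(loci), 2), -1, dtype=np.int16)
        for i, row in enumerate(calls):
            for j, call in enumerate(row):
                if call is MISSING or call is None:
                    continue
                a, b = call
                locus = loci[j]
                try:
                    ia, ib = locus.alleles.index(a), locus.alleles.index(b)
                except ValueError:
                    raise ValueError(
                        f"call {call} at locus {locus.locus_id} uses an allele "
                        f"outside {locus.alleles}"
                    ) from None
                pairs[i, j] = sorted((ia, ib))
        return cls(list(samples), loci, pairs)

    @classmethod
    def empty(cls, samples, loci) -> "GenotypeMatrix":
        return cls(list(samples), list(loci),
                   np.full((len(samples), len(loci), 2), -1, dtype=np.int16))

    # -- basic access ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_idx[sample_id]

    def locus_index(self, locus_id: str) -> int:
        return self._locus_idx[locus_id]

    def call(self, sample_id: str, locus_id: str):
        """Allele-string pair for one cell, or MISSING."""
        i = self._sample_idx[sample_id]
        j = self._locus_idx[locus_id]
        a, b = self.pairs[i, j]
        if a < 0:
            return MISSING
        alleles = self.loci[j].alleles
        return (alleles[a], alleles[b])

    def is_missing(self) -> np.ndarray:
        return self.pairs[:, :, 0] < 0

    def genotype_codes(self) -> np.ndarray:
        """Canonical genotype codes (n_samples, n_loci); -1 where missing.

        For a biallelic locus the code is the alt-allele dosage 0/1/2.
        """
        a = self.pairs[:, :, 0].astype(np.int32)
        b = self.pairs[:, :, 1].astype(np.int32)
        codes = b * (b + 1) // 2 + a
        codes[a < 0] = -1
        return codes

    def allele_counts(self, locus_id: str) -> np.ndarray:
        """Counts of each declared allele over non-missing calls at a locus."""
        j = self._locus_idx[locus_id]
        locus = self.loci[j]
        col = self.pairs[:, j, :].ravel()
        col = col[col >= 0]
        return np.bincount(col, minlength=locus.n_alleles)

    def call_rate_per_sample(self) -> np.ndarray:
        return 1.0 - self.is_missing().mean(axis=1)

    def call_rate_per_locus(self) -> np.ndarray:
        return 1.0 - self.is_missing().mean(axis=0)

    # -- manipulation ------------------------------------------------------
    def subset(self, samples=None, loci=None) -> "GenotypeMatrix":
        rows = (list(range(self.n_samples)) if samples is None
                else [self._sample_idx[s] for s in samples])
        cols = (list(range(self.n_loci)) if loci is None
                else [self._locus_idx[l] for l in loci])
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.loci[j] for j in cols],
            self.pairs[np.ix_(rows, cols)],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), list(self.loci), self.pairs.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.pairs, other.pairs)
        )


class AlleleCodingError(ValueError):
    """Raised when the same locus carries incompatible allele sets across runs."""


def merge_runs(matrices: list[GenotypeMatrix], policy: str = "prefer_latest") -> GenotypeMatrix:
    """Merge genotype matrices from successive sequencing runs.

    ``prefer_latest`` keeps the latest run's call when a sample was re-typed;
    ``consensus_or_missing`` keeps agreeing calls and blanks disagreements
    (discordance count logged). Matrices are given in run order.
    """
    if policy not in ("prefer_latest", "consensus_or_missing"):
        raise ValueError(f"unknown merge policy {policy!r}")
    if not matrices:
        raise ValueError("no matrices to merge")

    loci: list[Locus] = []
    locus_seen: dict[str, Locus] = {}
    for m in matrices:
        for l in m.loci:
            prev = locus_seen.get(l.locus_id)
            if prev is None:
                locus_seen[l.locus_id] = l
                loci.append(l)
            elif prev.alleles != l.alleles:
                raise AlleleCodingError(
                    f"locus {l.locus_id}: allele coding differs across runs "
                    f"({prev.alleles} vs {l.alleles})"
                )
    samples: list[str] = []
    for m in matrices:
        for s in m.samples:
            if s not in samples:
                samples.append(s)

    out = np.full((len(samples), len(loci), 2), -1, dtype=np.int16)
    filled = np.zeros((len(samples), len(loci)), dtype=bool)
    s_idx = {s: i for i, s in enumerate(samples)}
    l_idx = {l.locus_id: j for j, l in enumerate(loci)}
    discordant = 0
    for m in matrices:  # run order
        rows = np.array([s_idx[s] for s in m.samples])
        cols = np.array([l_idx[l] for l in m.locus_ids])
        for mi, gi in enumerate(rows):
            new = m.pairs[mi]
            present = new[:, 0] >= 0
            for mj_arr in (np.nonzero(present)[0],):
                gj = cols[mj_arr]
                conflict = filled[gi, gj] & (
                    (out[gi, gj, 0] != new[mj_arr, 0]) | (out[gi, gj, 1] != new[mj_arr, 1])
                )
                if policy == "prefer_latest":
                    out[gi, gj] = new[mj_arr]
                else:
                    fresh = ~filled[gi, gj]
                    out[gi, gj[fresh]] = new[mj_arr[fresh]]
                    out[gi, gj[conflict]] = -1
                    discordant += int(conflict.sum())
                filled[gi, gj] = True
    if discordant:
        log.info("merge_runs: %d discordant duplicate calls set to MISSING", discordant)
    merged = GenotypeMatrix(samples, loci, out)
    merged.discordant_calls = discordant
    return merged
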