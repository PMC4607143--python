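"""Marker-panel domain types: loci, amplicons and per-site read summaries.

An amplicon is a long-range PCR product (typically several kilobases); the
SNPs inside one amplicon are physically linked and are inherited together as
haplotypes. A panel is the ordered collection of amplicons used by a
genotyping assay, each tagged with the class of variation it targets
(putatively neutral, immune or behavioural).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TARGET_CLASSES = ("neutral", "immune", "behavioural")


@dataclass(frozen=True)
class Locus:
    """A single variant site belonging to exactly one amplicon.

    Coordinates are 1-based inclusive (VCF convention). ``alt_alleles`` has
    length 1 for a biallelic SNP; longer tuples are permitted so that
    multi-allelic markers (e.g. microsatellites used for cross-marker
    comparisons) can share the same container.
    """

    locus_id: str
    amplicon_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1, got {self.position}")
        alleles = (self.ref_allele, *self.alt_alleles)
        if not all(alleles):
            raise ValueError(f"{self.locus_id}: empty allele")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{self.locus_id}: alleles must be mutually distinct: {alleles}")
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_biallelic(self) -> bool:
        return self.n_alleles == 2


@dataclass
class Amplicon:
    amplicon_id: str
    target_class: str
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(
                f"{self.amplicon_id}: target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )
        if not self.loci:
            raise ValueError(f"{self.amplicon_id}: amplicon must contain at least one locus")
        for locus in self.loci:
            if locus.amplicon_id != self.amplicon_id:
                raise ValueError(
                    f"locus {locus.locus_id} claims amplicon {locus.amplicon_id}, "
                    f"not {self.amplicon_id}"
                )
        self.loci = sorted(self.loci, key=lambda l: l.position)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


class AmpliconPanel:
    """Ordered set of amplicons; every locus belongs to exactly one amplicon."""

    def __init__(self, amplicons: list[Amplicon]):
        self.amplicons = list(amplicons)
        seen: dict[str, str] = {}
        for amp in self.amplicons:
            for locus in amp.loci:
                if locus.locus_id in seen:
                    raise ValueError(
                        f"locus id {locus.locus_id} appears in amplicons "
                        f"{seen[locus.locus_id]} and {amp.amplicon_id}"
                    )
                seen[locus.locus_id] = amp.amplicon_id
        self._locus_map = {l.locus_id: l for a in self.amplicons for l in a.loci}
        self._coord_map = {(l.chromosome, l.position): l for l in self._locus_map.values()}
        self._amp_map = {a.amplicon_id: a for a in self.amplicons}
        if len(self._amp_map) != len(self.amplicons):
            raise ValueError("duplicate amplicon ids in panel")

    @property
    def loci(self) -> list[Locus]:
        return [l for a in self.amplicons for l in a.loci]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def amplicon_ids(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons]

    @property
    def n_loci(self) -> int:
        return sum(a.n_loci for a in self.amplicons)

    def get_locus(self, locus_id: str) -> Locus:
        return self._locus_map[locus_id]

    def get_amplicon(self, amplicon_id: str) -> Amplicon:
        return self._amp_map[amplicon_id]

    def locus_at(self, chromosome: str, position: int) -> Locus | None:
        return self._coord_map.get((chromosome, position))

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._locus_map

    def subset(self, locus_ids) -> "AmpliconPanel":
        """Panel restricted to the given loci; amplicons left empty are dropped."""
        keep = set(locus_ids)
        amps = []
        for a in self.amplicons:
            loci = [l for l in a.loci if l.locus_id in keep]
            if loci:
                amps.append(Amplicon(a.amplicon_id, a.target_class, loci))
        return AmpliconPanel(amps)


@dataclass(frozen=True)
class PileupSite:
    """Read-count summary at one site, restricted to quality reads.

    ``depth_q`` counts reads passing both base and mapping quality >= ``qmin``
    (default 20); ``alt_count`` of those support the alternate base.
    """

    chromosome: str
    position: int
    depth_q: int
    alt_count: int
    qmin: int = 20
    locus_id: str | None = None

    def __post_init__(self) -> None:
        if self.qmin < 0:
            raise ValueError("qmin must be >= 0")
        if not (0 <= self.alt_count <= self.depth_q):
            raise ValueError(
                f"alt_count must satisfy 0 <= alt_count <= depth_q, "
                f"got alt={self.alt_count}, depth={self.depth_q}"
            )
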