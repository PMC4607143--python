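"""Pedigree registry: offspring with known and candidate parents per facility."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PedigreeEntry:
    offspring_id: str
    facility_id: str
    known_dam: str | None = None
    known_sire: str | None = None
    candidate_dams: set[str] = field(default_factory=set)
    candidate_sires: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.candidate_dams = set(self.candidate_dams)
        self.candidate_sires = set(self.candidate_sires)
        if self.known_dam is not None and self.known_dam in self.candidate_dams:
            raise ValueError(
                f"{self.offspring_id}: known dam {self.known_dam} also listed as candidate"
            )
        if self.known_sire is not None and self.known_sire in self.candidate_sires:
            raise ValueError(
                f"{self.offspring_id}: known sire {self.known_sire} also listed as candidate"
            )
        if self.known_dam is None and not self.candidate_dams:
            raise ValueError(f"{self.offspring_id}: no known dam and empty candidate dam set")
        if self.known_sire is None and not self.candidate_sires:
            raise ValueError(f"{self.offspring_id}: no known sire and empty candidate sire set")
        if self.offspring_id in self.candidate_dams | self.candidate_sires:
            raise ValueError(f"{self.offspring_id}: offspring cannot be its own candidate parent")


class PedigreeRegistry:
    def __init__(self, entries: list[PedigreeEntry]):
        self.entries = list(entries)
        ids = [e.offspring_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate offspring ids in registry")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def offspring_ids(self) -> list[str]:
        return [e.offspring_id for e in self.entries]

    def get(self, offspring_id: str) -> PedigreeEntry:
        for e in self.entries:
            if e.offspring_id == offspring_id:
                return e
        raise KeyError(offspring_id)

    def facilities(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.facility_id not in seen:
                seen.append(e.facility_id)
        return seen
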