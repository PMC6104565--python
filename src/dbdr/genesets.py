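"""Gene-set (pathway) containers.

A :class:`GeneSetCollection` plays the role of a pathway database (e.g. KEGG
exported as GMT): an ordered collection of named gene sets with unique ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from dbdr.errors import ValidationError


@dataclass(frozen=True)
class GeneSet:
    """One pathway: an id, a human-readable name, and its member gene ids."""

    id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError("members", f"gene set {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets with unique pathway ids."""

    entries: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError("entries", f"duplicate pathway ids: {dupes}")
        self._index = {e.id: e for e in self.entries}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._index

    def __getitem__(self, pathway_id: str) -> GeneSet:
        return self._index[pathway_id]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def members(self, pathway_id: str) -> tuple[str, ...]:
        return self._index[pathway_id].members

    @classmethod
    def from_dict(cls, sets: dict[str, Sequence[str]]) -> "GeneSetCollection":
        return cls([GeneSet(pid, pid, tuple(genes)) for pid, genes in sets.items()])
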