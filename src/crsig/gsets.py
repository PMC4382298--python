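"""Gene-set collections (GO-term style) with ontology depth and overlaps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError


@dataclass
class GeneSetCollection:
    """Named gene sets with term metadata.

    Parameters
    ----------
    sets
        Mapping term_id -> frozenset of member gene IDs (opaque strings).
    names
        Mapping term_id -> human-readable description.
    depth
        Mapping term_id -> ontology depth (a positive integer; the level of
        the term in the ontology hierarchy, supplied as metadata).
    seed
        Seed of the generating simulation, if the collection is synthetic.
    """

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.sets = {t: frozenset(m) for t, m in self.sets.items()}
        for term, members in self.sets.items():
            if len(members) == 0:
                raise ConfigError(f"term {term!r} has no members")
        for term, d in self.depth.items():
            if d < 1:
                raise ConfigError(f"term {term!r} has depth {d} < 1")

    @property
    def term_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def size(self, term: str) -> int:
        return len(self.sets[term])

    def overlap(self, term_a: str, term_b: str) -> int:
        """Number of genes shared by two terms."""
        return len(self.sets[term_a] & self.sets[term_b])

    def effective_members(self, term: str, measured: Iterable[str]) -> frozenset[str]:
        """Members of ``term`` actually measured in a study."""
        return self.sets[term] & frozenset(measured)

    def subset(self, terms: Iterable[str]) -> "GeneSetCollection":
        terms = list(terms)
        missing = [t for t in terms if t not in self.sets]
        if missing:
            raise ConfigError(f"terms not in collection: {missing[:5]}")
        return GeneSetCollection(
            sets={t: self.sets[t] for t in terms},
            names={t: self.names.get(t, t) for t in terms},
            depth={t: self.depth[t] for t in terms if t in self.depth},
            seed=self.seed,
        )

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def depths_as_mapping(depth: Mapping[str, int], terms: Iterable[str]) -> dict[str, int]:
    missing = [t for t in terms if t not in depth]
    if missing:
        raise ConfigError(f"terms without depth metadata: {missing[:5]}")
    return {t: int(depth[t]) for t in terms}
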