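"""Causal prior network and phosphosite-effect library.

A *causal prior* is a curated pathway fragment stating that one protein's
activity can change a measurable feature of another protein.  Four relation
types are supported: phosphorylation, dephosphorylation, and transcriptional
up/downregulation.  Phospho relations may be annotated with the target
site(s) they act on, in canonical UniProt coordinates.

The site-effect library records, per (gene symbol, site), whether
phosphorylation at that site activates or inhibits the protein's relevant
activity; absent entries read as ``unknown``.

File dialects are tab-delimited, one relation per line, close to the SIF
(simple interaction format) convention:

    Source <TAB> Relation <TAB> Target [<TAB> TargetSites [<TAB> Mediators]]

with sites semicolon-joined (``Y406;S235``).  Multiple sites on one relation
mean "any of these sites".  Gene symbols are uppercased on load and compared
case-sensitively afterwards.
"""

from __future__ import annotations

import enum
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .ternary import Ternary

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True, order=True)
class Site:
    """A protein residue position in canonical UniProt coordinates."""

    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid code: {self.residue!r}")
        if not isinstance(self.position, int) or self.position < 1:
            raise ValueError(f"site position must be a positive integer: {self.position!r}")

    @classmethod
    def parse(cls, token: str) -> "Site":
        """Parse a residue+position token such as ``Y406``."""
        token = token.strip()
        if len(token) < 2:
            raise ValueError(f"malformed site token: {token!r}")
        residue, pos = token[0].upper(), token[1:]
        if not pos.isdigit():
            raise ValueError(f"malformed site token (non-integer position): {token!r}")
        return cls(residue, int(pos))

    def __str__(self) -> str:
        return f"{self.residue}{self.position}"


class RelationType(enum.Enum):
    """The four causal prior relation types."""

    PHOSPHORYLATES = "phosphorylates"
    DEPHOSPHORYLATES = "dephosphorylates"
    UPREGULATES_EXPRESSION = "upregulates-expression"
    DOWNREGULATES_EXPRESSION = "downregulates-expression"

    @classmethod
    def parse(cls, token: str) -> "RelationType":
        canon = token.strip().lower().replace("_", "-")
        for member in cls:
            if member.value == canon:
                return member
        raise ValueError(f"unknown relation type: {token!r}")

    @property
    def is_phospho(self) -> bool:
        return self in (RelationType.PHOSPHORYLATES, RelationType.DEPHOSPHORYLATES)

    @property
    def is_expression(self) -> bool:
        return not self.is_phospho

    @property
    def sign(self) -> bool:
        """True for phosphorylation and expression upregulation."""
        return self in (RelationType.PHOSPHORYLATES, RelationType.UPREGULATES_EXPRESSION)


class Effect(enum.Enum):
    """Effect of phosphorylation at a site on the protein's activity."""

    ACTIVATING = "activating"
    INHIBITING = "inhibiting"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "Effect":
        canon = token.strip().lower()
        mapping = {
            "a": cls.ACTIVATING,
            "activating": cls.ACTIVATING,
            "i": cls.INHIBITING,
            "inhibiting": cls.INHIBITING,
        }
        if canon not in mapping:
            raise ValueError(f"unknown site-effect token: {token!r}")
        return mapping[canon]

    @property
    def as_ternary(self) -> Ternary:
        if self is Effect.ACTIVATING:
            return Ternary.TRUE
        if self is Effect.INHIBITING:
            return Ternary.FALSE
        return Ternary.UNKNOWN


@dataclass(frozen=True)
class PriorRelation:
    """One signed, typed, optionally site-annotated causal prior edge."""

    source: str
    rtype: RelationType
    target: str
    target_sites: tuple[Site, ...] = ()
    mediators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", self.source.strip().upper())
        object.__setattr__(self, "target", self.target.strip().upper())
        if not self.source or not self.target:
            raise ValueError("prior relation source and target must be nonempty")
        object.__setattr__(self, "target_sites", tuple(sorted(set(self.target_sites))))
        object.__setattr__(self, "mediators", tuple(self.mediators))
        if self.target_sites and not self.rtype.is_phospho:
            raise ValueError(
                f"expression relation {self.source}->{self.target} may not carry target sites"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity at the (source, type, target) level, ignoring sites."""
        return (self.source, self.rtype.value, self.target)

    @property
    def dedup_key(self) -> tuple:
        return (self.source, self.rtype.value, self.target, self.target_sites)

    @property
    def is_self(self) -> bool:
        """Self-edges (e.g. autophosphorylation) are permitted but flagged."""
        return self.source == self.target

    def __str__(self) -> str:
        sites = ";".join(str(s) for s in self.target_sites)
        return f"{self.source} {self.rtype.value} {self.target}" + (f" [{sites}]" if sites else "")


class PriorNetwork:
    """An indexed, duplicate-free collection of :class:`PriorRelation`."""

    def __init__(self, relations: Iterable[PriorRelation] = ()) -> None:
        merged: dict[tuple, PriorRelation] = {}
        for rel in relations:
            prev = merged.get(rel.dedup_key)
            if prev is None:
                merged[rel.dedup_key] = rel
            elif rel.mediators:
                mediators = prev.mediators + tuple(
                    m for m in rel.mediators if m not in prev.mediators
                )
                merged[rel.dedup_key] = PriorRelation(
                    prev.source, prev.rtype, prev.target, prev.target_sites, mediators
                )
        self._relations: tuple[PriorRelation, ...] = tuple(merged.values())
        self._by_source: dict[str, list[PriorRelation]] = {}
        self._by_target: dict[str, list[PriorRelation]] = {}
        for rel in self._relations:
            self._by_source.setdefault(rel.source, []).append(rel)
            self._by_target.setdefault(rel.target, []).append(rel)

    @property
    def relations(self) -> tuple[PriorRelation, ...]:
        return self._relations

    def by_source(self, symbol: str) -> Sequence[PriorRelation]:
        return self._by_source.get(symbol.upper(), ())

    def by_target(self, symbol: str) -> Sequence[PriorRelation]:
        return self._by_target.get(symbol.upper(), ())

    def symbols(self) -> set[str]:
        return set(self._by_source) | set(self._by_target)

    def relation_keys(self) -> set[tuple[str, str, str]]:
        return {rel.key for rel in self._relations}

    def counts_by_type(self) -> dict[str, int]:
        counts = {member.value: 0 for member in RelationType}
        for rel in self._relations:
            counts[rel.rtype.value] += 1
        return counts

    def __len__(self) -> int:
        return len(self._relations)

    def __iter__(self) -> Iterator[PriorRelation]:
        return iter(self._relations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PriorNetwork):
            return NotImplemented
        return set(r.dedup_key for r in self) == set(r.dedup_key for r in other)


class SiteEffectLibrary:
    """Mapping from (gene symbol, site) to activating/inhibiting effect.

    Lookups of absent pairs return :attr:`Effect.UNKNOWN`.  Conflicting
    duplicate annotations for the same pair are rejected at construction.
    """

    def __init__(self, entries: Iterable[tuple[str, Site, Effect]] = ()) -> None:
        self._effects: dict[tuple[str, Site], Effect] = {}
        for symbol, site, effect in entries:
            key = (symbol.strip().upper(), site)
            prev = self._effects.get(key)
            if prev is not None and prev is not effect:
                raise ValueError(
                    f"conflicting effects for {key[0]} {site}: {prev.value} vs {effect.value}"
                )
            self._effects[key] = effect

    def effect_of(self, symbol: str, site: Site) -> Effect:
        return self._effects.get((symbol.upper(), site), Effect.UNKNOWN)

    def items(self) -> Iterable[tuple[tuple[str, Site], Effect]]:
        return self._effects.items()

    def __len__(self) -> int:
        return len(self._effects)


def _parse_sites_field(text: str) -> tuple[Site, ...]:
    text = text.strip()
    if not text:
        return ()
    tokens = [t for part in text.split(";") for t in part.split("|") if t.strip()]
    seen: dict[Site, None] = {}
    for token in tokens:
        seen.setdefault(Site.parse(token), None)
    return tuple(seen)


def read_prior_network(path: str | Path, fmt: str = "tsv") -> PriorNetwork:
    """Load a prior network from a tab-delimited relation file.

    Each data line must have at least three fields: source, relation type,
    target, optionally followed by semicolon-joined target sites and a
    mediators/provenance field.  A header line is recognized when the second
    field is not a valid relation type token and reads like a header.
    Malformed lines (fewer than 3 fields) are counted, logged and skipped;
    an unrecognized relation type is a hard error naming the line.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported prior file dialect: {fmt!r}")
    path = Path(path)
    relations: list[PriorRelation] = []
    n_malformed = 0
    n_self = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_malformed += 1
                logger.warning("%s:%d: malformed line (fewer than 3 fields)", path, lineno)
                continue
            try:
                rtype = RelationType.parse(fields[1])
            except ValueError:
                if lineno == 1 and fields[1].strip().lower() in ("relation", "rtype", "interaction"):
                    continue  # header line
                raise ValueError(
                    f"{path}:{lineno}: unknown relation type {fields[1]!r}"
                ) from None
            sites = _parse_sites_field(fields[3]) if len(fields) > 3 else ()
            if sites and rtype.is_expression:
                # Expression relations carry no sites; drop with a warning.
                logger.warning("%s:%d: ignoring sites on expression relation", path, lineno)
                sites = ()
            mediators = tuple(
                m.strip() for m in fields[4].split(";") if m.strip()
            ) if len(fields) > 4 else ()
            rel = PriorRelation(fields[0], rtype, fields[2], sites, mediators)
            if rel.is_self:
                n_self += 1
            relations.append(rel)
    net = PriorNetwork(relations)
    if len(net) == 0:
        logger.warning("%s: empty prior network", path)
    if n_malformed:
        logger.warning("%s: skipped %d malformed lines", path, n_malformed)
    if n_self:
        logger.info("%s: %d self-edges retained", path, n_self)
    logger.info("%s: loaded %d relations: %s", path, len(net), net.counts_by_type())
    return net


def write_prior_network(net: PriorNetwork, path: str | Path) -> None:
    """Write a prior network in the dialect read by :func:`read_prior_network`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Source\tRelation\tTarget\tTargetSites\tMediators\n")
        for rel in sorted(net, key=lambda r: r.dedup_key):
            sites = ";".join(str(s) for s in rel.target_sites)
            mediators = ";".join(rel.mediators)
            fh.write(f"{rel.source}\t{rel.rtype.value}\t{rel.target}\t{sites}\t{mediators}\n")


def read_site_effects(path: str | Path) -> SiteEffectLibrary:
    """Load a site-effect library: TSV lines of symbol, site, effect token.

    Effect tokens are ``a``/``activating`` and ``i``/``inhibiting``; anything
    else is a hard error (a header line is tolerated when its third field is
    literally ``effect``).
    """
    path = Path(path)
    entries: list[tuple[str, Site, Effect]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected symbol, site, effect")
            if lineno == 1 and fields[2].strip().lower() == "effect":
                continue
            try:
                effect = Effect.parse(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            entries.append((fields[0], Site.parse(fields[1]), effect))
    return SiteEffectLibrary(entries)


def write_site_effects(library: SiteEffectLibrary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Symbol\tSite\tEffect\n")
        for (symbol, site), effect in sorted(
            library.items(), key=lambda kv: (kv[0][0], kv[0][1])
        ):
            fh.write(f"{symbol}\t{site}\t{effect.value}\n")


def neighborhood_filter(net: PriorNetwork, seeds: Iterable[str], hops: int) -> PriorNetwork:
    """Restrict ``net`` to relations within ``hops`` undirected steps of seeds.

    A relation is kept when it can be reached by traversing at most ``hops``
    edges from a seed, i.e. at least one of its endpoints lies at undirected
    distance <= hops - 1 from the seed set.  The result is a subset of the
    input; the operation is idempotent at fixed seeds/hops and monotone in
    ``hops``.
    """
    seed_set = {s.strip().upper() for s in seeds if s.strip()}
    if not seed_set:
        raise ValueError("neighborhood_filter requires at least one seed symbol")
    if hops < 1:
        raise ValueError("hops must be >= 1")
    adjacency: dict[str, set[str]] = {}
    for rel in net:
        adjacency.setdefault(rel.source, set()).add(rel.target)
        adjacency.setdefault(rel.target, set()).add(rel.source)
    # Multi-source BFS for undirected distances from the seed set.
    dist: dict[str, int] = {s: 0 for s in seed_set if s in adjacency}
    queue = deque(dist)
    while queue:
        node = queue.popleft()
        for nbr in adjacency.get(node, ()):
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    kept = [
        rel
        for rel in net
        if min(dist.get(rel.source, hops), dist.get(rel.target, hops)) <= hops - 1
    ]
    return PriorNetwork(kept)
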