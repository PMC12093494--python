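"""Domain architectures and combinatorial pattern classification.

After filtering, the retained domains of a protein are arranged in order of
their position along the sequence — its *domain architecture* (e.g.
``GH23+CBM50+CBM50``).  Each protein is classified into one of three
combinatorial pattern classes:

``alone``
    a single domain;
``multi_copy``
    two or more copies of one family and nothing else (e.g. CE8 in
    triplicate);
``with_accessory``
    at least two distinct families, i.e. a catalytic domain accompanied by
    accessory domains such as carbohydrate-binding modules (GH23 with one to
    three copies of CBM50).

Tallies can be taken at subfamily granularity (the default: GH13_11 is its
own key, so subfamily-specific associations like GH13_11 with CBM48 are
countable) or collapsed to parent families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Mapping, Union

from .domtblout import DomainHit
from .vocab import FamilyLabel, parse_family_label

Granularity = Literal["subfamily", "family"]

#: key used for the focal family's no-partner bucket in co-occurrence tables
SELF = "self"


class Pattern(str, Enum):
    ALONE = "alone"
    MULTI_COPY = "multi_copy"
    WITH_ACCESSORY = "with_accessory"


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered retained domains of one protein plus its pattern class."""

    protein_id: str
    organism_tag: str
    domains: tuple[FamilyLabel, ...]
    pattern: Pattern

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def architecture_string(self) -> str:
        return "+".join(d.canonical for d in self.domains)

    def families(self, granularity: Granularity = "subfamily") -> frozenset[FamilyLabel]:
        """Distinct family labels present, at the requested granularity."""
        if granularity == "family":
            return frozenset(d.parent for d in self.domains)
        return frozenset(self.domains)


def _classify(domains: tuple[FamilyLabel, ...]) -> Pattern:
    if len(domains) == 1:
        return Pattern.ALONE
    if len({d.canonical for d in domains}) == 1:
        return Pattern.MULTI_COPY
    return Pattern.WITH_ACCESSORY


def build_architecture(retained_hits: Iterable[DomainHit]) -> ProteinArchitecture:
    """Arrange one protein's retained hits by sequence position.

    Hits must already be filtered/resolved and share one protein.  Ordering
    key is the alignment start (ties: alignment end, then family string).
    """
    hits = list(retained_hits)
    if not hits:
        raise ValueError("cannot build an architecture from zero hits")
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    ordered = sorted(hits, key=lambda h: (h.ali_from, h.ali_to, h.family.canonical))
    domains = tuple(h.family for h in ordered)
    return ProteinArchitecture(
        protein_id=hits[0].protein_id,
        organism_tag=hits[0].organism_tag,
        domains=domains,
        pattern=_classify(domains),
    )


def build_architectures(
    hits_by_protein: Mapping[str, Iterable[DomainHit]]
) -> list[ProteinArchitecture]:
    """Architectures for every protein of a filtered proteome, sorted by id."""
    return [
        build_architecture(hits) for _, hits in sorted(hits_by_protein.items())
    ]


def _as_label(family: Union[FamilyLabel, str]) -> FamilyLabel:
    return parse_family_label(family) if isinstance(family, str) else family


def cooccurrence_table(
    architectures: Iterable[ProteinArchitecture],
    focal: Union[FamilyLabel, str],
    *,
    granularity: Granularity = "subfamily",
) -> dict[str, int]:
    """Protein-level co-occurrence partners of a focal family.

    For every protein containing the focal family, each *distinct* partner
    family present in the same protein is counted once.  Proteins where the
    focal family has no distinct partner (alone or in multiple copies of
    itself) land in the ``"self"`` bucket.
    """
    focal = _as_label(focal)
    if granularity == "family":
        focal = focal.parent
    focal_key = focal.canonical
    table: Counter[str] = Counter()
    for arch in architectures:
        fams = {f.canonical for f in arch.families(granularity)}
        if focal_key not in fams:
            continue
        partners = fams - {focal_key}
        if partners:
            for p in partners:
                table[p] += 1
        else:
            table[SELF] += 1
    return dict(table)


def pattern_frequency(
    architectures: Iterable[ProteinArchitecture],
    *,
    granularity: Granularity = "subfamily",
) -> dict[str, tuple[int, int, int]]:
    """Per-family protein counts in each combinatorial pattern class.

    Returns family -> (alone, multi_copy, with_accessory); a protein
    contributes once for each distinct family it contains, so per family the
    three counts sum to the number of proteins containing that family.
    """
    freq: dict[str, list[int]] = {}
    idx = {Pattern.ALONE: 0, Pattern.MULTI_COPY: 1, Pattern.WITH_ACCESSORY: 2}
    for arch in architectures:
        for fam in arch.families(granularity):
            freq.setdefault(fam.canonical, [0, 0, 0])[idx[arch.pattern]] += 1
    return {k: tuple(v) for k, v in sorted(freq.items())}
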