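"""Quality filtering and overlap resolution of CAZyme domain hits.

Raw domain tables contain low-quality matches (weak e-values, small covered
fractions of the HMM profile) and overlapping redundant hits where several
profiles match the same stretch of a protein.  This module keeps
high-quality matches and resolves overlaps greedily in favour of the better
independent e-value, the same convention the dbCAN parser family of tools
uses: i-Evalue <= 1e-15 for alignments of at least 80 residues (1e-3 for
shorter ones), profile coverage >= 0.35, and at most 50% overlap between
retained hits measured on the shorter alignment interval.  All thresholds
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .domtblout import DomainHit


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for hit quality filtering and overlap resolution.

    Parameters
    ----------
    max_ievalue:
        Independent e-value ceiling for alignments of at least
        ``short_alignment_cutoff`` residues.
    min_coverage:
        Minimum covered fraction of the HMM profile.
    overlap_fraction:
        Two retained hits may share at most this fraction of the shorter of
        the two alignment intervals.
    relaxed_ievalue_for_short:
        e-value ceiling applied instead of ``max_ievalue`` when the alignment
        is shorter than ``short_alignment_cutoff`` residues.
    same_family_only:
        Resolve overlaps only between hits of the same family; by default
        overlaps are resolved across families.
    """

    max_ievalue: float = 1e-15
    min_coverage: float = 0.35
    overlap_fraction: float = 0.5
    relaxed_ievalue_for_short: float = 1e-3
    short_alignment_cutoff: int = 80
    same_family_only: bool = False

    def __post_init__(self) -> None:
        if self.max_ievalue <= 0 or self.relaxed_ievalue_for_short <= 0:
            raise ValueError("e-value thresholds must be positive")
        if not (0 <= self.min_coverage <= 1):
            raise ValueError("min_coverage must lie in [0, 1]")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if self.short_alignment_cutoff <= 0:
            raise ValueError("short_alignment_cutoff must be positive")

    def passes_quality(self, hit: DomainHit) -> bool:
        if hit.coverage < self.min_coverage:
            return False
        if hit.dom_ievalue <= self.max_ievalue:
            return True
        return (
            hit.ali_length < self.short_alignment_cutoff
            and hit.dom_ievalue <= self.relaxed_ievalue_for_short
        )


def quality_filter(hits: Iterable[DomainHit], cfg: FilterConfig | None = None) -> list[DomainHit]:
    """Keep hits meeting the coverage and e-value thresholds; order preserved."""
    cfg = cfg or FilterConfig()
    return [h for h in hits if cfg.passes_quality(h)]


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1


def _conflicts(a: DomainHit, b: DomainHit, cfg: FilterConfig) -> bool:
    """True if a and b overlap by more than the allowed fraction of the shorter."""
    if cfg.same_family_only and a.family.canonical != b.family.canonical:
        return False
    ov = _overlap_len(a, b)
    if ov <= 0:
        return False
    shorter = min(a.ali_length, b.ali_length)
    return ov > cfg.overlap_fraction * shorter


def _priority_key(h: DomainHit) -> tuple:
    # better (smaller) i-Evalue first; ties: higher coverage, then canonical
    # family string, then leftmost alignment start; the remaining fields make
    # the order total so the outcome cannot depend on input order
    return (
        h.dom_ievalue, -h.coverage, h.family.canonical, h.ali_from,
        h.ali_to, h.hmm_length, h.hmm_from, h.hmm_to, h.env_from, h.env_to,
        h.dom_score, h.full_seq_evalue,
    )


def resolve_overlaps(hits: Iterable[DomainHit], cfg: FilterConfig | None = None) -> list[DomainHit]:
    """Greedy overlap resolution among hits on one protein.

    Hits are visited in order of ascending independent e-value (ties broken
    by higher coverage, then family string, then alignment start).  A hit is
    accepted iff its alignment interval overlaps every previously accepted
    hit by at most ``overlap_fraction`` of the shorter of the two intervals.
    Accepted hits are returned sorted by alignment start.  The result is
    deterministic regardless of input order, and idempotent.
    """
    cfg = cfg or FilterConfig()
    hits = list(hits)
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise ValueError(f"resolve_overlaps expects one protein, got {sorted(protein_ids)}")
    accepted: list[DomainHit] = []
    for h in sorted(hits, key=_priority_key):
        if all(not _conflicts(h, kept, cfg) for kept in accepted):
            accepted.append(h)
    return sorted(accepted, key=lambda h: (h.ali_from, h.ali_to, h.family.canonical))


def filter_organism(
    hits_by_protein: Mapping[str, Iterable[DomainHit]],
    cfg: FilterConfig | None = None,
) -> dict[str, list[DomainHit]]:
    """Apply quality filtering then overlap resolution to each protein.

    Proteins left without any retained hit are dropped from the mapping.
    """
    cfg = cfg or FilterConfig()
    out: dict[str, list[DomainHit]] = {}
    for protein_id, hits in hits_by_protein.items():
        kept = resolve_overlaps(quality_filter(hits, cfg), cfg)
        if kept:
            out[protein_id] = kept
    return out
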