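import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cazprofiler.domtblout import group_by_protein
from cazprofiler.filtering import (
    FilterConfig,
    filter_organism,
    quality_filter,
    resolve_overlaps,
)
from cazprofiler.vocab import parse_family_label

from .strategies import domain_hits
from .test_domtblout import make_hit

CFG = FilterConfig()


# ---------------------------------------------------------------- oracles
def overlap_ok(a, b, cfg):
    """Independent pairwise compatibility check."""
    if cfg.same_family_only and a.family.canonical != b.family.canonical:
        return True
    ov = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    return ov <= cfg.overlap_fraction * min(a.ali_length, b.ali_length)


def priority(h):
    return (
        h.dom_ievalue, -h.coverage, h.family.canonical, h.ali_from,
        h.ali_to, h.hmm_length, h.hmm_from, h.hmm_to, h.env_from, h.env_to,
        h.dom_score, h.full_seq_evalue,
    )


def brute_force_resolution(hits, cfg):
    """Enumerate all subsets; return the unique greedy-consistent one.

    A subset S is the greedy outcome iff it is pairwise compatible and every
    excluded hit conflicts with some member of S of higher priority (fully
    identical hits take their priority from their rank in the sorted list).
    """
    order = sorted(hits, key=priority)
    rank = {id(h): i for i, h in enumerate(order)}
    for r in range(len(order), -1, -1):
        for subset in itertools.combinations(order, r):
            if not all(overlap_ok(a, b, cfg) for a, b in itertools.combinations(subset, 2)):
                continue
            chosen = set(id(h) for h in subset)
            consistent = True
            for h in order:
                if id(h) in chosen:
                    continue
                blockers = [
                    s for s in subset
                    if rank[id(s)] < rank[id(h)] and not overlap_ok(s, h, cfg)
                ]
                if not blockers:
                    consistent = False
                    break
            if consistent:
                return sorted(subset, key=lambda h: (h.ali_from, h.ali_to, h.family.canonical))
    raise AssertionError("no greedy-consistent subset found")


# ---------------------------------------------------------------- quality
class TestQualityFilter:
    def test_low_coverage_dropped(self):
        h = make_hit(hmm_from=1, hmm_to=34)  # coverage 0.34
        assert quality_filter([h], CFG) == []

    def test_good_hit_kept(self):
        h = make_hit(hmm_from=1, hmm_to=90, dom_ievalue=1e-30)
        assert quality_filter([h], CFG) == [h]

    def test_short_alignment_relaxed_evalue(self):
        short = make_hit(ali_from=10, ali_to=60, dom_ievalue=1e-5)  # 51 aa < 80
        long = make_hit(ali_from=10, ali_to=120, dom_ievalue=1e-5)
        assert quality_filter([short], CFG) == [short]
        assert quality_filter([long], CFG) == []

    @given(st.lists(domain_hits(), max_size=25))
    def test_matches_naive_predicate_scan(self, hits):
        def keep(h):
            if h.coverage < CFG.min_coverage:
                return False
            return h.dom_ievalue <= CFG.max_ievalue or (
                h.ali_length < CFG.short_alignment_cutoff
                and h.dom_ievalue <= CFG.relaxed_ievalue_for_short
            )

        assert quality_filter(hits, CFG) == [h for h in hits if keep(h)]


# ---------------------------------------------------------------- overlaps
def hit_at(ali_from, ali_to, ievalue, family="GH13", pid="p1"):
    return make_hit(
        protein_id=pid,
        family=parse_family_label(family),
        ali_from=ali_from,
        ali_to=ali_to,
        dom_ievalue=ievalue,
        full_seq_evalue=ievalue,
    )


class TestResolveOverlaps:
    def test_better_evalue_wins_on_heavy_overlap(self):
        a = hit_at(1, 100, 1e-50)
        b = hit_at(41, 140, 1e-20)  # overlap 60 of shorter 100 -> conflict
        assert resolve_overlaps([a, b], CFG) == [a]
        assert resolve_overlaps([b, a], CFG) == [a]

    def test_disjoint_hits_both_kept_sorted(self):
        a = hit_at(200, 300, 1e-20)
        b = hit_at(1, 100, 1e-50)
        assert resolve_overlaps([a, b], CFG) == [b, a]

    def test_chain_keeps_flanks_drops_middle(self):
        # b shares 60 of its 101 residues with a (> half the shorter hit)
        # but only 12 with c, so resolution keeps the two flanks
        a = hit_at(1, 100, 1e-40)
        b = hit_at(41, 141, 1e-10)
        c = hit_at(130, 230, 1e-30)
        kept = resolve_overlaps([a, b, c], CFG)
        assert kept == [a, c]
        assert kept == brute_force_resolution([a, b, c], CFG)

    def test_moderate_chain_overlaps_all_retained(self):
        # pairwise overlaps of 41 and 31 residues stay under half the
        # shorter interval, so no hit conflicts with any other
        a = hit_at(1, 100, 1e-40)
        b = hit_at(60, 160, 1e-10)
        c = hit_at(130, 230, 1e-30)
        kept = resolve_overlaps([a, b, c], CFG)
        assert kept == [a, b, c]
        assert kept == brute_force_resolution([a, b, c], CFG)

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps([hit_at(1, 10, 1e-9, pid="p1"), hit_at(1, 10, 1e-9, pid="p2")], CFG)

    def test_same_family_only_mode_keeps_cross_family_overlap(self):
        cfg = FilterConfig(same_family_only=True)
        a = hit_at(1, 100, 1e-50, family="GH13")
        b = hit_at(1, 100, 1e-20, family="CBM48")
        # final ordering is positional with family string as tie-break
        assert resolve_overlaps([a, b], cfg) == [b, a]
        c = hit_at(5, 95, 1e-10, family="GH13")
        assert resolve_overlaps([a, b, c], cfg) == [b, a]

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 150),
                st.integers(1, 150),
                st.floats(1e-60, 1e-5),
                st.sampled_from(["GH13", "GH13_11", "CBM48", "GH23"]),
            ).map(lambda t: hit_at(t[0], t[0] + t[1] - 1, t[2], t[3])),
            max_size=6,
        )
    )
    def test_equals_brute_force_subset_enumeration(self, hits):
        assert resolve_overlaps(hits, CFG) == brute_force_resolution(hits, CFG)

    @given(st.lists(domain_hits(protein_id="p1"), max_size=12), st.randoms())
    def test_idempotent_and_order_independent(self, hits, rnd):
        once = resolve_overlaps(hits, CFG)
        assert resolve_overlaps(once, CFG) == once
        shuffled = list(hits)
        rnd.shuffle(shuffled)
        assert resolve_overlaps(shuffled, CFG) == once
        # no two retained hits overlap beyond the allowed fraction
        for a, b in itertools.combinations(once, 2):
            assert overlap_ok(a, b, CFG)
        assert all(h in hits for h in once)


# ---------------------------------------------------------------- driver
class TestFilterOrganism:
    def test_empty_mapping(self):
        assert filter_organism({}, CFG) == {}

    def test_single_passing_hit_unchanged(self):
        h = make_hit()
        assert filter_organism({"p1": [h]}, CFG) == {"p1": [h]}

    def test_failing_proteins_removed(self):
        bad = make_hit(hmm_from=1, hmm_to=10)  # coverage 0.1
        assert filter_organism({"p1": [bad]}, CFG) == {}

    def test_planted_truth_recovered_with_decoys(self, small_dataset):
        """Precision = recall = 1 for hit retention on decoy-laden proteomes."""
        for tag, truth in small_dataset.truth.items():
            hits = small_dataset.hits_by_organism[tag]
            filtered = filter_organism(group_by_protein(hits), CFG)
            planted = {pid: tmpl for pid, tmpl in truth.architectures}
            assert set(filtered) == set(planted)
            for pid, kept in filtered.items():
                got = tuple(h.family.canonical for h in kept)
                assert got == planted[pid]
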