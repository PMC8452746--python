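import itertools
import random

import numpy as np
import pytest

from clonedeconv.event_unification import (
    build_mcf_matrix,
    classify_scope,
    detect_stem,
    impute_missing,
    same_event,
    unify_events,
)
from clonedeconv.genome import load_genome
from clonedeconv.segment_io import McfMatrix
from conftest import make_record

MB = 1_000_000


class TestSameEvent:
    def test_within_cutoff_is_same(self):
        a = make_record("a", chrom="17", start=1 * MB, end=20 * MB,
                        mcf={"P1": 50.0})
        b = make_record("b", chrom="17", start=int(1.5 * MB), end=int(20.4 * MB),
                        mcf={"P1": 55.0})
        assert same_event(a, b, co_ev=MB)

    def test_different_type_never_same(self):
        a = make_record("a", chrom="17", alt_type="gain", mcf={"P1": 50.0})
        b = make_record("b", chrom="17", alt_type="loss", mcf={"P1": 50.0})
        assert not same_event(a, b)

    def test_identity(self):
        a = make_record("a", mcf={"P1": 50.0})
        assert same_event(a, a)

    def test_cutoff_is_inclusive(self):
        a = make_record("a", start=MB, end=5 * MB, mcf={"P1": 40.0})
        b = make_record("b", start=2 * MB, end=5 * MB, mcf={"P1": 40.0})
        assert same_event(a, b, co_ev=MB)
        assert not same_event(a, b, co_ev=MB - 1)

    def test_stem_records_never_merge(self):
        a = make_record("a", mcf={"P1": 95.0, "P2": 99.0})
        b = make_record("b", mcf={"P1": 95.0, "P2": 99.0})
        assert not same_event(a, b)


class TestUnifyEvents:
    def test_chained_merge_single_linkage(self):
        # pairwise deltas <= 1 Mbp chain three detections into one event
        recs = [
            make_record("a", start=1 * MB, end=10 * MB, mcf={"P1": 50.0}),
            make_record("b", start=2 * MB, end=11 * MB, mcf={"P2": 40.0}),
            make_record("c", start=3 * MB, end=12 * MB, mcf={"P3": 30.0}),
        ]
        cat = unify_events(recs, co_ev=MB)
        assert len(cat.unique_events) == 1
        assert cat.unique_events[0].event_id == "a"
        assert cat.unique_events[0].mcf == {"P1": 50.0, "P2": 40.0, "P3": 30.0}

    def test_beyond_cutoff_stays_separate(self):
        recs = [
            make_record("a", chrom="11", start=1 * MB, end=30 * MB,
                        alt_type="cnni", mcf={"P1": 60.0}),
            make_record("b", chrom="11", start=3 * MB, end=30 * MB,
                        alt_type="cnni", mcf={"P1": 50.0}),
        ]
        cat = unify_events(recs, co_ev=MB)
        assert len(cat.unique_events) == 2

    def test_empty_input(self):
        cat = unify_events([])
        assert cat.unique_events == [] and cat.membership == {}

    def test_partition_property_and_order_invariance(self):
        rng = random.Random(7)
        recs = []
        for i in range(30):
            start = rng.randrange(1, 50 * MB)
            recs.append(
                make_record(
                    f"e{i}", chrom=rng.choice(["1", "2"]),
                    start=start, end=start + 10 * MB,
                    alt_type=rng.choice(["gain", "loss"]),
                    mcf={"P1": rng.uniform(0, 85)},
                )
            )
        cat = unify_events(recs)
        assert sorted(cat.membership) == sorted(r.event_id for r in recs)

        # independent oracle: brute-force transitive closure over same_event
        def brute_partition(records):
            n = len(records)
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i, j in itertools.combinations(range(n), 2):
                if same_event(records[i], records[j]):
                    parent[find(i)] = find(j)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), set()).add(records[i].event_id)
            return {frozenset(g) for g in groups.values()}

        expected = brute_partition(recs)
        got = {}
        for raw, uid in cat.membership.items():
            got.setdefault(uid, set()).add(raw)
        assert {frozenset(g) for g in got.values()} == expected

        shuffled = list(recs)
        rng.shuffle(shuffled)
        cat2 = unify_events(shuffled)
        got2 = {}
        for raw, uid in cat2.membership.items():
            got2.setdefault(uid, set()).add(raw)
        assert {frozenset(g) for g in got2.values()} == expected

    def test_same_biopsy_conflict_takes_max_and_warns(self):
        recs = [
            make_record("a", start=1 * MB, end=10 * MB, mcf={"P1": 50.0}),
            make_record("b", start=int(1.2 * MB), end=int(10.2 * MB),
                        mcf={"P1": 70.0}),
        ]
        cat = unify_events(recs)
        assert cat.unique_events[0].mcf["P1"] == 70.0
        assert any("maximum" in w for w in cat.warnings)


class TestStemDetection:
    @pytest.mark.parametrize(
        "row,expected",
        [((100.0, 95.0, 92.0), True), ((100.0, 100.0, 89.0), False)],
    )
    def test_threshold_in_every_biopsy(self, row, expected):
        T = McfMatrix(["e1"], ["P1", "P2", "P3"], np.array([row]))
        assert detect_stem(T)["e1"] is expected

    def test_single_biopsy_inclusive_boundary(self):
        T = McfMatrix(["e1"], ["P1"], np.array([[90.0]]))
        assert detect_stem(T)["e1"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        T = McfMatrix(
            [f"e{i}" for i in range(20)], ["P1", "P2"],
            rng.uniform(0, 100, size=(20, 2)),
        )
        low = detect_stem(T, threshold=80)
        high = detect_stem(T, threshold=95)
        for e in T.events:
            assert not (high[e] and not low[e])


class TestMissingMcf:
    def test_user_stem_missing_becomes_100(self):
        recs = [make_record("amp", alt_type="amplification",
                            mcf={"P1": None, "P2": None})]
        cat = unify_events(recs)
        cat, warnings = impute_missing(cat, ["P1", "P2"], user_stem=["amp"])
        ev = cat.unique_events[0]
        assert ev.mcf == {"P1": 100.0, "P2": 100.0}
        assert cat.is_stem["amp"]
        assert not warnings

    def test_subclonal_missing_dropped_with_warning(self):
        recs = [
            make_record("keep", mcf={"P1": 40.0, "P2": 0.0}),
            make_record("drop", start=20 * MB, end=30 * MB,
                        mcf={"P1": 40.0, "P2": None}),
        ]
        cat = unify_events(recs)
        cat, warnings = impute_missing(cat, ["P1", "P2"])
        assert cat.event_ids == ["keep"]
        assert any("drop" in w for w in warnings)

    def test_complete_input_unchanged(self):
        recs = [make_record("a", mcf={"P1": 40.0, "P2": 10.0})]
        cat = unify_events(recs)
        cat, warnings = impute_missing(cat, ["P1", "P2"])
        assert not warnings and cat.event_ids == ["a"]


@pytest.fixture(scope="module")
def genome():
    return load_genome()


class TestScope:
    def test_whole_chromosome(self, genome):
        length = genome["17"].length
        ev = make_record("a", chrom="17", start=1, end=length, mcf={"P1": 10.0})
        assert classify_scope(ev, genome) == "whole_chromosome"

    def test_chromosome_arm(self, genome):
        c = genome["17"]
        ev = make_record("a", chrom="17", start=c.centromere_end, end=c.length,
                         mcf={"P1": 10.0})
        assert classify_scope(ev, genome) == "chromosome_arm"

    def test_segmental_and_point(self, genome):
        ev = make_record("a", chrom="17", start=30 * MB, end=35 * MB,
                         mcf={"P1": 10.0})
        assert classify_scope(ev, genome) == "segmental"
        snv = make_record("s", chrom="17", start=7 * MB, end=7 * MB,
                          alt_type="snv", mcf={"P1": 10.0})
        assert classify_scope(snv, genome) == "point"

    def test_unknown_chromosome_raises(self, genome):
        ev = make_record("a", chrom="99", mcf={"P1": 10.0})
        with pytest.raises(KeyError):
            classify_scope(ev, genome)


def test_unique_event_mcf_matrix_absent_is_zero():
    recs = [
        make_record("a", mcf={"P1": 50.0}),
        make_record("b", chrom="2", mcf={"P2": 30.0}),
    ]
    cat = unify_events(recs)
    T = build_mcf_matrix(cat, ["P1", "P2"])
    assert T.row("a")[1] == 0.0 and T.row("b")[0] == 0.0
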