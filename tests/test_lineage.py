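import itertools

import numpy as np
import pytest

from kinclock.lineage import (
    CellRecord,
    Epoch,
    Fate,
    LineageError,
    LineageForest,
    Relation,
    epoch_of,
    extract_pairs,
    kinship_distance,
    read_lineage_table,
    write_lineage_table,
)


def _full_binary_forest(depth: int, imt: float = 10.0) -> LineageForest:
    """Complete binary tree of the given depth, every internal cell divided."""
    cells = {}

    def grow(cid, mother, birth, d):
        fate = Fate.DIVIDED if d < depth else Fate.CENSORED
        end = birth + imt
        cells[cid] = CellRecord(cid, mother, birth, end, fate)
        if d < depth:
            for tag in "ab":
                grow(cid + tag, cid, end, d + 1)

    grow("r", None, 0.0, 0)
    return LineageForest(cells=cells, T_d=None,
                         T_end=(depth + 1) * imt).with_generations()


def _brute_force_distance(forest, a, b):
    """Independent kinship oracle: explicit ancestor-chain intersection."""
    ca = [a] + forest.ancestors(a)
    cb = [b] + forest.ancestors(b)
    for i, x in enumerate(ca):
        for j, y in enumerate(cb):
            if x == y:
                return i if i == j else None
    return None


class TestEpochClassification:
    @pytest.mark.parametrize(
        "birth,end,expected",
        [
            (10.0, 40.0, Epoch.PRE),
            (40.0, 60.0, Epoch.STRADDLE),
            (50.0, 70.0, Epoch.POST),   # birth exactly at T_d counts as POST
            (30.0, 50.0, Epoch.PRE),    # end exactly at T_d counts as PRE
        ],
    )
    def test_boundaries(self, birth, end, expected):
        cell = CellRecord("c", None, birth, end, Fate.DIVIDED)
        assert epoch_of(cell, 50.0) is expected

    def test_partition_exhaustive_and_exclusive(self, rng):
        for _ in range(200):
            b = rng.uniform(0, 100)
            e = b + rng.uniform(0, 50)
            cell = CellRecord("c", None, b, e, Fate.DIVIDED)
            assert epoch_of(cell, 50.0) in (Epoch.PRE, Epoch.STRADDLE, Epoch.POST)


class TestKinship:
    def test_named_relations(self, tiny_forest):
        assert kinship_distance(tiny_forest, "f0a", "f0b") == 1
        assert kinship_distance(tiny_forest, "f0aa", "f0ab") == 1
        assert kinship_distance(tiny_forest, "f0aa", "f0ba") == 2
        # aunt-niece is not a symmetric relation
        assert kinship_distance(tiny_forest, "f0a", "f0bb") is None

    def test_unknown_id_raises(self, tiny_forest):
        with pytest.raises(LineageError):
            kinship_distance(tiny_forest, "f0", "nope")

    def test_different_founders_unrelated(self):
        cells = {
            "x": CellRecord("x", None, 0.0, 10.0, Fate.CENSORED),
            "y": CellRecord("y", None, 0.0, 10.0, Fate.CENSORED),
        }
        forest = LineageForest(cells=cells, T_end=10.0)
        assert kinship_distance(forest, "x", "y") is None

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_matches_brute_force_on_full_tree(self, depth):
        forest = _full_binary_forest(depth)
        ids = sorted(forest.cells)
        for a, b in itertools.combinations(ids, 2):
            assert kinship_distance(forest, a, b) == _brute_force_distance(forest, a, b)


class TestExtractPairs:
    def test_two_generation_tree_counts(self):
        forest = _full_binary_forest(1)
        # all three cells divided would be needed for MD pairs; leaves censored
        forest2 = _full_binary_forest(2)
        sisters = extract_pairs(forest2, Relation.SISTER, event_filter=Fate.DIVIDED)
        md = extract_pairs(forest2, Relation.MOTHER_DAUGHTER, event_filter=Fate.DIVIDED)
        assert len(sisters) == 1          # the two divided gen-1 cells
        assert len(md) == 2               # root with each divided daughter
        del forest

    def test_cousin_pairs_among_grandchildren(self):
        forest = _full_binary_forest(2)
        cousins = extract_pairs(forest, Relation.COUSIN)
        assert len(cousins) == 4

    @pytest.mark.parametrize("depth", [3, 4])
    def test_counts_match_brute_force(self, depth):
        forest = _full_binary_forest(depth)
        ids = sorted(forest.cells)
        for rel, k in [(Relation.SISTER, 1), (Relation.COUSIN, 2),
                       (Relation.SECOND_COUSIN, 3)]:
            expected = sum(
                1 for a, b in itertools.combinations(ids, 2)
                if _brute_force_distance(forest, a, b) == k
            )
            assert len(extract_pairs(forest, rel)) == expected

    def test_mother_daughter_requires_divided_mother(self):
        cells = {
            "m": CellRecord("m", None, 0.0, 10.0, Fate.DIED),
        }
        forest = LineageForest(cells=cells, T_end=10.0)
        assert extract_pairs(forest, Relation.MOTHER_DAUGHTER) == []

    def test_event_filter_both_members(self, tiny_forest):
        both_div = extract_pairs(tiny_forest, Relation.SISTER, event_filter=Fate.DIVIDED)
        ids = {(p.id1, p.id2) for p in both_div}
        assert ("f0a", "f0b") in ids and ("f0aa", "f0ab") in ids
        assert all(p.e1 is Fate.DIVIDED and p.e2 is Fate.DIVIDED for p in both_div)


class TestTableIO:
    def test_round_trip_identity(self, fixture_suite, tmp_path):
        out_dir, _ = fixture_suite
        forest = read_lineage_table(out_dir / "cisplatin.csv", T_d=50.0, T_end=122.0)
        copy = tmp_path / "copy.csv"
        write_lineage_table(forest, copy)
        assert copy.read_bytes() == (out_dir / "cisplatin.csv").read_bytes()
        forest2 = read_lineage_table(copy, T_d=50.0, T_end=122.0)
        assert forest2.cells == forest.cells

    def test_minimal_tree(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "cell_id,mother_id,birth_time,end_time,fate\n"
            "a,,0,16,divided\n"
            "aa,a,16,30,censored\n"
            "ab,a,16,30,censored\n"
        )
        forest = read_lineage_table(p, T_d=50.0, T_end=30.0)
        assert len(forest) == 3
        assert len(extract_pairs(forest, Relation.SISTER)) == 1

    def test_self_mother_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,mother_id,birth_time,end_time,fate\na,a,0,16,divided\n")
        with pytest.raises(LineageError):
            read_lineage_table(p)

    def test_unknown_fate_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,mother_id,birth_time,end_time,fate\na,,0,16,vanished\n")
        with pytest.raises(LineageError):
            read_lineage_table(p)

    def test_stitching_tolerance(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cell_id,mother_id,birth_time,end_time,fate\n"
            "a,,0,16,divided\n"
            "aa,a,17.2,30,censored\n"   # 1.2 h gap > one frame
            "ab,a,16,30,censored\n"
        )
        with pytest.raises(LineageError, match="aa"):
            read_lineage_table(p)

    def test_empty_forest_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_lineage_table(LineageForest(cells={}), p)
        assert p.read_text().startswith("cell_id,mother_id")
        assert len(read_lineage_table(p)) == 0

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,mom,b,e,outcome\na,,0,16,divided\n")
        forest = read_lineage_table(
            p, column_map={"id": "cell_id", "mom": "mother_id", "b": "birth_time",
                           "e": "end_time", "outcome": "fate"})
        assert "a" in forest.cells
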