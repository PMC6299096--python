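"""Lineage forests: the data model for single-cell fate-timing experiments.

A *forest* is a set of cell lineage trees tracked by time-lapse microscopy.
Each cell is a record with a birth time, an end time, and a terminal fate:
it divided into two daughters, it died, or it was still alive when
observation ended (right-censored).  The experiment has two epochs separated
by a drug-administration time ``T_d``: events ending at or before ``T_d``
are PRE, events starting before and ending after straddle the boundary, and
events starting at or after ``T_d`` are POST.

Kinship is counted as the number of divisions separating two same-generation
relatives from their most recent common ancestor: sisters are 1 apart,
first cousins 2, second cousins 3, third cousins 4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Fate",
    "Epoch",
    "Relation",
    "CellRecord",
    "LineageForest",
    "PairObservation",
    "LineageError",
    "read_lineage_table",
    "write_lineage_table",
    "epoch_of",
    "kinship_distance",
    "extract_pairs",
    "STITCH_TOLERANCE_H",
]

# One imaging frame (30-minute acquisition interval): tolerance for
# mother-end / daughter-birth time stitching.
STITCH_TOLERANCE_H = 0.5


class Fate(str, enum.Enum):
    DIVIDED = "divided"
    DIED = "died"
    CENSORED = "censored"


class Epoch(str, enum.Enum):
    PRE = "pre"
    STRADDLE = "straddle"
    POST = "post"


class Relation(str, enum.Enum):
    SISTER = "sister"
    MOTHER_DAUGHTER = "mother_daughter"
    COUSIN = "cousin"
    SECOND_COUSIN = "second_cousin"
    THIRD_COUSIN = "third_cousin"
    UNRELATED = "unrelated"


#: kinship distance (divisions from the MRCA) for each symmetric relation
RELATION_DISTANCE = {
    Relation.SISTER: 1,
    Relation.COUSIN: 2,
    Relation.SECOND_COUSIN: 3,
    Relation.THIRD_COUSIN: 4,
}


class LineageError(ValueError):
    """Structural or validation error in a lineage table."""


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    mother_id: str | None
    birth_time: float
    end_time: float
    fate: Fate
    position: tuple[float, float] | None = None
    generation: int = 0

    @property
    def lifetime(self) -> float:
        return self.end_time - self.birth_time


@dataclass
class LineageForest:
    cells: dict[str, CellRecord]
    T_d: float | None = None
    T_end: float | None = None
    _daughters: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._daughters = {}
        for c in self.cells.values():
            if c.mother_id is not None:
                self._daughters.setdefault(c.mother_id, []).append(c.cell_id)
        for v in self._daughters.values():
            v.sort()

    def __len__(self) -> int:
        return len(self.cells)

    def daughters(self, cell_id: str) -> list[str]:
        return self._daughters.get(cell_id, [])

    def founders(self) -> list[str]:
        return [c.cell_id for c in self.cells.values() if c.mother_id is None]

    def validate(self) -> None:
        """Check all forest invariants; raise LineageError on violation."""
        for c in self.cells.values():
            if c.end_time < c.birth_time:
                raise LineageError(f"cell {c.cell_id}: end_time < birth_time")
            if c.mother_id is not None:
                if c.mother_id not in self.cells:
                    raise LineageError(f"cell {c.cell_id}: unknown mother {c.mother_id}")
                m = self.cells[c.mother_id]
                if abs(c.birth_time - m.end_time) > STITCH_TOLERANCE_H:
                    raise LineageError(
                        f"cell {c.cell_id}: birth {c.birth_time} != mother "
                        f"{c.mother_id} end {m.end_time} beyond {STITCH_TOLERANCE_H} h"
                    )
                if m.fate is not Fate.DIVIDED:
                    raise LineageError(
                        f"cell {c.cell_id}: mother {c.mother_id} has fate {m.fate.value}"
                    )
        # acyclicity: walk each cell to a founder, bounded by forest size
        n = len(self.cells)
        for c in self.cells.values():
            seen = 0
            cur: str | None = c.cell_id
            while cur is not None:
                seen += 1
                if seen > n:
                    raise LineageError(f"cycle in mother links at cell {c.cell_id}")
                cur = self.cells[cur].mother_id
        for mid, ds in self._daughters.items():
            if len(ds) > 2:
                raise LineageError(f"cell {mid} has {len(ds)} daughters")
        if self.T_end is not None:
            late = [c.cell_id for c in self.cells.values() if c.end_time > self.T_end + 1e-9]
            if late:
                raise LineageError(f"cells end after T_end: {late[:5]}")

    def ancestors(self, cell_id: str) -> list[str]:
        """Chain of ancestor ids, nearest first (mother, grandmother, ...)."""
        out = []
        cur = self.cells[cell_id].mother_id
        while cur is not None:
            out.append(cur)
            cur = self.cells[cur].mother_id
        return out

    def with_generations(self) -> "LineageForest":
        """Return a copy with generation numbers recomputed from the links."""
        gen: dict[str, int] = {}

        def g(cid: str) -> int:
            if cid not in gen:
                m = self.cells[cid].mother_id
                gen[cid] = 0 if m is None else g(m) + 1
            return gen[cid]

        cells = {cid: replace(c, generation=g(cid)) for cid, c in self.cells.items()}
        return LineageForest(cells=cells, T_d=self.T_d, T_end=self.T_end)


@dataclass(frozen=True)
class PairObservation:
    """Lifetimes and fates of one related-cell pair.

    ``entry1`` / ``entry2`` are delayed-entry ages: a cell only observed
    under the current regime from that age onward (a drug-epoch boundary
    crossing, or a founder already alive when imaging starts) contributes
    to likelihoods conditionally on having survived to its entry age.
    """

    t1: float
    t2: float
    e1: Fate
    e2: Fate
    relation: Relation
    epoch: Epoch | None = None
    id1: str | None = None
    id2: str | None = None
    entry1: float = 0.0
    entry2: float = 0.0


def epoch_of(cell: CellRecord, T_d: float) -> Epoch:
    """Classify a cell's lifetime relative to drug administration.

    Boundary convention: end exactly at T_d is PRE; birth exactly at T_d
    is POST.
    """
    if cell.end_time <= T_d:
        return Epoch.PRE
    if cell.birth_time >= T_d:
        return Epoch.POST
    return Epoch.STRADDLE


def kinship_distance(forest: LineageForest, id_a: str, id_b: str) -> int | None:
    """Divisions separating two same-generation relatives from their MRCA.

    Returns ``None`` if the cells share no common ancestor or sit at unequal
    depths below the MRCA (e.g. aunt-niece); such pairs are treated as
    outside the symmetric relation classes.
    """
    if id_a not in forest.cells or id_b not in forest.cells:
        raise LineageError(f"unknown cell id: {id_a if id_a not in forest.cells else id_b}")
    if id_a == id_b:
        return 0
    chain_a = [id_a] + forest.ancestors(id_a)
    chain_b = [id_b] + forest.ancestors(id_b)
    set_b = {cid: i for i, cid in enumerate(chain_b)}
    for i, cid in enumerate(chain_a):
        if cid in set_b:
            j = set_b[cid]
            if i != j:
                return None
            return i
    return None


def _relation_of_distance(d: int | None) -> Relation:
    for rel, dd in RELATION_DISTANCE.items():
        if d == dd:
            return rel
    return Relation.UNRELATED


def _pair_epoch(a: CellRecord, b: CellRecord, T_d: float | None) -> Epoch | None:
    if T_d is None:
        return None
    ea, eb = epoch_of(a, T_d), epoch_of(b, T_d)
    if ea == eb:
        return ea
    return Epoch.STRADDLE


def extract_pairs(
    forest: LineageForest,
    relation: Relation,
    epoch: Epoch | None = None,
    event_filter: tuple[Fate, Fate] | Fate | None = None,
) -> list[PairObservation]:
    """All unordered pairs at the requested kinship, filtered by epoch/fate.

    ``event_filter`` of a single :class:`Fate` requires both members to have
    that fate (e.g. both DIVIDED for IMT pairs, both DIED for AT pairs); a
    tuple requires the two fates in either order; ``None`` keeps all pairs.
    Mother-daughter pairs pair the mother's lifetime with each daughter's;
    they require the mother to have divided (a dying cell has no daughters)
    and apply the filter/epoch to the daughter's fate and to both epochs.
    """
    T_d = forest.T_d

    def fate_ok(ea: Fate, eb: Fate) -> bool:
        if event_filter is None:
            return True
        if isinstance(event_filter, Fate):
            return ea is event_filter and eb is event_filter
        fa, fb = event_filter
        return (ea is fa and eb is fb) or (ea is fb and eb is fa)

    out: list[PairObservation] = []
    if relation is Relation.MOTHER_DAUGHTER:
        for mid, ds in forest._daughters.items():
            m = forest.cells[mid]
            if m.fate is not Fate.DIVIDED:
                continue
            for did in ds:
                d = forest.cells[did]
                if event_filter is not None and not fate_ok(Fate.DIVIDED, d.fate):
                    continue
                ep = _pair_epoch(m, d, T_d)
                if epoch is not None and ep is not epoch:
                    continue
                out.append(
                    PairObservation(m.lifetime, d.lifetime, m.fate, d.fate,
                                    relation, ep, mid, did)
                )
        return out

    if relation is Relation.UNRELATED:
        ids = sorted(forest.cells)
        for i, ia in enumerate(ids):
            for ib in ids[i + 1:]:
                if kinship_distance(forest, ia, ib) is not None:
                    continue
                a, b = forest.cells[ia], forest.cells[ib]
                if not fate_ok(a.fate, b.fate):
                    continue
                ep = _pair_epoch(a, b, T_d)
                if epoch is not None and ep is not epoch:
                    continue
                out.append(PairObservation(a.lifetime, b.lifetime, a.fate, b.fate,
                                           relation, ep, ia, ib))
        return out

    target = RELATION_DISTANCE[relation]
    for ia, ib in _id_pairs_at_distance(forest, target):
        a, b = forest.cells[ia], forest.cells[ib]
        if not fate_ok(a.fate, b.fate):
            continue
        ep = _pair_epoch(a, b, T_d)
        if epoch is not None and ep is not epoch:
            continue
        out.append(PairObservation(a.lifetime, b.lifetime, a.fate, b.fate,
                                   relation, ep, ia, ib))
    return out


def _id_pairs_at_distance(forest: LineageForest, k: int):
    """All unordered id pairs exactly k divisions below their MRCA.

    Cells are grouped by their k-th ancestor; within a group, two cells are
    k-distant relatives iff their (k-1)-th ancestors differ (otherwise the
    MRCA is closer).  Linear in cells + emitted pairs, unlike the naive
    all-pairs kinship scan.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    for cid in sorted(forest.cells):
        chain = forest.ancestors(cid)
        if len(chain) < k:
            continue
        anc_k = chain[k - 1]
        branch = chain[k - 2] if k >= 2 else cid
        groups.setdefault(anc_k, []).append((branch, cid))
    for members in groups.values():
        for i, (br_a, ia) in enumerate(members):
            for br_b, ib in members[i + 1:]:
                if br_a != br_b:
                    yield (ia, ib) if ia < ib else (ib, ia)


_COLUMNS = ["cell_id", "mother_id", "birth_time", "end_time", "fate", "pos_x", "pos_y"]


def read_lineage_table(
    path,
    T_d: float | None = None,
    T_end: float | None = None,
    column_map: dict[str, str] | None = None,
) -> LineageForest:
    """Read a comma-separated lineage table into a validated forest.

    Required header columns: cell_id, mother_id (empty for founders),
    birth_time, end_time (hours), fate in {divided, died, censored};
    optional pos_x, pos_y (µm).  ``column_map`` renames caller columns to
    this layout, e.g. ``{"id": "cell_id"}``.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise LineageError(f"missing columns: {missing}")
    cells: dict[str, CellRecord] = {}
    for row in df.itertuples(index=False):
        cid = str(row.cell_id)
        mid = None if pd.isna(row.mother_id) or str(row.mother_id) == "" else str(row.mother_id)
        if mid == cid:
            raise LineageError(f"cell {cid} is its own mother")
        try:
            fate = Fate(str(row.fate).strip().lower())
        except ValueError:
            raise LineageError(f"cell {cid}: unknown fate {row.fate!r}") from None
        pos = None
        if "pos_x" in df.columns and "pos_y" in df.columns:
            if not (pd.isna(row.pos_x) or pd.isna(row.pos_y)):
                pos = (float(row.pos_x), float(row.pos_y))
        if cid in cells:
            raise LineageError(f"duplicate cell id {cid}")
        cells[cid] = CellRecord(cid, mid, float(row.birth_time), float(row.end_time), fate, pos)
    forest = LineageForest(cells=cells, T_d=T_d, T_end=T_end).with_generations()
    forest.validate()
    return forest


def write_lineage_table(forest: LineageForest, path) -> None:
    """Write a forest as CSV; ``read_lineage_table`` round-trips it exactly."""
    rows = []
    for cid in sorted(forest.cells):
        c = forest.cells[cid]
        rows.append(
            {
                "cell_id": c.cell_id,
                "mother_id": "" if c.mother_id is None else c.mother_id,
                "birth_time": repr(c.birth_time),
                "end_time": repr(c.end_time),
                "fate": c.fate.value,
                "pos_x": "" if c.position is None else repr(c.position[0]),
                "pos_y": "" if c.position is None else repr(c.position[1]),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(Path(path), index=False)
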