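"""Set partitions of a subtype alphabet and their merge/split lattice.

A *compound subtype* is a nonempty union of elementary subtype labels; a
*partition* divides the elementary set into disjoint covering compound
subtypes. One predictor is trained per part, so the set of all partitions —
``Bell(k)`` of them for ``k`` elementary subtypes — indexes the full sweep
from fully stratified (one part per subtype) down to a single untyped pool.
Partitions are connected into a Hasse diagram by single merge moves, which
is how the sweep is usually displayed.

Partitions are represented as ``frozenset`` of ``frozenset`` of labels, so
they hash and compare structurally; human-readable labels (``"La.Lb|H|B"``)
are bijective with partitions given the canonical elementary order.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

CompoundSubtype = frozenset  # frozenset[str]
Partition = frozenset        # frozenset[CompoundSubtype]

#: Short names used in partition labels, after the common breast-cancer set.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "lumA": "La",
    "lumB": "Lb",
    "Her2": "H",
    "basal": "B",
}

#: Enumeration guard: Bell(8) = 4140 partitions is the largest sweep that
#: stays desk-scale; raise the cap explicitly for bigger alphabets.
DEFAULT_MAX_SUBTYPES = 8

PART_SEPARATOR = "|"
MEMBER_SEPARATOR = "."


class ElementarySubtypeSet:
    """Ordered alphabet of distinct elementary subtype labels.

    The construction order is the canonical order used for naming parts and
    partitions; it never changes after construction.
    """

    def __init__(self, labels: Sequence[str]):
        labels = list(labels)
        if not labels:
            raise ValueError("empty subtype set")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate subtype labels in {labels!r}")
        self._labels = tuple(labels)
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def index(self, label: str) -> int:
        return self._index[label]

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementarySubtypeSet) and other._labels == self._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:
        return f"ElementarySubtypeSet({list(self._labels)!r})"


def bell_number(k: int) -> int:
    """Number of set partitions of ``k`` elements (Bell triangle recurrence)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    row = [1]
    for _ in range(k):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def enumerate_compound_subtypes(subtypes: ElementarySubtypeSet) -> set[CompoundSubtype]:
    """All ``2^k - 1`` nonempty subsets of the elementary set."""
    labels = subtypes.labels
    out: set[CompoundSubtype] = set()
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            out.add(frozenset(combo))
    return out


def _partitions_of(items: tuple[str, ...]) -> Iterator[list[list[str]]]:
    # Recursive "first element joins an existing block or opens a new one".
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for smaller in _partitions_of(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def enumerate_partitions(
    subtypes: ElementarySubtypeSet, max_subtypes: int = DEFAULT_MAX_SUBTYPES
) -> list[Partition]:
    """All distinct set partitions of the elementary set, ``Bell(k)`` of them.

    Returned in a deterministic order: by part count ascending (coarse to
    fine), then lexicographically by canonical label.
    """
    k = len(subtypes)
    if k > max_subtypes:
        raise ValueError(
            f"{k} elementary subtypes exceeds the enumeration cap of {max_subtypes}; "
            "pass a larger max_subtypes explicitly"
        )
    parts = [
        frozenset(frozenset(block) for block in p) for p in _partitions_of(subtypes.labels)
    ]
    uniq = set(parts)
    abbrev = abbreviations_for(subtypes)
    return sorted(uniq, key=lambda p: (len(p), partition_label(p, subtypes, abbrev)))


def merge_parts(partition: Partition, a: CompoundSubtype, b: CompoundSubtype) -> Partition:
    """Coarsen ``partition`` by merging two of its parts."""
    if a not in partition or b not in partition or a == b:
        raise ValueError("a and b must be two distinct parts of the partition")
    return frozenset((partition - {a, b}) | {a | b})


def hasse_edges(partitions: Sequence[Partition]) -> list[tuple[Partition, Partition]]:
    """Covering relation of the refinement order: (finer, coarser) pairs.

    ``coarser`` arises from ``finer`` by merging exactly two parts, so a node
    with ``p`` parts has ``p*(p-1)/2`` outgoing (coarsening) edges. The input
    must be the complete partition set of one elementary alphabet.
    """
    if not partitions:
        raise ValueError("empty partition list")
    universe = frozenset().union(*partitions[0])
    for p in partitions:
        if frozenset().union(*p) != universe:
            raise ValueError("partitions do not share one elementary set")
    if len(set(partitions)) != bell_number(len(universe)):
        raise ValueError(
            f"incomplete partition list: expected Bell({len(universe)}) = "
            f"{bell_number(len(universe))}, got {len(set(partitions))}"
        )
    node_set = set(partitions)
    edges: list[tuple[Partition, Partition]] = []
    for finer in partitions:
        for a, b in combinations(sorted(finer, key=sorted), 2):
            coarser = merge_parts(finer, a, b)
            assert coarser in node_set
            edges.append((finer, coarser))
    return edges


def refines(finer: Partition, coarser: Partition) -> bool:
    """True when every part of ``finer`` is contained in a part of ``coarser``."""
    return all(any(part <= cpart for cpart in coarser) for part in finer)


def abbreviations_for(
    subtypes: Iterable[str], abbrev: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Abbreviation map covering ``subtypes``: defaults where known, identity otherwise."""
    base = dict(DEFAULT_ABBREVIATIONS if abbrev is None else abbrev)
    for lab in subtypes:
        base.setdefault(lab, lab)
    return base


def _require_abbrev(labels: Iterable[str], abbrev: Mapping[str, str]) -> None:
    missing = [lab for lab in labels if lab not in abbrev]
    if missing:
        raise KeyError(f"no abbreviation for subtype label(s) {missing}")


def part_label(
    part: CompoundSubtype,
    subtypes: ElementarySubtypeSet,
    abbrev: Mapping[str, str] | None = None,
) -> str:
    """Dot-joined short names of a compound subtype, in canonical order."""
    abbrev = DEFAULT_ABBREVIATIONS if abbrev is None else abbrev
    members = sorted(part, key=subtypes.index)
    _require_abbrev(members, abbrev)
    return MEMBER_SEPARATOR.join(abbrev[m] for m in members)


def partition_label(
    partition: Partition,
    subtypes: ElementarySubtypeSet,
    abbrev: Mapping[str, str] | None = None,
) -> str:
    """Canonical string form of a partition, e.g. ``"La.Lb|H|B"``.

    Members within a part follow the elementary order; parts are ordered by
    the position of their earliest member. The mapping partition <-> label is
    bijective for a fixed alphabet and abbreviation map.
    """
    ordered = sorted(partition, key=lambda part: min(subtypes.index(m) for m in part))
    return PART_SEPARATOR.join(part_label(p, subtypes, abbrev) for p in ordered)


def parse_partition_label(
    label: str,
    subtypes: ElementarySubtypeSet,
    abbrev: Mapping[str, str] | None = None,
) -> Partition:
    """Inverse of :func:`partition_label`; validates disjoint cover."""
    abbrev = DEFAULT_ABBREVIATIONS if abbrev is None else abbrev
    _require_abbrev(subtypes, abbrev)
    reverse = {short: full for full, short in abbrev.items()}
    parts = []
    seen: set[str] = set()
    for chunk in label.split(PART_SEPARATOR):
        members = []
        for short in chunk.split(MEMBER_SEPARATOR):
            if short not in reverse:
                raise ValueError(f"unknown abbreviation {short!r} in {label!r}")
            full = reverse[short]
            if full not in subtypes:
                raise ValueError(f"label {full!r} not in the elementary set")
            if full in seen:
                raise ValueError(f"duplicate member {full!r} in {label!r}")
            seen.add(full)
            members.append(full)
        parts.append(frozenset(members))
    if seen != set(subtypes.labels):
        raise ValueError(f"{label!r} does not cover the elementary set")
    return frozenset(parts)


def coarsest_partition(subtypes: ElementarySubtypeSet) -> Partition:
    """Single-part partition: the untyped/baseline pool."""
    return frozenset({frozenset(subtypes.labels)})


def finest_partition(subtypes: ElementarySubtypeSet) -> Partition:
    """One part per elementary subtype: full stratification."""
    return frozenset(frozenset({lab}) for lab in subtypes.labels)


def edge_list_frame(partitions: Sequence[Partition], subtypes: ElementarySubtypeSet,
                    abbrev: Mapping[str, str] | None = None):
    """Hasse edges as a two-column DataFrame (finer_label, coarser_label)."""
    import pandas as pd

    rows = [
        {
            "finer_label": partition_label(f, subtypes, abbrev),
            "coarser_label": partition_label(c, subtypes, abbrev),
        }
        for f, c in hasse_edges(list(partitions))
    ]
    return pd.DataFrame(rows, columns=["finer_label", "coarser_label"])
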