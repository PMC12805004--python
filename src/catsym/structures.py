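"""Finite domain structures: spaces, transformations, and their groups.

A *structure* is a finite point space together with a set of generating
transformations of that space.  Four canonical kinds cover the semantic
domains analysed elsewhere in the package:

``linear``
    A one-dimensional continuum with no distinguished interior point
    (e.g. a scale of life forms), discretized as an even number of cells.
    Its single generator is the end-to-end reversal, so the group is the
    dihedral group of order 2 (equivalently the cyclic group Z2).
``bisected_linear``
    A one-dimensional continuum with a privileged central point that any
    category system must cover (e.g. days around "today", or tenses around
    the present).  Discretized with an odd number of cells so the centre is
    a real sample point; generator is the reversal fixing the centre.
``bisected_circular``
    A cycle with a privileged axis (e.g. the seasonal cycle anchored at the
    solstices, or cardinal directions anchored east-west).  Generators are
    the reflection in the privileged axis and rotation by half a turn; the
    group is the dihedral group of order 4.
``binary_feature``
    A disconnected space of 2**k feature bundles (e.g. sibling kin types
    classified by sex and relative age); one value-swap generator per
    feature, giving a group of order 2**k.

Sample points of the circular (and linear) spaces sit at cell midpoints,
i.e. at angles (i + 1/2)/n turns: no sample point lies on the privileged
axis or on its perpendicular.  The two privileged circular anchors are kept
as *edge markers* on the axis (angles 0 and 1/2) rather than sample points;
if the axis were sampled, the relational symmetry test would spuriously
forbid the two-category summer/winter split that the underlying continuum
clearly admits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "Point",
    "Space",
    "Transformation",
    "TransformationGroup",
    "Structure",
    "GroupClosureError",
    "identity",
    "compose",
    "generate_group",
    "make_structure",
    "structure_from_json",
    "STRUCTURE_KINDS",
]

STRUCTURE_KINDS = (
    "linear",
    "bisected_linear",
    "bisected_circular",
    "binary_feature",
    "custom",
)

DEFAULT_CLOSURE_CAP = 10_000


class GroupClosureError(RuntimeError):
    """Closure under composition exceeded the configured element cap."""


@dataclass(frozen=True)
class Point:
    """One sample point of a finite space.

    ``coord`` is a :class:`~fractions.Fraction` (position on the unit
    interval, or turns around the circle) or a tuple of bits for feature
    spaces.  ``privileged`` marks a point that every category system must
    assign (the centre of a bisected linear space).
    """

    index: int
    coord: object
    privileged: bool = False


@dataclass(frozen=True)
class Space:
    """A finite point set with a symmetric adjacency relation.

    ``topology`` is one of ``interval``, ``cycle``, ``feature`` or
    ``custom``; adjacency is empty for feature spaces (they are
    disconnected by design).  ``marker_angles`` holds privileged edge
    markers of a bisected circle (angles in turns); they are annotations on
    the continuum, not sample points.
    """

    points: tuple[Point, ...]
    topology: str
    adjacency: frozenset[tuple[int, int]]
    marker_angles: tuple[Fraction, ...] = ()

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def privileged_indices(self) -> frozenset[int]:
        return frozenset(p.index for p in self.points if p.privileged)

    def neighbors(self, i: int) -> frozenset[int]:
        out = set()
        for a, b in self.adjacency:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return frozenset(out)


@dataclass(frozen=True, eq=False)
class Transformation:
    """A bijection of point indices, stored as an index array.

    ``mapping[i]`` is the image of point ``i``.  Equality and hashing use
    the mapping only; labels are bookkeeping.
    """

    mapping: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.mapping)
        if sorted(self.mapping) != list(range(n)):
            raise ValueError(
                f"transformation mapping is not a bijection of 0..{n - 1}: "
                f"{self.mapping!r}"
            )

    def __call__(self, i: int) -> int:
        return self.mapping[i]

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Transformation):
            return NotImplemented
        return self.mapping == other.mapping

    def __hash__(self) -> int:
        return hash(self.mapping)

    def inverse(self) -> "Transformation":
        inv = [0] * len(self.mapping)
        for i, j in enumerate(self.mapping):
            inv[j] = i
        return Transformation(tuple(inv), label=f"inv({self.label})")


def identity(n: int) -> Transformation:
    return Transformation(tuple(range(n)), label="identity")


def compose(a: Transformation, b: Transformation) -> Transformation:
    """Composition a∘b: apply ``b`` first, then ``a`` (right-to-left)."""
    if len(a) != len(b):
        raise ValueError("cannot compose transformations of different degree")
    label = f"{a.label}∘{b.label}" if a.label and b.label else ""
    return Transformation(tuple(a.mapping[j] for j in b.mapping), label=label)


@dataclass(frozen=True)
class TransformationGroup:
    """Closure of a generator set under composition; always contains the
    identity, and (being finite) every inverse."""

    elements: tuple[Transformation, ...]
    generators: tuple[Transformation, ...]
    degree: int

    @property
    def order(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, t: Transformation) -> bool:
        return t in set(self.elements)


def generate_group(
    generators: Iterable[Transformation],
    n: int,
    cap: int = DEFAULT_CLOSURE_CAP,
) -> TransformationGroup:
    """Close a generator set under composition (breadth-first orbit of the
    identity).  ``cap`` guards against malformed custom structures whose
    closure would blow up; the cap is on the number of distinct elements.
    """
    gens = tuple(generators)
    for g in gens:
        if len(g) != n:
            raise ValueError(
                f"generator degree {len(g)} does not match space size {n}"
            )
    ident = identity(n)
    seen: dict[tuple[int, ...], Transformation] = {ident.mapping: ident}
    frontier = [ident]
    while frontier:
        new_frontier = []
        for e in frontier:
            for g in gens:
                ne = compose(g, e)
                if ne.mapping not in seen:
                    seen[ne.mapping] = ne
                    new_frontier.append(ne)
                    if len(seen) > cap:
                        raise GroupClosureError(
                            f"group closure exceeded cap of {cap} elements"
                        )
        frontier = new_frontier
    elements = tuple(sorted(seen.values(), key=lambda t: t.mapping))
    return TransformationGroup(elements=elements, generators=gens, degree=n)


@dataclass(frozen=True)
class Structure:
    """A space together with the group generated by its transformations."""

    space: Space
    group: TransformationGroup
    kind: str
    resolution: int

    @property
    def n(self) -> int:
        return self.space.n


def _validate_structure(struct: Structure) -> None:
    """Every group element must preserve adjacency and fix the privileged
    point set (setwise)."""
    adj = struct.space.adjacency
    priv = struct.space.privileged_indices
    for t in struct.group:
        for a, b in adj:
            ia, ib = t(a), t(b)
            if (min(ia, ib), max(ia, ib)) not in adj:
                raise ValueError(
                    f"transformation {t.label or t.mapping} does not preserve "
                    f"adjacency: edge ({a},{b}) maps to non-edge ({ia},{ib})"
                )
        if frozenset(t(i) for i in priv) != priv:
            raise ValueError(
                f"transformation {t.label or t.mapping} moves the privileged "
                "point set"
            )


def _path_adjacency(n: int) -> frozenset[tuple[int, int]]:
    return frozenset((i, i + 1) for i in range(n - 1))


def _cycle_adjacency(n: int) -> frozenset[tuple[int, int]]:
    return frozenset(
        (min(i, (i + 1) % n), max(i, (i + 1) % n)) for i in range(n)
    )


def _midpoints(n: int) -> list[Fraction]:
    return [Fraction(2 * i + 1, 2 * n) for i in range(n)]


def make_structure(
    kind: str, size: int, *, closure_cap: int = DEFAULT_CLOSURE_CAP
) -> Structure:
    """Build one of the canonical structures at the given resolution.

    Size constraints encode the discretization conventions: a linear space
    uses even ``size`` so no accidental centre point appears, a bisected
    linear space uses odd ``size`` so the centre is a sample point, a
    bisected circle uses even ``size`` >= 4 so the half-turn is defined and
    no sample point falls on the axis, and a feature space takes the number
    of binary features ``k`` (1..10), yielding 2**k points.
    """
    if kind == "linear":
        if size < 2 or size % 2 != 0:
            raise ValueError(
                "linear structure requires even size >= 2 (an odd size would "
                "create a privileged centre point)"
            )
        coords = _midpoints(size)
        points = tuple(Point(i, coords[i]) for i in range(size))
        space = Space(points, "interval", _path_adjacency(size))
        gens = [Transformation(tuple(size - 1 - i for i in range(size)), "reversal")]
    elif kind == "bisected_linear":
        if size < 3 or size % 2 != 1:
            raise ValueError(
                "bisected linear structure requires odd size >= 3 (an even "
                "size would destroy the privileged centre point)"
            )
        coords = _midpoints(size)
        centre = (size - 1) // 2
        points = tuple(
            Point(i, coords[i], privileged=(i == centre)) for i in range(size)
        )
        space = Space(points, "interval", _path_adjacency(size))
        gens = [Transformation(tuple(size - 1 - i for i in range(size)), "reversal")]
    elif kind == "bisected_circular":
        if size < 4 or size % 2 != 0:
            raise ValueError(
                "bisected circular structure requires even size >= 4 (the "
                "half-turn rotation must be defined and sample points must "
                "avoid the privileged axis)"
            )
        angles = _midpoints(size)
        points = tuple(Point(i, angles[i]) for i in range(size))
        markers = (Fraction(0), Fraction(1, 2))
        space = Space(points, "cycle", _cycle_adjacency(size), marker_angles=markers)
        reflection = Transformation(
            tuple(size - 1 - i for i in range(size)), "reflection-axis"
        )
        rotation = Transformation(
            tuple((i + size // 2) % size for i in range(size)), "rotation-half"
        )
        # the angle actions a -> -a and a -> a + 1/2 must fix the marker
        # pair {0, 1/2} setwise
        marker_set = set(markers)
        assert {(-m) % 1 for m in markers} == marker_set
        assert {(m + Fraction(1, 2)) % 1 for m in markers} == marker_set
        gens = [reflection, rotation]
    elif kind == "binary_feature":
        k = size
        if not 1 <= k <= 10:
            raise ValueError(
                "binary feature structure requires 1 <= k <= 10 features "
                "(2**k points grows combinatorially)"
            )
        npts = 2 ** k
        points = tuple(
            Point(i, tuple((i >> (k - 1 - j)) & 1 for j in range(k)))
            for i in range(npts)
        )
        space = Space(points, "feature", frozenset())
        gens = [
            Transformation(
                tuple(i ^ (1 << (k - 1 - j)) for i in range(npts)),
                f"swap-feature-{j}",
            )
            for j in range(k)
        ]
    else:
        raise ValueError(
            f"unknown structure kind {kind!r}; expected one of "
            f"{STRUCTURE_KINDS[:-1]} (use structure_from_json for custom "
            "structures)"
        )
    group = generate_group(gens, space.n, cap=closure_cap)
    struct = Structure(space=space, group=group, kind=kind, resolution=size)
    _validate_structure(struct)
    return struct


def structure_from_json(
    doc: str | dict, *, closure_cap: int = DEFAULT_CLOSURE_CAP
) -> Structure:
    """Build a custom structure from a JSON document (or parsed dict) with
    keys ``points`` (list of {index, coord?, privileged?}), ``adjacency``
    (list of [i, j] pairs) and ``generators`` (list of {mapping, label?}).
    """
    if isinstance(doc, str):
        doc = json.loads(doc)
    pts = sorted(doc["points"], key=lambda p: p["index"])
    indices = [p["index"] for p in pts]
    if indices != list(range(len(pts))):
        raise ValueError("point indices must be exactly 0..n-1 and unique")
    points = tuple(
        Point(p["index"], p.get("coord"), bool(p.get("privileged", False)))
        for p in pts
    )
    n = len(points)
    adjacency = frozenset(
        (min(a, b), max(a, b)) for a, b in doc.get("adjacency", [])
    )
    for a, b in adjacency:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise ValueError(f"invalid adjacency pair ({a}, {b})")
    gens = [
        Transformation(tuple(g["mapping"]), g.get("label", f"gen{i}"))
        for i, g in enumerate(doc.get("generators", []))
    ]
    space = Space(points, doc.get("topology", "custom"), adjacency)
    group = generate_group(gens, n, cap=closure_cap)
    struct = Structure(space=space, group=group, kind="custom", resolution=n)
    _validate_structure(struct)
    return struct
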