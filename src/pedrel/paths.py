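"""Connecting-path enumeration, Wright's path formula and verbal descriptions.

A *connecting path* between A and B is a common ancestor C together with two
descending, non-intersecting node paths from C to A and to B (one term of
Wright's sum; C may coincide with A or B, giving a lineal path of length 0).
Two raw paths that are identical except that their top ancestors form a
parental couple are merged into a single *full* path; the rest are *half*.

Each merged path is classified as lineal (l1 = 0 or l2 = 0), sibling
(l1 = l2 = 1), avuncular (min = 1 < max) or cousin (min > 1), with
path degree l1 + l2 - gamma (gamma = 1 for full paths), cousinship degree
min(l1, l2) - 1 and removal |l1 - l2|.  Groups of paths with the same
lengths and full/half tag are reported together as double, triple, ...
relationships in a standardized English rendering, in order of increasing
path degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .kinship import inbreeding, kinship
from .pedigree import FEMALE, MALE, Pedigree


@dataclass(frozen=True)
class ConnectingPath:
    """One (merged) term of Wright's sum.

    ``ancestors`` holds one id (half path) or the parental couple, father
    first (full path).  ``v1``/``v2`` are the nodes strictly below the
    ancestor(s) down to A resp. B (so ``l1 = len(v1)`` edge steps); empty
    for a length-0 lineal side.
    """

    ancestors: tuple[str, ...]
    v1: tuple[str, ...]
    v2: tuple[str, ...]

    @property
    def gamma(self) -> int:
        return 1 if len(self.ancestors) == 2 else 0

    @property
    def l1(self) -> int:
        return len(self.v1)

    @property
    def l2(self) -> int:
        return len(self.v2)

    def endpoint1(self) -> str:
        return self.v1[-1] if self.v1 else self.ancestors[0]

    def endpoint2(self) -> str:
        return self.v2[-1] if self.v2 else self.ancestors[0]

    def bracket(self) -> str:
        """Bracket notation, e.g. ``6-4-[2]-5-7`` or ``6-[4,5]-7``."""
        left = list(reversed(self.v1))
        right = list(self.v2)
        mid = "[" + ",".join(self.ancestors) + "]"
        return "-".join(left + [mid] + right)


@dataclass(frozen=True)
class PathClass:
    type: str           # lineal | sibling | avuncular | cousin
    path_degree: int
    cousin_degree: int | None
    removal: int


def classify(path: ConnectingPath) -> PathClass:
    """Classify one connecting path per the lineal/sibling/avuncular/cousin
    scheme."""
    l1, l2, g = path.l1, path.l2, path.gamma
    lo, hi = min(l1, l2), max(l1, l2)
    if lo == 0:
        kind = "lineal"
    elif l1 == l2 == 1:
        kind = "sibling"
    elif lo == 1:
        kind = "avuncular"
    else:
        kind = "cousin"
    return PathClass(
        type=kind,
        path_degree=l1 + l2 - g,
        cousin_degree=lo - 1 if kind == "cousin" else None,
        removal=hi - lo,
    )


def _descending_paths(ped: Pedigree, top: str, target: str) -> list[tuple[str, ...]]:
    """All node paths top -> ... -> target following parent-to-child edges."""
    if top == target:
        return [(top,)]
    out: list[tuple[str, ...]] = []
    for child in sorted(ped.children(top)):
        for tail in _descending_paths(ped, child, target):
            out.append((top,) + tail)
    return out


def raw_connecting_paths(ped: Pedigree, a: str, b: str) -> list[ConnectingPath]:
    """All unmerged (single-ancestor) connecting paths between a and b."""
    a, b = ped.resolve(a), ped.resolve(b)
    common = sorted(ped.ancestors_or_self(a) & ped.ancestors_or_self(b))
    paths: list[ConnectingPath] = []
    for c in common:
        downs_a = _descending_paths(ped, c, a)
        downs_b = _descending_paths(ped, c, b)
        for p1 in downs_a:
            for p2 in downs_b:
                if set(p1[1:]) & set(p2[1:]):
                    continue
                paths.append(ConnectingPath(ancestors=(c,), v1=p1[1:], v2=p2[1:]))
    paths.sort(key=lambda p: (p.l1 + p.l2, p.ancestors, p.v1, p.v2))
    return paths


def _merge(ped: Pedigree, raw: list[ConnectingPath]) -> list[ConnectingPath]:
    """Unify spouse-pairs of raw paths with identical continuations into
    full paths (father listed first in the ancestor couple)."""
    buckets: dict[tuple, list[ConnectingPath]] = {}
    merged: list[ConnectingPath] = []
    for p in raw:
        if p.l1 == 0 or p.l2 == 0:
            merged.append(p)  # lineal paths cannot merge
            continue
        buckets.setdefault((p.v1, p.v2), []).append(p)
    for (v1, v2), group in buckets.items():
        tops = [p.ancestors[0] for p in group]
        child = v1[0]
        m = ped.member(child)
        couple = {m.father_id, m.mother_id}
        if len(group) == 2 and set(tops) == couple:
            father = m.father_id
            mother = m.mother_id
            merged.append(ConnectingPath(ancestors=(father, mother), v1=v1, v2=v2))
        else:
            merged.extend(group)
    merged.sort(key=lambda p: (p.l1 + p.l2 - p.gamma, min(p.l1, p.l2),
                               p.ancestors, p.v1, p.v2))
    return merged


def connecting_paths(ped: Pedigree, a: str, b: str) -> list[ConnectingPath]:
    """Complete, duplicate-free list of merged connecting paths (empty when
    unrelated)."""
    return _merge(ped, raw_connecting_paths(ped, a, b))


def wright_kinship(ped: Pedigree, a: str, b: str) -> Fraction:
    """Wright's path formula: sum of (1/2)^(l1+l2+1) * (1+f_C) over raw
    (unmerged) connecting paths.  Exact; equals the recursive kinship."""
    total = Fraction(0)
    for p in raw_connecting_paths(ped, a, b):
        fc = inbreeding(ped, p.ancestors[0])
        total += Fraction(1, 2 ** (p.l1 + p.l2 + 1)) * (1 + fc)
    return total


# ---------------------------------------------------------------------------
# Verbal rendering
# ---------------------------------------------------------------------------

_MULTIPLICITY = {2: "double", 3: "triple", 4: "quadruple", 5: "quintuple",
                 6: "sextuple", 7: "septuple", 8: "octuple"}

_ORDINAL = {1: "first", 2: "second", 3: "third"}


def _ordinal(n: int) -> str:
    return _ORDINAL.get(n, f"{n}th")


def _removal_words(r: int) -> list[str]:
    if r == 0:
        return []
    if r == 1:
        return ["once", "removed"]
    if r == 2:
        return ["twice", "removed"]
    return [f"{r}", "times", "removed"]


def _lineal_word(steps: int) -> str:
    if steps == 1:
        return "parent-child"
    return "great-" * (steps - 2) + "grandparent"


def _avuncular_word(ped: Pedigree, path: ConnectingPath) -> str:
    """Sex-aware avuncular wording; falls back to 'avuncular'.  The member
    one step below the ancestors is the uncle/aunt and is named first."""
    if path.l1 == 1:
        senior, junior = path.endpoint1(), path.endpoint2()
    else:
        senior, junior = path.endpoint2(), path.endpoint1()
    s1, s2 = ped.member(senior).sex, ped.member(junior).sex
    if s1 == MALE:
        first = "uncle"
    elif s1 == FEMALE:
        first = "aunt"
    else:
        return "avuncular"
    if s2 == MALE:
        second = "nephew"
    elif s2 == FEMALE:
        second = "niece"
    else:
        return "avuncular"
    prefix = "great-" * (max(path.l1, path.l2) - 2)
    return f"{prefix}{first}-{second}"


@dataclass(frozen=True)
class DescriptionLine:
    text: str
    paths: tuple[str, ...]  # bracket notation


@dataclass(frozen=True)
class RelationshipDescription:
    lines: tuple[DescriptionLine, ...]

    def __str__(self) -> str:
        if not self.lines:
            return "Unrelated"
        return "\n".join(line.text for line in self.lines)

    def full_text(self) -> str:
        if not self.lines:
            return "Unrelated"
        out = []
        for line in self.lines:
            out.append(line.text)
            out.extend(f"  {p}" for p in line.paths)
        return "\n".join(out)


def describe(ped: Pedigree, a: str, b: str) -> RelationshipDescription:
    """Standardised verbal description of the relationship between a and b.

    Merged paths are grouped by (unordered path lengths, full/half tag);
    lines are ordered by path degree, ties broken by the shorter length.
    """
    a, b = ped.resolve(a), ped.resolve(b)
    paths = connecting_paths(ped, a, b)
    groups: dict[tuple[int, int, int], list[ConnectingPath]] = {}
    for p in paths:
        key = (min(p.l1, p.l2), max(p.l1, p.l2), p.gamma)
        groups.setdefault(key, []).append(p)

    lines: list[DescriptionLine] = []
    for (lo, hi, g), members in sorted(groups.items(),
                                       key=lambda kv: (kv[0][0] + kv[0][1] - kv[0][2],
                                                       kv[0][0])):
        count = len(members)
        cls = classify(members[0])
        words: list[str] = []
        if count >= 2:
            words.append(_MULTIPLICITY.get(count, f"{count}-fold"))
        if cls.type == "sibling":
            words += (["full", "siblings"] if g else ["half", "siblings"])
        elif cls.type == "lineal":
            words.append(_lineal_word(hi))
        elif cls.type == "avuncular":
            if g == 0:
                words.append("half")
            avunc = {_avuncular_word(ped, p) for p in members}
            words.append(avunc.pop() if len(avunc) == 1 else "avuncular")
        else:  # cousin
            if g == 0:
                words.append("half")
            words += [_ordinal(cls.cousin_degree), "cousins"]
            words += _removal_words(cls.removal)
        text = " ".join(words)
        text = text[0].upper() + text[1:]
        lines.append(DescriptionLine(text=text,
                                     paths=tuple(p.bracket() for p in members)))
    return RelationshipDescription(lines=tuple(lines))
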