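"""Pedigree data model, ped-file I/O and structural validation.

A pedigree is a directed acyclic family structure: every member either has
both parents in the pedigree (a *nonfounder*) or neither (a *founder*).
Fathers must be male and mothers female; individuals of unknown sex are
allowed as long as they are not parents.  Connectedness is not required --
validation merely reports the components.

Ped-file dialect (PLINK/linkage style, whitespace- or tab-delimited):

* 4 columns: ``id father mother sex`` with ``0`` meaning "no parent" and
  sex coded 1=male, 2=female, 0=unknown;
* 5 columns: as above plus an affection-status column
  (2=affected, 1=unaffected, 0/-9=unknown);
* 6 columns: a leading family-id column (PLINK order), which is dropped.

Lines starting with ``#`` are comments, except directives of the form
``# status: <id> <flag>`` (flag in {carrier, deceased, affected}) which
attach annotation flags; a first row whose first token is ``id``
(case-insensitive) is treated as a header and skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_IN = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_OUT = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}

STATUS_FLAGS = ("affected", "carrier", "deceased")


class PedigreeError(ValueError):
    """Base class for all pedigree-related errors."""


class MalformedLine(PedigreeError):
    pass


class DuplicateId(PedigreeError):
    pass


class UnknownParent(PedigreeError):
    pass


class SexConflict(PedigreeError):
    pass


class SingleParent(PedigreeError):
    pass


class CycleError(PedigreeError):
    pass


class UnknownMember(PedigreeError):
    pass


class UnknownSexOnPath(PedigreeError):
    pass


class SamePair(PedigreeError):
    pass


class UndefinedKappa(PedigreeError):
    pass


class DomainError(PedigreeError):
    pass


class UnknownFixture(PedigreeError):
    pass


@dataclass(frozen=True)
class Member:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both set or both ``None``
    (founder).  ``statuses`` is a pass-through annotation set drawn from
    {affected, carrier, deceased}.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    statuses: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise MalformedLine(f"invalid member id {self.id!r}: empty or contains whitespace")
        if (self.father_id is None) != (self.mother_id is None):
            raise SingleParent(
                f"member {self.id!r} has exactly one parent given; "
                "either both parents or none must be specified"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise MalformedLine(f"member {self.id!r}: invalid sex {self.sex!r}")
        bad = set(self.statuses) - set(STATUS_FLAGS)
        if bad:
            raise MalformedLine(f"member {self.id!r}: unknown status flags {sorted(bad)}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.level.upper()} [{self.code}] {self.message}"


class Pedigree:
    """An ordered, validated collection of :class:`Member`.

    Pass ``validated=False`` to skip structural checks (used to build
    deliberately broken structures for :func:`validate`).
    """

    def __init__(self, members: Iterable[Member], validated: bool = True):
        self._members: dict[str, Member] = {}
        for m in members:
            if m.id in self._members:
                raise DuplicateId(f"duplicate member id {m.id!r}")
            self._members[m.id] = m
        if validated:
            errors = [d for d in validate(self) if d.level == "error"]
            if errors:
                first = errors[0]
                raise _ERROR_CLASSES.get(first.code, PedigreeError)(first.message)

    # -- basic access ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Member]:
        return iter(self._members.values())

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._members

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return list(self) == list(other)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def member(self, member_id: str) -> Member:
        """Look up a member; lenient about spaces vs underscores in ids."""
        try:
            return self._members[member_id]
        except KeyError:
            pass
        wanted = member_id.replace(" ", "_").lower()
        hits = [m for i, m in self._members.items() if i.replace(" ", "_").lower() == wanted]
        if len(hits) == 1:
            return hits[0]
        raise UnknownMember(f"unknown member {member_id!r}")

    def resolve(self, member_id: str) -> str:
        return self.member(member_id).id

    def father(self, member_id: str) -> Member | None:
        m = self.member(member_id)
        return self._members[m.father_id] if m.father_id else None

    def mother(self, member_id: str) -> Member | None:
        m = self.member(member_id)
        return self._members[m.mother_id] if m.mother_id else None

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self if m.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [m.id for m in self if not m.is_founder]

    def children(self, member_id: str) -> list[str]:
        mid = self.resolve(member_id)
        return [m.id for m in self if mid in (m.father_id, m.mother_id)]

    # -- structure -------------------------------------------------------

    def ancestors(self, member_id: str) -> set[str]:
        """Strict ancestors of ``member_id`` (transitive closure of parents)."""
        mid = self.resolve(member_id)
        out: set[str] = set()
        stack = [mid]
        while stack:
            m = self._members[stack.pop()]
            for p in (m.father_id, m.mother_id):
                if p is not None and p in self._members and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def ancestors_or_self(self, member_id: str) -> set[str]:
        mid = self.resolve(member_id)
        return self.ancestors(mid) | {mid}

    def depth(self, member_id: str) -> int:
        """Generation number: 0 for founders, else 1 + max parental depth."""
        mid = self.resolve(member_id)
        memo: dict[str, int] = {}

        def rec(i: str) -> int:
            if i in memo:
                return memo[i]
            m = self._members[i]
            memo[i] = 0 if m.is_founder else 1 + max(rec(m.father_id), rec(m.mother_id))
            return memo[i]

        return rec(mid)

    def components(self) -> list[set[str]]:
        """Connected components of the undirected parent-child graph."""
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in self._members:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                i = stack.pop()
                m = self._members[i]
                nbrs = [p for p in (m.father_id, m.mother_id) if p in self._members]
                nbrs += self.children(i)
                for n in nbrs:
                    if n not in comp:
                        comp.add(n)
                        stack.append(n)
            seen |= comp
            comps.append(comp)
        return comps

    def with_member(self, member: Member) -> "Pedigree":
        """Return a copy with ``member`` replaced or appended (revalidates)."""
        members = [member if m.id == member.id else m for m in self]
        if member.id not in self._members:
            members.append(member)
        return Pedigree(members)


_ERROR_CLASSES: dict[str, type[PedigreeError]] = {
    "UnknownParent": UnknownParent,
    "SexConflict": SexConflict,
    "SingleParent": SingleParent,
    "CycleError": CycleError,
    "DuplicateId": DuplicateId,
}


def validate(ped: Pedigree) -> list[Diagnostic]:
    """Check all structural invariants; returns diagnostics, never raises.

    Errors: unknown parents, sex conflicts, cycles.  Warnings: disconnected
    components, parents of unknown sex.
    """
    out: list[Diagnostic] = []
    ids = set(ped.ids)
    for m in ped:
        for role, pid, want in (("father", m.father_id, MALE), ("mother", m.mother_id, FEMALE)):
            if pid is None:
                continue
            if pid not in ids:
                out.append(Diagnostic("error", "UnknownParent",
                                      f"member {m.id!r}: {role} {pid!r} is not in the pedigree"))
                continue
            parent = ped.member(pid)
            if parent.sex == UNKNOWN:
                out.append(Diagnostic("warning", "UnknownSexParent",
                                      f"member {m.id!r}: {role} {pid!r} has unknown sex"))
            elif parent.sex != want:
                out.append(Diagnostic("error", "SexConflict",
                                      f"member {m.id!r}: {role} {pid!r} has sex {parent.sex}"))

    # cycle detection (only meaningful if parents resolve)
    if not any(d.code == "UnknownParent" for d in out):
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def has_cycle(i: str) -> bool:
            if state.get(i) == 1:
                return False
            if state.get(i) == 0:
                return True
            state[i] = 0
            m = ped.member(i)
            for p in (m.father_id, m.mother_id):
                if p is not None and has_cycle(p):
                    return True
            state[i] = 1
            return False

        for i in ped.ids:
            if has_cycle(i):
                out.append(Diagnostic("error", "CycleError",
                                      f"member {i!r} is its own ancestor"))
                break

    comps = ped.components()
    if len(comps) > 1:
        sizes = sorted((len(c) for c in comps), reverse=True)
        out.append(Diagnostic("warning", "Disconnected",
                              f"pedigree has {len(comps)} connected components (sizes {sizes})"))
    return out


# -- ped-file I/O ---------------------------------------------------------


def read_ped(text: str) -> Pedigree:
    """Parse ped-file content into a validated :class:`Pedigree`.

    Raises :class:`MalformedLine`, :class:`DuplicateId`, :class:`SingleParent`,
    :class:`UnknownParent`, :class:`SexConflict` or :class:`CycleError`, each
    naming the offending row or id.
    """
    rows: list[tuple[int, list[str]]] = []
    status_directives: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("status:"):
                parts = body[len("status:"):].split()
                if len(parts) != 2 or parts[1] not in STATUS_FLAGS:
                    raise MalformedLine(
                        f"line {lineno}: bad status directive {line!r} "
                        f"(expected '# status: <id> <{'|'.join(STATUS_FLAGS)}>')")
                status_directives.append((lineno, parts[0], parts[1]))
            continue
        rows.append((lineno, line.split()))

    if rows and rows[0][1][0].lower() == "id":
        rows = rows[1:]

    members: list[Member] = []
    seen: set[str] = set()
    for lineno, cols in rows:
        if len(cols) == 6:  # PLINK order: famid id fid mid sex aff
            cols = cols[1:]
        if len(cols) not in (4, 5):
            raise MalformedLine(
                f"line {lineno}: expected 4-6 columns (id father mother sex [affection]), "
                f"got {len(cols)}: {' '.join(cols)!r}")
        mid, fid, moid, sex = cols[:4]
        if mid in seen:
            raise DuplicateId(f"line {lineno}: duplicate member id {mid!r}")
        seen.add(mid)
        if sex not in _SEX_IN:
            raise MalformedLine(f"line {lineno}: invalid sex code {sex!r} for member {mid!r}")
        if (fid == "0") != (moid == "0"):
            raise SingleParent(
                f"line {lineno}: member {mid!r} has exactly one parent given "
                f"(father {fid!r}, mother {moid!r})")
        statuses: set[str] = set()
        if len(cols) == 5:
            aff = cols[4]
            if aff == "2":
                statuses.add("affected")
            elif aff not in ("0", "1", "-9"):
                raise MalformedLine(
                    f"line {lineno}: invalid affection code {aff!r} for member {mid!r}")
        members.append(Member(
            id=mid,
            father_id=None if fid == "0" else fid,
            mother_id=None if moid == "0" else moid,
            sex=_SEX_IN[sex],
            statuses=frozenset(statuses),
        ))

    by_id = {m.id: m for m in members}
    for lineno, mid, flag in status_directives:
        if mid not in by_id:
            raise MalformedLine(f"line {lineno}: status directive for unknown member {mid!r}")
        m = by_id[mid]
        by_id[mid] = replace(m, statuses=m.statuses | {flag})
    return Pedigree(by_id[m.id] for m in members)


def write_ped(ped: Pedigree) -> str:
    """Serialise a pedigree; ``read_ped(write_ped(p))`` equals ``p``."""
    any_aff = any("affected" in m.statuses for m in ped)
    lines = []
    for m in ped:
        cols = [m.id, m.father_id or "0", m.mother_id or "0", _SEX_OUT[m.sex]]
        if any_aff:
            cols.append("2" if "affected" in m.statuses else "1")
        lines.append(" ".join(cols))
    for m in ped:
        for flag in ("carrier", "deceased"):
            if flag in m.statuses:
                lines.append(f"# status: {m.id} {flag}")
    return "\n".join(lines) + "\n"
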