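"""Built-in pedigree library and a seeded random-pedigree generator.

The catalogue ships as plain ped files in package data and covers the
standard textbook relationships (trio, siblings, cousins, ...), the worked
examples (``fig1-example``, ``figS1-incest``) and the historic Habsburg
branch (the ancestry of Charles II of Spain).
"""

from __future__ import annotations

import random as _random
from importlib import resources

from .pedigree import (FEMALE, MALE, Member, Pedigree, UnknownFixture, read_ped)

#: fixture name -> the pair of members the fixture's name refers to
FIXTURE_PAIRS: dict[str, tuple[str, str]] = {
    "trio": ("1", "3"),                          # parent-offspring
    "full-siblings": ("3", "4"),
    "half-siblings": ("4", "5"),
    "grandparent": ("1", "5"),
    "aunt-nephew": ("3", "6"),
    "first-cousins": ("7", "8"),
    "second-cousins": ("11", "12"),
    "quadruple-half-first-cousins": ("9", "10"),
    "fig1-example": ("6", "7"),
    "figS1-incest": ("1", "5"),
    "habsburg": ("Philip_IV", "Mariana"),
}

FIXTURE_NAMES: tuple[str, ...] = tuple(FIXTURE_PAIRS)


def fixture_text(name: str) -> str:
    """Raw ped-file content of a built-in fixture."""
    if name not in FIXTURE_PAIRS:
        raise UnknownFixture(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return resources.files("pedrel.data").joinpath(f"{name}.ped").read_text()


def builtin(name: str) -> Pedigree:
    """Load a named built-in pedigree (see :data:`FIXTURE_NAMES`)."""
    return read_ped(fixture_text(name))


def random_pedigree(seed: int, max_nonfounders: int = 8,
                    allow_inbreeding: bool = True) -> Pedigree:
    """Generate a random valid pedigree with ``1..max_nonfounders`` nonfounders.

    Children pick their parents from existing members (enabling complex,
    cross-generational inbreeding when ``allow_inbreeding``) or from fresh
    founder couples.  Used by property tests to stress the coefficient
    recursions; the structure is always a valid ped per :func:`validate`.
    """
    rng = _random.Random(seed)
    members: list[Member] = []
    counter = [0]

    def new_founder(sex: str) -> str:
        counter[0] += 1
        mid = str(counter[0])
        members.append(Member(id=mid, sex=sex))
        return mid

    males = [new_founder(MALE)]
    females = [new_founder(FEMALE)]
    n_children = rng.randint(1, max_nonfounders)
    for _ in range(n_children):
        if allow_inbreeding and rng.random() < 0.65:
            father = rng.choice(males)
            mother = rng.choice(females)
        else:
            father, mother = new_founder(MALE), new_founder(FEMALE)
        counter[0] += 1
        cid = str(counter[0])
        sex = rng.choice((MALE, FEMALE))
        members.append(Member(id=cid, father_id=father, mother_id=mother, sex=sex))
        (males if sex == MALE else females).append(cid)
    return Pedigree(members)
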