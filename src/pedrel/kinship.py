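"""Inbreeding and kinship coefficients (autosomal and X) and relationship degree.

The kinship coefficient phi(A,B) is the probability that one allele drawn at
random from A and one from B at the same autosomal locus are identical by
descent (IBD) within the pedigree.  The inbreeding coefficient f(A) is the
kinship of A's parents (0 for founders).  All values are computed with the
classical two-gene recursion in exact rational arithmetic
(:class:`fractions.Fraction`), so downstream identities hold exactly.

On the X chromosome males are hemizygous: a male carries a single X gene,
inherited from his mother, and his X inbreeding coefficient is 1 by
convention (his one gene is trivially identical to itself), which makes
phi_X(M,M) = 1 consistent with the (1+f)/2 diagonal form.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .pedigree import (FEMALE, MALE, UNKNOWN, DomainError, Pedigree,
                       UnknownSexOnPath)

Rational = Fraction


def _kinship_memo(ped: Pedigree) -> dict:
    # one memo per Pedigree instance, lazily attached
    memo = getattr(ped, "_phi_memo", None)
    if memo is None:
        memo = {}
        ped._phi_memo = memo  # type: ignore[attr-defined]
    return memo


def kinship(ped: Pedigree, a: str, b: str) -> Fraction:
    """Autosomal kinship coefficient phi(a, b); a == b gives (1 + f_a)/2."""
    a, b = ped.resolve(a), ped.resolve(b)
    memo = _kinship_memo(ped)

    def phi(x: str, y: str) -> Fraction:
        if ped.depth(x) < ped.depth(y):
            x, y = y, x
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        mx = ped.member(x)
        if x == y:
            val = Fraction(1, 2) if mx.is_founder else \
                Fraction(1, 2) * (1 + phi(mx.father_id, mx.mother_id))
        elif mx.is_founder:
            # x has max depth, so y is a founder too and x != y
            val = Fraction(0)
        else:
            val = Fraction(1, 2) * (phi(mx.father_id, y) + phi(mx.mother_id, y))
        memo[key] = val
        return val

    return phi(a, b)


def inbreeding(ped: Pedigree, a: str) -> Fraction:
    """f(a) = kinship of a's parents, or 0 for a founder."""
    m = ped.member(a)
    if m.is_founder:
        return Fraction(0)
    return kinship(ped, m.father_id, m.mother_id)


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """All-pairs kinship (floats), diagonal (1+f)/2, indexed by member id."""
    ids = ped.ids
    data = [[float(kinship(ped, a, b)) for b in ids] for a in ids]
    return pd.DataFrame(data, index=ids, columns=ids)


# -- X chromosome ---------------------------------------------------------


def check_x_sexes(ped: Pedigree, a: str, b: str) -> None:
    """Raise :class:`UnknownSexOnPath` if any member on a connecting path
    between a and b has unknown sex."""
    a, b = ped.resolve(a), ped.resolve(b)
    anc_a, anc_b = ped.ancestors_or_self(a), ped.ancestors_or_self(b)
    common = anc_a & anc_b
    for m in anc_a | anc_b:
        on_path = (ped.ancestors_or_self(m) & common) and True
        if on_path and ped.member(m).sex == UNKNOWN:
            raise UnknownSexOnPath(
                f"member {m!r} lies on a connecting path of ({a!r}, {b!r}) "
                "but has unknown sex; X-chromosomal coefficients need known sexes")


def kinship_x(ped: Pedigree, a: str, b: str) -> Fraction:
    """X-chromosomal kinship; males hemizygous (their X is maternal)."""
    a, b = ped.resolve(a), ped.resolve(b)
    check_x_sexes(ped, a, b)
    memo = getattr(ped, "_phix_memo", None)
    if memo is None:
        memo = {}
        ped._phix_memo = memo  # type: ignore[attr-defined]

    def phi(x: str, y: str) -> Fraction:
        if ped.depth(x) < ped.depth(y):
            x, y = y, x
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        mx = ped.member(x)
        if x == y:
            if mx.sex == MALE:
                val = Fraction(1)
            else:
                val = Fraction(1, 2) if mx.is_founder else \
                    Fraction(1, 2) * (1 + phi_parents_x(x))
        elif mx.is_founder:
            val = Fraction(0)
        elif mx.sex == MALE:
            val = phi(mx.mother_id, y)
        else:
            val = Fraction(1, 2) * (phi(mx.father_id, y) + phi(mx.mother_id, y))
        memo[key] = val
        return val

    def phi_parents_x(x: str) -> Fraction:
        m = ped.member(x)
        return phi(m.father_id, m.mother_id)

    return phi(a, b)


def inbreeding_x(ped: Pedigree, a: str) -> Fraction:
    """X inbreeding: 1 for males (hemizygous convention), else kinship_x of
    the parents (0 for female founders)."""
    m = ped.member(a)
    if m.sex == MALE:
        return Fraction(1)
    if m.is_founder:
        return Fraction(0)
    return kinship_x(ped, m.father_id, m.mother_id)


# -- degree ---------------------------------------------------------------

UNRELATED = "unrelated"


def degree(phi: Fraction | float) -> int | str:
    """Relationship degree: round(log2(1/phi) - 1), exact halves rounded down.

    The intervals are closed below: degree 0 for phi in [2^(-3/2), 1],
    degree 1 for [2^(-5/2), 2^(-3/2)), etc.  phi = 0 gives "unrelated".
    Computed exactly: degree d is the smallest integer with
    phi^2 * 2^(2d+3) >= 1.
    """
    q = Fraction(phi)
    if q < 0 or q > 1:
        raise DomainError(f"kinship coefficient {phi!r} outside [0, 1]")
    if q == 0:
        return UNRELATED
    d = 0
    while q * q * (1 << (2 * d + 3)) < 1:
        d += 1
    return d
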