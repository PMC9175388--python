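"""Independent brute-force oracles for the coefficient recursions.

Exhaustive enumeration over all inheritance vectors (2 bits per nonfounder:
which parental gene each transmitted gene copies).  Exponential in the
number of nonfounders, so only usable on small pedigrees (<= 7 nonfounders),
but exact and entirely independent of the package's recursive engine.
"""

from fractions import Fraction
from itertools import product

# Jacquard's ordering of the 15 detailed states over genes
# (1=A-pat, 2=A-mat, 3=B-pat, 4=B-mat), written out by hand.
DETAILED_PARTITIONS = [
    [{1, 2, 3, 4}],
    [{1, 2}, {3, 4}],
    [{1, 2, 3}, {4}],
    [{1, 2, 4}, {3}],
    [{1, 2}, {3}, {4}],
    [{1, 3, 4}, {2}],
    [{2, 3, 4}, {1}],
    [{3, 4}, {1}, {2}],
    [{1, 3}, {2, 4}],
    [{1, 4}, {2, 3}],
    [{1, 3}, {2}, {4}],
    [{1, 4}, {2}, {3}],
    [{2, 3}, {1}, {4}],
    [{2, 4}, {1}, {3}],
    [{1}, {2}, {3}, {4}],
]


def _partition_of(genes):
    """IBD partition of the 4 positional genes by label equality."""
    blocks = {}
    for pos, g in enumerate(genes, start=1):
        blocks.setdefault(g, set()).add(pos)
    part = sorted(blocks.values(), key=lambda s: sorted(s))
    for idx, ref in enumerate(DETAILED_PARTITIONS):
        if sorted(ref, key=lambda s: sorted(s)) == part:
            return idx
    raise AssertionError("unreachable")


def _condensed_of(genes):
    """0-based condensed state index of (x1, x2, y1, y2)."""
    x1, x2, y1, y2 = genes
    aa, bb = x1 == x2, y1 == y2
    cross = [x1 == y1, x1 == y2, x2 == y1, x2 == y2]
    if aa and bb:
        return 0 if x1 == y1 else 1
    if aa:
        return 2 if any(cross) else 3
    if bb:
        return 4 if any(cross) else 5
    if (x1 == y1 and x2 == y2) or (x1 == y2 and x2 == y1):
        return 6
    return 7 if any(cross) else 8


def enumerate_identity(ped, a, b):
    """Exact (phi, delta9, delta15) for a pair by exhausting all inheritance
    vectors; requires a small pedigree."""
    a, b = ped.resolve(a), ped.resolve(b)
    order = sorted(ped.ids, key=ped.depth)
    nonfounders = [i for i in order if not ped.member(i).is_founder]
    n = len(nonfounders)
    assert n <= 8, "oracle limited to small pedigrees"

    founder_genes = {}
    label = 0
    for i in order:
        if ped.member(i).is_founder:
            founder_genes[i] = (label, label + 1)
            label += 2

    w = Fraction(1, 4 ** n)
    phi = Fraction(0)
    delta9 = [Fraction(0)] * 9
    delta15 = [Fraction(0)] * 15
    for bits in product((0, 1), repeat=2 * n):
        genes = dict(founder_genes)
        for idx, i in enumerate(nonfounders):
            m = ped.member(i)
            pat = genes[m.father_id][bits[2 * idx]]
            mat = genes[m.mother_id][bits[2 * idx + 1]]
            genes[i] = (pat, mat)
        four = (genes[a][0], genes[a][1], genes[b][0], genes[b][1])
        delta15[_partition_of(four)] += w
        delta9[_condensed_of(four)] += w
        ibd_pairs = sum(1 for x in four[:2] for y in four[2:] if x == y)
        phi += w * Fraction(ibd_pairs, 4)
    return phi, tuple(delta9), tuple(delta15)
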