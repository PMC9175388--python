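"""Jacquard identity coefficients, IBD coefficients and a gene-drop oracle.

The four genes of a pair (A's paternal/maternal gene, B's paternal/maternal
gene) fall into one of 15 *detailed* identity-by-descent states
(delta_1..delta_15, the set partitions of the four genes), which collapse to
Jacquard's 9 *condensed* states (Delta_1..Delta_9) when parental origin is
ignored.  For noninbred pairs only the last three condensed states are
attainable and kappa = (Delta_9, Delta_8, Delta_7) gives the probabilities
of sharing 0/1/2 alleles IBD.

Everything is computed exactly (``fractions.Fraction``) from *generalized
kinship coefficients*: probabilities that prescribed groups of genes are
each all-IBD.  These obey Karigl-style recursions obtained by conditioning
on which parental gene a random draw picks; the condensed coefficients are
recovered by solving a fixed 9x9 linear system, the detailed ones by Moebius
inversion over the partition lattice of the four genes.

X-chromosomal versions treat males as hemizygous (one gene, maternal).  For
the condensed X coefficients a male's single gene is counted twice, so the
usual 9-state space applies with unattainable states carrying probability 0.

A Monte-Carlo *gene dropping* simulator (labelled founder alleles transmitted
by fair Mendelian draws) provides an independent stochastic check.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Literal, NamedTuple

import numpy as np

from .kinship import check_x_sexes, inbreeding, inbreeding_x
from .pedigree import MALE, Pedigree, SamePair, UndefinedKappa

Chromosome = Literal["autosomal", "X"]

# ---------------------------------------------------------------------------
# Generalized kinship engine
#
# A *state* is a tuple of groups; each group is a tuple of slots; the value
# of a state is the probability that, within every group, all genes are IBD.
# Slot kinds:
#   ('r', id)       a fresh uniform draw among the individual's genes
#   ('s', id, o)    the individual's specific parental gene, o in {'p','m'}
#   ('t', id, o)    a founder allele label (IBD with nothing else)
# Two occurrences of the same specific slot or token denote the SAME
# physical gene: they are deduplicated within a group, and groups sharing
# one are merged.  Random slots denote independent draws and keep their
# multiplicity.
# ---------------------------------------------------------------------------

_R, _S, _T = "r", "s", "t"


def _canonical(groups):
    """Dedupe shared physical genes, merge groups sharing one, drop trivial
    groups; returns (key, groups) or the literal 0 when impossible."""
    merged: list[set | list] = []
    work = [list(g) for g in groups]
    # merge groups sharing a specific slot or token
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                shared = {s for s in work[i] if s[0] in (_S, _T)} & \
                         {s for s in work[j] if s[0] in (_S, _T)}
                if shared:
                    work[i] = work[i] + [s for s in work[j]]
                    del work[j]
                    changed = True
                    break
            if changed:
                break
    out = []
    for g in work:
        seen: set = set()
        gg = []
        for s in g:
            if s[0] in (_S, _T):
                if s in seen:
                    continue
                seen.add(s)
            gg.append(s)
        if len(gg) <= 1:
            continue
        if sum(1 for s in gg if s[0] == _T) >= 1 and len(gg) >= 2:
            # a founder allele can only be IBD with itself; if anything else
            # remains in the group the state is impossible only when ALL
            # other slots are tokens or belong to other founders -- but by
            # construction tokens are created only once every individual in
            # the state is a founder, so any companion slot is impossible.
            if all(s[0] == _T for s in gg):
                return None  # two distinct founder alleles required IBD
        out.append(tuple(sorted(gg)))
    return tuple(sorted(out))


class _Engine:
    def __init__(self, ped: Pedigree, x: bool):
        self.ped = ped
        self.x = x
        attr = "_gk_memo_x" if x else "_gk_memo"
        memo = getattr(ped, attr, None)
        if memo is None:
            memo = {}
            setattr(ped, attr, memo)
        self.memo: dict = memo

    def value(self, groups) -> Fraction:
        state = _canonical(groups)
        if state is None:
            return Fraction(0)
        return self._eval(state)

    def _eval(self, state) -> Fraction:
        if not state:
            return Fraction(1)
        if state in self.memo:
            return self.memo[state]
        ped = self.ped
        inds = {s[1] for g in state for s in g if s[0] != _T}
        if not inds:
            # only founder-allele tokens remain; any surviving group needs
            # two distinct alleles IBD -> impossible
            val = Fraction(0)
        else:
            a = max(inds, key=lambda i: (ped.depth(i), i))
            if self.x and ped.member(a).sex == MALE:
                val = self._reduce_male_x(state, a)
            else:
                val = self._reduce(state, a)
        self.memo[state] = val
        return val

    def _substitute(self, slot):
        """Resolve a specific slot ('s', a, o) one generation up."""
        _, a, o = slot
        m = self.ped.member(a)
        if m.is_founder:
            return (_T, a, o)
        if self.x:
            # o == 'p': the father's single X gene; o == 'm': maternal draw
            parent = m.father_id if o == "p" else m.mother_id
            return (_R, parent)
        parent = m.father_id if o == "p" else m.mother_id
        return (_R, parent)

    def _reduce(self, state, a) -> Fraction:
        """Condition on the parental origin of each random draw from ``a``."""
        groups = [list(g) for g in state]
        positions = [(gi, si) for gi, g in enumerate(groups)
                     for si, s in enumerate(g) if s == (_R, a)]
        k = len(positions)
        total = Fraction(0)
        for pattern in product("pm", repeat=k):
            branch = [list(g) for g in groups]
            for (gi, si), o in zip(positions, pattern):
                branch[gi][si] = (_S, a, o)
            # dedupe/merge FIRST: equal specific slots are one physical gene
            merged = _canonical(branch)
            if merged is None:
                continue
            resolved = [[self._substitute(s) if s[:2] == (_S, a) else s
                         for s in g] for g in merged]
            total += self.value(resolved)
        return total / (1 << k) if k else total

    def _reduce_male_x(self, state, a) -> Fraction:
        """A male has one X gene: all his slots are the same physical gene."""
        groups = [list(g) for g in state]
        touching = [g for g in groups if any(s[0] != _T and s[1] == a for s in g)]
        rest = [g for g in groups if g not in touching]
        merged = [s for g in touching for s in g if not (s[0] != _T and s[1] == a)]
        m = self.ped.member(a)
        gene = (_T, a, "h") if m.is_founder else (_R, m.mother_id)
        merged.append(gene)
        return self.value(rest + [merged])


# ---------------------------------------------------------------------------
# Condensed identity coefficients (9x9 linear system)
# ---------------------------------------------------------------------------

F = Fraction
H, Q, E, S16 = F(1, 2), F(1, 4), F(1, 8), F(1, 16)

# Rows: sum, f_a, f_b, phi_ab, phi_aab, phi_abb, phi_aabb, phi_aa.bb, phi_ab.ab
# Columns: Delta_1 .. Delta_9 (Jacquard's classical ordering).
_M9 = [
    [1, 1, 1, 1, 1, 1, 1, 1, 1],
    [1, 1, 1, 1, 0, 0, 0, 0, 0],
    [1, 1, 0, 0, 1, 1, 0, 0, 0],
    [1, 0, H, 0, H, 0, H, Q, 0],
    [1, 0, H, 0, Q, 0, Q, E, 0],
    [1, 0, Q, 0, H, 0, Q, E, 0],
    [1, 0, Q, 0, Q, 0, E, S16, 0],
    [1, 1, H, H, H, H, Q, Q, Q],
    [1, 0, Q, 0, Q, 0, Q, S16, 0],
]


def _solve(mat, vec):
    """Exact Gaussian elimination over the rationals."""
    n = len(vec)
    m = [[F(x) for x in row] + [F(v)] for row, v in zip(mat, vec)]
    for col in range(n):
        piv = next(r for r in range(col, n) if m[r][col] != 0)
        m[col], m[piv] = m[piv], m[col]
        inv = 1 / m[col][col]
        m[col] = [x * inv for x in m[col]]
        for r in range(n):
            if r != col and m[r][col] != 0:
                f = m[r][col]
                m[r] = [x - f * y for x, y in zip(m[r], m[col])]
    return tuple(m[r][n] for r in range(n))


def condensed_identity(ped: Pedigree, a: str, b: str,
                       chromosome: Chromosome = "autosomal") -> tuple[Fraction, ...]:
    """Jacquard's condensed identity coefficients (Delta_1..Delta_9), exact."""
    a, b = ped.resolve(a), ped.resolve(b)
    if a == b:
        raise SamePair(f"identity coefficients need two distinct members, got {a!r} twice")
    x = chromosome == "X"
    if x:
        check_x_sexes(ped, a, b)
        fa, fb = inbreeding_x(ped, a), inbreeding_x(ped, b)
    else:
        fa, fb = inbreeding(ped, a), inbreeding(ped, b)
    g = _Engine(ped, x)
    ra, rb = ("r", a), ("r", b)
    vec = [
        F(1),
        fa,
        fb,
        g.value([[ra, rb]]),
        g.value([[ra, ra, rb]]),
        g.value([[ra, rb, rb]]),
        g.value([[ra, ra, rb, rb]]),
        g.value([[ra, ra], [rb, rb]]),
        g.value([[ra, rb], [ra, rb]]),
    ]
    return _solve(_M9, vec)


def condensed_identity_x(ped: Pedigree, a: str, b: str) -> tuple[Fraction, ...]:
    return condensed_identity(ped, a, b, chromosome="X")


# ---------------------------------------------------------------------------
# Detailed identity coefficients (Moebius inversion over partitions)
# ---------------------------------------------------------------------------

# Jacquard's ordering of the 15 partitions of (1,2,3,4) =
# (A-paternal, A-maternal, B-paternal, B-maternal).
_PARTITIONS: list[tuple[tuple[int, ...], ...]] = [
    ((1, 2, 3, 4),),
    ((1, 2), (3, 4)),
    ((1, 2, 3), (4,)),
    ((1, 2, 4), (3,)),
    ((1, 2), (3,), (4,)),
    ((1, 3, 4), (2,)),
    ((2, 3, 4), (1,)),
    ((3, 4), (1,), (2,)),
    ((1, 3), (2, 4)),
    ((1, 4), (2, 3)),
    ((1, 3), (2,), (4,)),
    ((1, 4), (2,), (3,)),
    ((2, 3), (1,), (4,)),
    ((2, 4), (1,), (3,)),
    ((1,), (2,), (3,), (4,)),
]


def _refines(p, q) -> bool:
    """True if every block of p is contained in a block of q."""
    return all(any(set(bp) <= set(bq) for bq in q) for bp in p)


# delta_8 of the condensed scale collects four detailed states, etc.
AGGREGATION_15_TO_9: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3, 4), (5,), (6, 7), (8,), (9, 10), (11, 12, 13, 14), (15,),
)


def aggregate_detailed(delta15) -> tuple[Fraction, ...]:
    """Collapse the 15 detailed coefficients to the 9 condensed ones."""
    return tuple(sum((Fraction(delta15[i - 1]) for i in grp), Fraction(0))
                 for grp in AGGREGATION_15_TO_9)


def detailed_identity(ped: Pedigree, a: str, b: str) -> tuple[Fraction, ...]:
    """Jacquard's detailed identity coefficients (delta_1..delta_15), exact.

    Gene 1/2 = A's paternal/maternal gene, gene 3/4 = B's.  For founders the
    two genes are exchangeable, so the paternal/maternal assignment is a
    harmless convention.
    """
    a, b = ped.resolve(a), ped.resolve(b)
    if a == b:
        raise SamePair(f"identity coefficients need two distinct members, got {a!r} twice")
    g = _Engine(ped, x=False)
    slot = {1: ("s", a, "p"), 2: ("s", a, "m"), 3: ("s", b, "p"), 4: ("s", b, "m")}
    psi = [g.value([[slot[i] for i in block] for block in part])
           for part in _PARTITIONS]
    zeta = [[1 if _refines(pi, sj) else 0 for sj in _PARTITIONS]
            for pi in _PARTITIONS]
    return _solve(zeta, psi)


# ---------------------------------------------------------------------------
# kappa / IBD coefficients
# ---------------------------------------------------------------------------


class KappaTriple(NamedTuple):
    k0: Fraction
    k1: Fraction
    k2: Fraction
    defined: bool = True


def kappa(ped: Pedigree, a: str, b: str,
          chromosome: Chromosome = "autosomal") -> KappaTriple:
    """IBD coefficients (kappa0, kappa1, kappa2); only defined when neither
    member is inbred, otherwise ``defined`` is False."""
    a, b = ped.resolve(a), ped.resolve(b)
    if a == b:
        raise SamePair(f"kappa needs two distinct members, got {a!r} twice")
    if chromosome == "X":
        fa, fb = inbreeding_x(ped, a), inbreeding_x(ped, b)
    else:
        fa, fb = inbreeding(ped, a), inbreeding(ped, b)
    if fa > 0 or fb > 0:
        return KappaTriple(Fraction(0), Fraction(0), Fraction(0), defined=False)
    d = condensed_identity(ped, a, b, chromosome=chromosome)
    return KappaTriple(d[8], d[7], d[6], defined=True)


# ---------------------------------------------------------------------------
# Gene dropping (Monte-Carlo oracle)
# ---------------------------------------------------------------------------


@dataclass
class GeneDropResult:
    """Estimated condensed identity coefficients with binomial standard errors."""
    freq: tuple[float, ...]      # 9 state frequencies
    se: tuple[float, ...]        # binomial standard errors
    n: int
    chromosome: Chromosome

    @property
    def phi(self) -> float:
        f = self.freq
        return f[0] + 0.5 * (f[2] + f[4] + f[6]) + 0.25 * f[7]

    @property
    def phi_se(self) -> float:
        """Standard error of the phi estimate (a linear functional of the
        multinomial state frequencies)."""
        c = (1.0, 0.0, 0.5, 0.0, 0.5, 0.0, 0.5, 0.25, 0.0)
        m1 = sum(ci * fi for ci, fi in zip(c, self.freq))
        m2 = sum(ci * ci * fi for ci, fi in zip(c, self.freq))
        return max(m2 - m1 * m1, 0.0) ** 0.5 / self.n ** 0.5


def _classify_states(x1, x2, y1, y2) -> np.ndarray:
    """Vectorised condensed-state index (0-based) of four gene labels."""
    aa = x1 == x2
    bb = y1 == y2
    c11, c12 = x1 == y1, x1 == y2
    c21, c22 = x2 == y1, x2 == y2
    anycross = c11 | c12 | c21 | c22
    state = np.full(x1.shape, 8, dtype=np.int8)  # default Delta9
    both = aa & bb
    state[both & c11] = 0
    state[both & ~c11] = 1
    state[aa & ~bb & anycross] = 2
    state[aa & ~bb & ~anycross] = 3
    state[~aa & bb & anycross] = 4
    state[~aa & bb & ~anycross] = 5
    two = ~aa & ~bb & ((c11 & c22) | (c12 & c21))
    one = ~aa & ~bb & ~two & anycross
    state[two] = 6
    state[one] = 7
    return state


def gene_drop(ped: Pedigree, a: str, b: str, n: int, seed: int,
              chromosome: Chromosome = "autosomal") -> GeneDropResult:
    """Drop labelled founder alleles through the pedigree ``n`` times and
    tabulate the condensed identity state of the pair (a, b).

    Founders receive distinct allele labels (one only for males on X);
    transmissions are fair Mendelian draws.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    a, b = ped.resolve(a), ped.resolve(b)
    x = chromosome == "X"
    if x:
        check_x_sexes(ped, a, b)
    rng = np.random.default_rng(seed)
    order = sorted(ped.ids, key=ped.depth)
    genes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = 0
    for mid in order:
        m = ped.member(mid)
        male = m.sex == MALE
        if m.is_founder:
            if x and male:
                g = np.full(n, label, dtype=np.int32)
                genes[mid] = (g, g)
                label += 1
            else:
                genes[mid] = (np.full(n, label, dtype=np.int32),
                              np.full(n, label + 1, dtype=np.int32))
                label += 2
        else:
            fg, mg = genes[m.father_id], genes[m.mother_id]
            pick_m = rng.integers(0, 2, size=n)
            mat = np.where(pick_m == 0, mg[0], mg[1])
            if x and male:
                genes[mid] = (mat, mat)  # hemizygous: single maternal gene
            else:
                pick_p = rng.integers(0, 2, size=n)
                pat = np.where(pick_p == 0, fg[0], fg[1])
                genes[mid] = (pat, mat)
    states = _classify_states(genes[a][0], genes[a][1], genes[b][0], genes[b][1])
    counts = np.bincount(states, minlength=9)
    freq = counts / n
    se = np.sqrt(freq * (1 - freq) / n)
    return GeneDropResult(tuple(freq.tolist()), tuple(se.tolist()), n, chromosome)


def phi_from_condensed(delta9) -> Fraction:
    """phi = Delta1 + (Delta3 + Delta5 + Delta7)/2 + Delta8/4."""
    d = [Fraction(x) for x in delta9]
    return d[0] + Fraction(1, 2) * (d[2] + d[4] + d[6]) + Fraction(1, 4) * d[7]
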