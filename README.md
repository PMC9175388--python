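# pedrel

Pedigree-based relatedness analysis: exact kinship, inbreeding, IBD and
Jacquard identity coefficients (autosomal and X-chromosomal), the
relatedness (IBD) triangle, and standardized verbal descriptions of
pairwise relationships.

`pedrel` is aimed at medical and forensic geneticists, animal breeders and
teachers who need the *expected* relatedness implied by a family structure
— as opposed to relatedness *estimated* from genotype data.  It reads and
writes plain-text ped files (PLINK/linkage dialect), ships a library of
built-in pedigrees (textbook relationships, the famously inbred Habsburg
branch, worked teaching examples), and exposes both a Python API and a
`pedrel` command-line tool.

## The coefficients

For members *A*, *B* of a pedigree:

- **Inbreeding** `f_A`: the kinship coefficient of A's parents (0 for a
  founder); the probability that A's two alleles at a locus are identical
  by descent (IBD).
- **Kinship** `φ_AB`: the probability that a random allele from A and one
  from B at the same autosomal locus are IBD.  Computed by the classical
  recursion `φ(A,B) = ½[φ(F_A,B) + φ(M_A,B)]`, `φ(A,A) = (1+f_A)/2`, in
  exact rational arithmetic.
- **IBD coefficients** `κ = (κ0, κ1, κ2)`: probabilities of sharing 0/1/2
  alleles IBD; defined only for pairs of non-inbred individuals.
- **Condensed identity coefficients** `Δ1..Δ9` (Jacquard) and **detailed
  identity coefficients** `δ1..δ15` (paternal/maternal genes
  distinguished), computed exactly via generalized-kinship recursions.
- **Relationship degree**: the discretisation `round(log2(1/φ) − 1)`
  (1 = parent-child, 2 = half siblings, ...), with boundaries closed below.
- X-chromosomal versions of all of the above, treating males as hemizygous.

Verbal descriptions are built from Wright's path formula

```
φ_AB = Σ_{C, v1, v2} (1/2)^(l1+l2+1) (1 + f_C)
```

summed over all common ancestors *C* and pairs of non-intersecting
descending paths to A and B.  Each connecting path is classified as lineal,
sibling, avuncular or cousin; spouse-pairs of paths merge into *full*
paths; groups of numerically identical paths are reported together as
double/triple/... relationships.

## Worked example

The parents of Charles II of Spain — Philip IV and his niece Mariana — in
the built-in Habsburg branch pedigree:

```
$ pedrel coeffs habsburg Philip_IV Mariana
Pair: Philip_IV - Mariana (autosomal)
Inbreeding coefficients: f = 0.082 and f = 0.136
Kinship coefficient: phi = 0.231
Relationship degree: 1
IBD coefficients kappa: undefined (inbred pair)
Condensed identity Delta: (0.011, 0.004, 0.044, 0.024, 0.077, 0.044, 0.071, 0.498, 0.228)
Detailed identity delta: (0.011, 0.004, 0.007, 0.037, 0.024, 0.016, 0.06, 0.044, 0.013, 0.059, 0.016, 0.208, 0.072, 0.202, 0.228)
```

Their kinship (0.231) is close to parent-child level (0.25), hence degree
1; κ is undefined because both are themselves inbred.  The verbal
description untangles how they are simultaneously related in nine distinct
ways:

```
$ pedrel describe habsburg Philip_IV Mariana
Uncle-niece
First cousins once removed
Second cousins once removed
Triple second cousins twice removed
Triple third cousins
Septuple third cousins once removed
Sextuple third cousins twice removed
Triple 4th cousins
Septuple 4th cousins once removed
```

(`--paths` appends each connecting path in bracket notation, the common
ancestor(s) shown in brackets, e.g.
`Philip_IV-[Philip_III,Margaret_of_Austria]-Maria_Anna_of_Spain-Mariana`.)

A small teaching pedigree (`fig1-example`, two children of a couple who are
themselves half siblings) shows the path machinery at desk scale: the pair
(6,7) has four connecting paths, merging to

```
$ pedrel describe fig1-example 6 7 --paths
Full siblings
  6-[4,5]-7
Double half first cousins
  6-4-[2]-5-7
  6-5-[2]-4-7
```

and `φ = 2·(1/8) + 2·(1/32) = 5/16 = 0.3125` by Wright's formula, equal to
the recursive value.  For non-inbred pairs, `pedrel triangle` plots
`(κ0, κ2)` in the IBD triangle against the standard reference
relationships, with Thompson's inadmissible region `κ1² < 4κ0κ2` shaded.

Other commands: `pedrel validate` (structural diagnostics for ped files),
`pedrel convert` (dialect normalisation), `pedrel fixtures` (the built-in
library), `pedrel gendrop` (Monte-Carlo gene-drop estimates).

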