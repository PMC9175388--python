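# Methods

## Pedigree model

A pedigree is a finite directed acyclic graph of individuals in which every
member has either both parents present (nonfounder) or neither (founder).
Fathers are male and mothers female; members of unknown sex are accepted as
long as they are not parents, and X-chromosomal computations additionally
require known sex for every member on a connecting path of the queried
pair.  Connectedness is not required; validation reports components as
warnings.  Founders are assumed mutually unrelated and non-inbred: all
coefficients are relative to the founder population, so truncating a deep
genealogy changes the numbers (the packaged Habsburg branch, for instance,
gives Philip IV f = 0.082, whereas genealogies reaching further back give
larger values).

The both-or-neither parent rule (a `SingleParent` error otherwise) keeps
every recursion well-defined without inventing placeholder parents.  The
ped-file dialect is the de-facto PLINK/linkage layout: `id father mother
sex` with `0` for a missing parent and sex codes 1/2/0, an optional fifth
affection column, and an optional leading family-id column (detected when
six columns are present, then dropped).  Carrier/deceased annotation —
which has no standard ped-file encoding — travels in `# status: <id>
<flag>` comment directives, which ordinary ped consumers ignore; round
trips through `write_ped`/`read_ped` are exact.

## Kinship and inbreeding

The kinship coefficient is computed by the classical two-gene recursion
(descend on the member with the larger generation number, memoised), with
`phi(A,A) = (1 + f_A)/2` and `f_A` the parental kinship.  All arithmetic
uses `fractions.Fraction`: the values are exact rationals, so the internal
consistency identities (`f = 2 phi_self - 1`, the Delta/phi relations
below) are asserted as exact equalities rather than to a tolerance.

On X, a male carries a single gene inherited from his mother:
`phi_X(male, B) = phi_X(mother, B)`, `phi_X(M, M) = 1`, and his X
inbreeding coefficient is 1 by convention (one gene, trivially identical
to itself), keeping the `(1+f)/2` diagonal form coherent.  Females follow
the autosomal rules.

## Relationship degree

The degree discretises kinship: `round(log2(1/phi) - 1)`, so parent-child
(phi = 1/4) is degree 1, half siblings (1/8) degree 2, and so on.  The
interval boundaries `2^-(d + 3/2)` belong to the *lower* degree (intervals
closed below), which corresponds to rounding exact halves down.  The
implementation avoids logarithms entirely: d is the smallest integer with
`phi^2 * 2^(2d+3) >= 1`, an exact rational test that is monotone and makes
the closed-below convention unambiguous even for floating-point inputs.
Degree is defined from the autosomal kinship only; no X degree is reported.

## Identity coefficients

The four genes of a pair (A's paternal and maternal gene, B's) fall in one
of the 15 set partitions by IBD — Jacquard's detailed states
delta_1..delta_15 — which aggregate to the 9 condensed states
Delta_1..Delta_9 when parental origin is ignored (Delta_1 = all four genes
IBD, ..., Delta_8 = exactly one cross pair IBD, Delta_9 = no IBD).

Both vectors are derived from *generalized kinship coefficients*: the
probability that prescribed groups of genes are each internally IBD.  The
engine represents a query as groups of gene slots (a random draw from an
individual, a specific parental gene, or a founder-allele label) and
reduces the individual of maximal generation: each random draw from that
individual is conditioned on picking the paternal or maternal gene (2^k
branches), slots that become the same physical gene are merged (groups
sharing a gene are unioned), and the remaining specific genes are replaced
by one random draw from the corresponding parent.  Founder alleles are
pairwise non-IBD, terminating the recursion; states are memoised per
pedigree.  This is the Karigl-style recursion scheme generalised enough to
serve the pairwise (kappa/Delta), detailed (delta) and X cases uniformly.

* Condensed: nine linear functionals of the state vector — the total mass,
  f_A, f_B, phi and the five second-order generalized kinships
  (phi_aab, phi_abb, phi_aabb, phi_aa;bb, phi_ab;ab) — form a fixed
  invertible 9x9 system, solved exactly by rational Gaussian elimination.
* Detailed: for each of the 15 partitions the engine evaluates the
  probability that every block is internally IBD (a coarsening event);
  Moebius inversion on the partition lattice (a unitriangular 15x15 solve)
  yields the exclusive-state probabilities.  The fixed 15-to-9 aggregation
  map is unit-tested against the condensed route, which is computationally
  independent of it.
* kappa: for pairs with f_A = f_B = 0, kappa = (Delta_9, Delta_8, Delta_7);
  if either member is inbred kappa is reported undefined.
* X: the same engine with hemizygous reduction (all draws from a male are
  one physical gene; it resolves to one maternal draw).  A male's gene is
  counted twice so the usual 9-state space applies; states unattainable
  under the pair's sexes carry probability 0 exactly (two unrelated males:
  Delta_2 = 1, the no-IBD state of the degenerate male-male space).

Exhaustive enumeration over inheritance vectors (2 bits per nonfounder) is
exponential and is therefore not the production algorithm, but it is exact
and entirely independent; it lives in the test suite as an oracle and
corroborates kinship, Delta and delta on every small fixture and on random
pedigrees with up to 6 nonfounders.

## Connecting paths and verbal descriptions

All common ancestors C of A and B are found from ancestor-or-self sets
(C may equal A or B, making one side length 0); for each C all descending
path pairs that share no node besides C are enumerated depth-first.
Wright's formula sums `(1/2)^(l1+l2+1) (1+f_C)` over these *raw* paths —
each member of an ancestral couple contributes its own term — and its exact
agreement with the recursive kinship on every pair of 200 random pedigrees
is the central cross-validation of the enumerator.

For description, raw path pairs that are identical except that their top
ancestors form the parental couple of both continuations are merged into
one *full* path (gamma = 1); the rest are *half*.  Classification: lineal
(min length 0), sibling (1,1), avuncular (min 1 < max), cousin (min > 1);
path degree `l1 + l2 - gamma`; cousinship degree `min - 1`; removal
`|l1 - l2|`.  Merged paths are grouped by (unordered lengths, gamma) —
unordered, because a pair can be, say, third cousins once removed through
ancestors four steps above A and five above B *and* through ancestors five
above A and four above B, and these belong on one line.  Lines are ordered
by path degree, ties by the shorter length, which reproduces the published
nine-line Habsburg ordering.

Vocabulary (reconstructed from the published outputs, fixed here): cousin
ordinals "first/second/third" then "4th, 5th, ..."; removal "once/twice/
N times removed"; "half" prefixes gamma = 0 sibling/avuncular/cousin
groups, while full groups carry no prefix except "Full siblings";
avuncular wording is sex-aware ("Uncle-niece", senior side first, "great-"
per extra step) with fallback "Avuncular"; lineal wording is
"Parent-child", "Grandparent", "Great-...-grandparent".  Multiplicity
words run Double..Octuple, then "9-fold".  No published output shows a
lineal or half-avuncular line, so that corner of the vocabulary is this
package's own reconstruction.  The multiplicity prefix is applied
uniformly to all types, including sibling groups.

## The IBD triangle

kappa maps to the point (kappa_0, kappa_2) in the triangle kappa_0,
kappa_2 >= 0, kappa_0 + kappa_2 <= 1.  Thompson's inadmissible region is
`kappa_1^2 < 4 kappa_0 kappa_2`; the boundary (parametrised by
kappa_0 = (1-p)^2, kappa_2 = p^2) is *included* in the admissible set, so
half siblings (1/2, 1/2, 0) are admissible.  Admissibility is a theorem
for pedigree relationships and is property-tested on random pedigrees.
The renderer shades the region rather than clipping, draws user points
inside it with a warning glyph and a log warning, and returns a manifest
(points and region drawn) so tests never compare pixels.  Of the eight
reference points, seven are computed from built-in fixtures through the
identity module; MZ twins have no pedigree encoding (a pedigree cannot
express zygosity) and are the vertex (0, 1) by definition.

## Gene-drop simulation

The Monte-Carlo oracle assigns each founder two distinct allele labels
(one for males on X), transmits alleles by fair Mendelian draws in
generation order (vectorised over replicates), classifies the pair's genes
into a condensed state per replicate, and reports frequencies with
binomial standard errors.  It emulates exactly the model underlying the
recursions — no mutation, genotyping error or linkage — so agreement
supports the algebra, not the realism of the IBD model itself.

Statistical tolerances: a single comparison uses 3 standard errors.  The
fixture-wide sweep makes ~200 simultaneous state comparisons, where a
per-comparison 3 SE rule would fail spuriously about half the time by
construction; there each fixture's phi functional (1-dimensional summary)
is held to 3 SE and the individual states to 4 SE, keeping the family-wise
false-alarm rate under ~2% at 100,000 replicates.

## Built-in pedigrees

The catalogue covers the common textbook structures, the theoretically
interesting quadruple half first cousins, the cross-generational incest
example that trips up many drawing tools (father-daughter mating,
`figS1-incest`), the teaching example `fig1-example`, and `habsburg` — the
ancestry of Charles II of Spain (29 members), transcribed once from the
historical genealogy with printed names as ids (underscores for spaces,
birth years disambiguating duplicated names).  The second-cousins fixture
uses the minimal structure compatible with the both-parents rule
(12 members).  The random-pedigree generator used by the property suites
grows up to 8 nonfounders whose parents are drawn from existing members
(complex, cross-generational inbreeding) or fresh founder couples; it
emulates structure only — no genotypes, no missing links — so passing
property tests demonstrate algebraic correctness on arbitrary structures,
not robustness to malformed real-world files (that is the parser
validation's job).

## Numerical choices and limitations

- Exact rationals everywhere in the coefficient machinery; floats appear
  only at output (default 3 decimals, matching conventional reporting) and
  in plotting.
- Deterministic ordering throughout (path enumeration sorts by length and
  label; description output is byte-identical across runs).
- Path enumeration is exponential in pedigree complexity in the worst
  case; it is instantaneous on the 29-member Habsburg branch but would
  slow on very large, deeply looped pedigrees.  The recursions themselves
  are polynomial with memoisation.
- Two-locus/linked identity coefficients, coefficients for 3+ individuals,
  genotype-based estimation, pedigree drawing and GEDCOM import are out of
  scope.
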