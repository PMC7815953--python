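# Methods

## The model

A metabolic network is a stoichiometry matrix `N` (metabolites × reactions)
with reversibility flags, a partition of metabolites into *internal*
(steady-state balanced) and *external*, and, for each external metabolite, a
direction annotation: `input` (the network can only consume it), `output`
(only produce), or `both`.  With all reversible reactions split into
forward/backward pairs, the space of realizable net conversions at internal
steady state is the polyhedral cone

```
C = { c = N v  |  v >= 0,  c_i = 0 for every internal metabolite i }.
```

The **elementary conversion modes (ECMs)** are the minimal set of conversions
such that every member of `C` is a nonnegative sum of ECMs in which no
external metabolite's production is cancelled (a *conformal* sum).  When `C`
lies in a single orthant — every external metabolite moves in only one
direction — the ECMs are exactly the extreme rays of `C`.  A bidirectional
external metabolite X breaks this: conversions through the interior of the
cone (those with net-zero X) can be elementary too.  The package therefore
splits each such X into virtual single-direction metabolites `X__in`/`X__out`
joined by one-way transports, enumerates the single-orthant cone, and nets
the two virtual coordinates back into one reported X coordinate afterwards.
A generator that uses both `X__in` and `X__out` (a pure pass-through) nets to
zero and is dropped; this loses nothing because the pass-through conveys no
conversion.

Direction annotations are treated as *descriptive*: the enumeration assumes
an `input`-annotated metabolite genuinely cannot be net-produced by the
network.  The random-network generator guarantees this by construction; for
SBML models the annotation is inferred from exchange-reaction orientation and
flux-bound signs and can be overridden per metabolite.

## Direct method

Start from `R(0)` = columns of `N` (the cone of all conversions reachable by
conical combination of reactions, steady state not yet imposed).  For one
internal metabolite i per iteration, intersect the current cone with the
hyperplane `c_i = 0`: generators partition into plus/zero/minus groups by the
sign of coordinate i, each plus/minus pair combines into a candidate with
coordinate i balanced, and a candidate is kept only if it is *not* a
nonnegative combination of the other prospective generators (an exact LP
feasibility test).  After all internal coordinates are processed, the columns
are the ECMs of the single-orthant network.

Numerical/structural choices:

* **Processing order** — by default the cheapest hyperplane first (fewest
  plus×minus pairs, recomputed each iteration); any explicit order gives the
  same final set, which the tests check by permutation.
* **Canonical rays** — every column is kept scaled to coprime integer
  entries, making deduplication exact and keeping numerators small.
* **Independent vs. sequential filtering** — redundancy tests of different
  candidates are independent (they commute), which is exactly correct when
  the starting cone is pointed: extreme rays can never be filtered.
  `cone(N)` is pointed iff no nonnegative combination of columns vanishes
  (no zero-sum cycle), checked once by LP at the start.  On a non-pointed
  input (cycles not compressed away) the implementation falls back to
  sequential removal, which is sound for any cone but order-dependent in
  which representative of a mutually-redundant group survives.
* **Final reduction** — `R(0)` need not be minimal (a reaction column may be
  a conical combination of others) and such columns are never candidates, so
  one global sequential reduction runs at the end.  For pointed cones this
  only ever removes redundant columns.

## Indirect method

The classical route: the generator representation of the start cone `C0` is,
by cone duality, an inequality representation of the dual cone `C0*`.  One
double-description (DD) run converts it into generators of `C0*`, which is an
inequality representation of `C0` itself.  Steady state is imposed by
deleting the internal-metabolite columns of that inequality matrix —
evaluating the system at `c_int = 0` — followed by removal of rows that
became zero, proportional, or conically redundant.  A second DD run yields
the extreme rays of `C`: the ECMs.

The DD implementation is incremental and exact: it starts from the whole
space (lineality basis = identity) and inserts one inequality at a time.  A
lineality vector not orthogonal to the new inequality is turned into a ray
and the rest of the representation is projected onto the new face; otherwise
rays are split by sign and adjacent plus/minus pairs are combined, with
adjacency decided by the standard combinatorial zero-set test over the
inequalities processed so far.  Insertion follows row order (lexicographic by
construction of the callers); intermediate representation sizes depend on
this order, and a configurable cap (`max_intermediate`) turns blow-ups into a
resource error naming the stage — the first DD application is the known
choke point of this route.  Non-pointed intermediate cones are expected (the
dual of a non-full-dimensional cone) and are carried as an explicit lineality
basis; a lineality vector contributes an equality, i.e. a ± inequality pair,
when the representation is swapped.

## Hide and tag

*Hiding* an external metabolite removes it from the report without breaking
steady state: it is marked internal and given free creation (if it could be
consumed), free disposal (if produced), or both.  Reported conversions are
then generally not elementally balanced, which reports mark with `??` on the
consumed and/or produced side according to the hidden metabolite's original
direction.  *Tagging* a reaction appends a virtual output-only metabolite
with coefficient +1, so the reaction's rate surfaces as an ordinary ECM
coordinate.  Tag metabolites may not themselves be hidden.

## Compression

Six ECM-preserving rules shrink the network before enumeration, ordered
cheap-structural-first and iterated to a fixpoint (each rule strictly
removes reactions and/or metabolites, so termination is guaranteed; a pass
cap of 50 is a safety net): (4) dead-end internal metabolites and their
reactions; (1) reactions that can carry no flux in any steady state (exact
LP); (5) a sole producer (or consumer) of an internal metabolite folded into
the opposite side; (3) antiparallel reaction pairs — the split image of a
reversible reaction — used to cancel one adjacent internal metabolite
everywhere; (6) zero-sum cycles, cancelled one reaction and one internal
metabolite at a time using the cycle relation to keep all folds conical; (2)
reactions that are conical combinations of others.  Rule 6 only fires when
some cycle reaction touches an internal metabolite: an all-external zero-sum
cycle (e.g. an antiparallel exchange pair) encodes genuine conversions and
is left alone.  Rules 3 and 6 overlap by construction, since a split
reversible pair is a 2-cycle; both are kept because rule 3 is cheaper and
rule 6 strictly more general.  Ties (which metabolite or reaction to cancel)
are broken by lowest index for determinism.

## Verification

Three properties characterize a correct ECM set, and all are decided with
exact LPs: (1) every ECM is realizable — some `v >= 0` with `N v` equal to
the ECM exists (the witness flux vector is returned); (2) every ECM is
elementary — no conformal nonnegative combination of the other ECMs
reproduces it, where conformal means per-coordinate sign agreement and a
zero coordinate of the target forces zero in every contributor; (3)
steady-state conversions decompose conformally into the ECM set with zero
tolerance.  A rational tolerance is available for decomposing conversions
derived from floating-point flux data (default 0; 1e-7 is a sensible value
for that use).

The ground-truth **oracle** enumerates ECMs by brute force on small networks
(caps: 12 metabolites, 15 reaction columns): for each sign pattern over the
bidirectional external metabolites it restricts the flux cone to that
orthant, enumerates its extreme rays exhaustively by active-set search over
(d−1)-subsets of the inequality rows in equality-kernel coordinates, maps
them through `N`, reduces to minimal conversion generators, and unions over
orthants.  It shares only the low-level LP/linear-algebra primitives with
the enumeration paths, none of the enumeration logic; the LP primitive is
itself cross-checked in the tests against an independent exact
basic-solution search.

## Exact arithmetic

Every coefficient, generator and LP pivot uses `fractions.Fraction`; no
floating-point value ever enters a result.  SBML doubles are converted via
their shortest decimal representation (0.1 becomes exactly 1/10), because
models are authored in decimal.  The LP core is a phase-1/phase-2 dense
tableau simplex with Bland's rule (termination guaranteed); problem sizes in
this package are tens of variables, where a dense exact tableau is faster
than any sparse cleverness.

## Synthetic networks: what they emulate and what they do not

The generator draws stoichiometric coefficients from ±{1,2,3} with a
configurable participation density, reversibility probability 0.2 and
bidirectional-external probability 0.3 by default, and redraws until the ECM
set is nonempty.  Defaults for the test harnesses (4 internal + 3 external
metabolites, 7 reactions) keep every instance within the oracle's reach, so
the cross-method equivalence statement is exact, not sampled.  These
networks emulate the combinatorial structure of metabolism (branching,
cycles, reversibility, bidirectional boundary metabolites) but not its
scale, its sparsity pattern, or biologically realistic stoichiometric
ratios; passing tests therefore demonstrate algorithmic correctness of the
enumeration, not performance claims about genome-scale models.  Published
genome-scale models are accepted through the SBML reader but are not part of
the test surface.

## Known limitations

* The indirect route's first DD application can be exponentially larger than
  the final answer; the cap surfaces this as an error rather than thrashing.
* Compression order is a heuristic; any order preserves ECMs but intermediate
  sizes differ.
* Direction annotations are trusted (descriptive); an annotation
  inconsistent with the network structure (e.g. `input` on a producible
  metabolite) makes the single-orthant assumption false and the output
  undefined.  The SBML inference derives annotations from the model's own
  exchange reactions, which keeps them consistent in practice.
* No parallel execution: candidate redundancy tests are independent by
  contract and could be distributed, but this implementation runs them
  serially.
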