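# ecmenum

Exact enumeration of **elementary conversion modes (ECMs)** — the complete,
minimal set of net substrate-to-product conversions a metabolic network can
catalyze at steady state.

## Why ECMs

A genome-scale metabolic reconstruction determines every reaction a cell can
run, and hence every *pathway* (elementary flux mode, EFM) — but EFM
enumeration explodes combinatorially, and many pathways realize the same
overall conversion of nutrients into biomass and by-products.  For questions
about a cell's capabilities — which substrates it can grow on, at which
yields, which products it can secrete, what it may do in a community — the
net conversions suffice.  ECMs are exactly those: the minimal building
blocks of all macrochemical equations of a network, typically orders of
magnitude fewer than the EFMs.  This package targets systems biologists who
have a stoichiometric model (SBML or a plain table) and want its full
conversion repertoire, exactly.

## The mathematics in brief

With all reversible reactions split so that `v >= 0`, the steady-state
conversion cone is

```
C = { c = N v | v >= 0, c_i = 0 for internal metabolites i }.
```

ECMs are the conformally non-decomposable elements of `C`: every steady-state
conversion is a nonnegative sum of ECMs in which no coordinate's production
is cancelled.  After splitting each bidirectional external metabolite into a
virtual input and output, `C` lies in one orthant and the ECMs are its
extreme rays.  Two enumeration routes are implemented, both in exact
rational arithmetic:

* **direct** — start from the cone generated by the columns of `N` and
  intersect it with one steady-state hyperplane `c_i = 0` at a time;
  plus/minus generator pairs yield candidates, and an LP-based redundancy
  (adjacency) test keeps the generator set minimal at every step;
* **indirect** — double description applied twice via the dual cone, with
  steady state imposed by deleting internal-metabolite columns of the
  inequality representation.

Around the core: ECM-preserving network **compression** (six rules), the
**hide** method (drop chosen external metabolites from the report while
keeping the whole network at steady state) and the **tag** method (surface a
reaction's rate as a virtual ECM coordinate), plus built-in **verification**
of the three correctness properties (realizability, elementarity, conformal
decomposability) and a brute-force per-orthant oracle for small networks.
See `docs/methods.md` for the full account.

## Worked example

The package ships the worked 8-metabolite network (inputs A, E, F; output
BM) as a fixture:

```sh
$ ecmenum run --fixture box3 --no-compress
2 ECMs over metabolites A, E, F, BM
  2 A + E -> BM
  2 A + F -> BM
```

Two conversions: biomass can be made from two units of A plus one unit of
either E or F.  Hiding E and F keeps the steady-state constraint on the full
network but reports only the A-to-biomass stoichiometry (the `??` marks the
hidden, possibly unbalanced, consumed side):

```sh
$ ecmenum run --fixture box3_hidden --no-compress
1 ECMs over metabolites A, BM
  2 A + ?? -> BM
```

The same from Python:

```python
import ecmenum as e

ecms, report = e.run_pipeline(e.PipelineConfig(fixture="box3", method="indirect"))
print(ecms.conversion_strings())   # ['2 A + E -> BM', '2 A + F -> BM']
```

`ecmenum run` also accepts `--model model.xml` (SBML L2/L3; externals and
their directions inferred from boundary conditions and exchange reactions)
or `--matrix stoich.csv --annotations ann.csv`, writes the ECM table with
`--out`, and `ecmenum verify --input ecms.csv --model model.xml` re-checks
a table against a model, exiting non-zero on any failed property.

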