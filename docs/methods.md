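# Methods

## Graph model and conventions

A compound is represented by its hydrogen-suppressed molecular graph: one
vertex per heavy atom, one edge per bond between heavy atoms. Bond order,
aromaticity, charge, isotopes and stereochemistry are discarded. These
conventions are not arbitrary: the bundled taxifolin worked example quotes
its descriptors over n = 22 = the heavy-atom count of C15H12O7, fixing
hydrogen suppression; and tropolone's value D = 6/9³ requires its two
oxygens to sit at graph distance 3 with every bond a single edge, fixing the
bond-order convention. Disconnected inputs (salts, mixtures) are a hard
error — the descriptors are defined for connected graphs, and silently
keeping the largest fragment would change n.

Distances are unit-weight shortest paths, computed by one BFS per vertex
(O(n·m); molecular graphs here have n ≤ ~50, so nothing faster is needed).

## The irregularity index: a resolved ambiguity

The defining phrase for t(v) — "the number of neighbours of v with distinct
degrees" — admits two readings:

* **A**: the number of distinct degree values among v's neighbours;
* **B**: the number of neighbours whose degree differs from deg(v).

The taxifolin worked example is the only authoritative disambiguator: its
internal score sum is 85.8333 under A and 79.5000 under B. A is therefore
the default everywhere; B remains selectable (`interpretation="B"`,
`--irregularity B`) for sensitivity checks.

A related numerical footnote: the quoted ζ for taxifolin (0.1773415)
divides the 4-decimal-rounded sum 85.8333 by 22²; the unrounded sum is
1030/12, giving 0.17734160. The package keeps numerators exact (integers and
`fractions.Fraction`) and only rounds on output, so both chains are
reproducible and are asserted in the tests.

## Descriptor conventions and degenerate inputs

For external vertices the score sums distances to *all* end vertices
including v itself; d(v,v) = 0, so the choice is immaterial and is documented
rather than configurable. The external numerator counts every unordered
end-pair distance twice and is therefore always even — a parity fact the
test-suite leans on (see "Reference-data curation" below). Graphs with no
end vertices (cycles) get D = 0, and graphs with no internal vertices (the
single edge) get ζ = 0, rather than erroring; whether such graphs are
meaningful inputs to the IC50 model is a modelling question, not a
descriptor one.

## The IC50 model

Predicted IC50 is a cubic polynomial in (D, ζ) with the D³ term omitted,
nine coefficients in the fixed feature order [1, D, ζ, D², Dζ, ζ², D²ζ,
Dζ², ζ³]. The bundled training table has exactly nine compounds, so fitting
is interpolation: a square linear solve. The design matrix mixes columns of
magnitude 1 down to 10⁻⁵ (D ~ 10⁻², so D²ζ ~ 10⁻⁵) and has condition number
~10⁹; the solve is done over exact rationals (sympy), with float inputs
re-read through their shortest decimal representation so that table-derived
decimals are treated as the decimals they are. With more than nine records
the model falls back to double-precision least squares. Diagnostics follow
the usual definitions: SSE = Σ residual², R² = 1 − SSE/SST about the mean of
the observed responses. Evaluating the exact interpolant in double precision
leaves SSE ~10⁻¹⁹ — numerical noise on the μM² scale.

Two coefficient provenances ship:

* **refit** (default): the exact interpolant. This is the set that
  regenerates the bundled 26-compound screening table: identical rank order
  (26/26), kojic acid's prediction to 0.14%, and the chrysin:tropolone fold
  difference of 33.91 ≈ 34.
* **printed**: the same coefficients rounded to 4 significant figures, as
  quoted in the reference source. Because predictions are small differences
  of terms of magnitude ~10⁶, the rounding shifts predictions by hundreds of
  μM near the training region (quercetin: 409 instead of 96), breaks the
  screening rank order in three places and inflates the chrysin:tropolone
  ratio to 64. It is retained for transparency and comparison only.

Negative predictions are genuine model output — the polynomial extrapolates
freely outside the descriptor region spanned by the training set, and the
screening ranking uses relative order only. They are reported unchanged with
a logged applicability-domain warning; clipping would silently reorder
nothing and hide the extrapolation.

Ranking sorts ascending by predicted IC50 (strongest inhibitor first), with
lexicographic name tie-break, ranks 1..N.

## Reference-data curation

Structures for the 26 named compounds were encoded once, by hand, from their
standard published structures and are shipped as SMILES with embedded
checksums. Recomputing descriptors from these structures reproduces the
printed tables for 17 of 26 compounds (D to all 9 printed decimals, ζ to ≥6
decimals). The remainder are provably irreproducible from *any* graph and
are flagged per entry:

* Four printed D values imply odd external numerators (205, 215, 143, 355)
  — impossible by the parity fact above; the structures give the even value
  one higher in each case.
* Four printed internal sums (tamarixetin 102.5, luteolin-7-methyl ether
  98.0, kojic acid 23.8333, xanthoxylin 29.0) match no placement of the
  compounds' substituents on their scaffolds, checked by exhaustive
  enumeration; one further ζ (0.2352) disagrees with the exact rational
  value 94/400 in the fourth decimal.
* The quercetin-3-rutinoside row simply repeats quercetin's descriptors; the
  true 43-heavy-atom structure gives different values.

The printed tables remain canonical for fitting and ranking (they are the
data the model was defined on); the flags record where structure-derived
recomputation can and cannot match them, and the tests assert both sides.

## Synthetic graphs and the oracle

The generator produces paths, cycles, stars, barbells (two triangles joined
by a path, n ≥ 6), uniform random trees (seeded Prüfer sequences) and random
connected graphs (random tree plus up to n extra non-edges), deterministically
from (family, n, seed). These are abstract test graphs, not chemistry: they
exercise arbitrary degree/eccentricity patterns but say nothing about, e.g.,
typical molecular diameters, so passing property tests demonstrates
correctness of the descriptor algebra, not chemical realism.

`oracle_activity` recomputes both descriptors with deliberately different
machinery — dense Floyd–Warshall distances (scipy) and naive per-vertex
loops — and is restricted to n ≤ 30. Tests assert exact equality of external
numerators and exact (Fraction) equality of internal numerators on 200
seeded random graphs, plus hand-derived closed forms: stars K_{1,k} have
D = 2k(k−1)/(k+1)³ and ζ = (1/k)/(k+1)², cycles C_n have D = 0 and
ζ = ⌊n/2⌋/(2n), both asserted for all sizes up to 12.

## Numerical and formatting choices

Descriptors are written to CSV at 9 decimal places and predictions at 7,
mirroring the reference tables so diffs are mechanical; full precision is
always available programmatically. All randomness is seeded and every
pipeline is deterministic: identical inputs give byte-identical outputs.

## Known limitations

* The training set is nine compounds; the exact-interpolation "perfect fit"
  has zero residual by construction and no predictive-uncertainty estimate.
  No cross-validation or regularisation is attempted, matching the model's
  definition.
* The model is specific to the flavonoid-like descriptor region; predictions
  far outside it (most of the screening set) are extrapolations meaningful
  only as a ranking signal.
* Descriptors are 2D-topological only: tautomers, protonation states and 3D
  geometry are out of scope.
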