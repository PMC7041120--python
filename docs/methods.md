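# Methods

## Model

A regulatory network is a signed directed graph with at most one edge per
ordered gene pair and no negative self-edges. Gene `i` follows the switching
system

    dx_i/dt = -γ_i x_i + Λ_i,    Λ_i = Π_e σ±_e(x_src(e)),

one step function per input edge: σ⁺ returns `U_e` above the threshold
`θ_e` and `L_e` below (σ⁻ mirrored), with `0 < L_e < U_e` and `θ_e, γ_i > 0`.
Logic is restricted to pure products of single-edge terms — the form of every
node in the EMT and toggle-switch circuits. Product-of-sums logic is
deliberately out of scope: products become *linear* constraints after a log
transform, which is what makes the region enumeration exact and cheap
(general logics would need cylindrical algebraic decomposition).

The negative-self-edge exclusion is structural, not cosmetic: the production
term of gene `i` is then constant across every face of the phase-space grid
perpendicular to `x_i`, so each face is crossed in exactly one direction and
the state transition graph is well defined. Positive self-edges are allowed
by the framework (the face rule is evaluated per cell side and remains
consistent by monotonicity); the study networks contain none.

## Phase space and state transition graph

A gene with `p` out-edges carries `p` thresholds on its axis; cells of the
resulting grid are labeled by the count of thresholds below each coordinate.
The EMT circuit discretizes to a 4×4×3×2×2×3 grid of 576 cells in gene order
(Zeb1, Snail1, miR200, miR34a, TGFβ, Ovol2). On the face at threshold rank
`k` of gene `i`, the edge points upward from the lower cell iff the region's
sign pattern puts Λ_i (at that cell's input combination) above the
decay-scaled threshold; downward otherwise. Cells with all faces incoming
get a self-edge. Construction is vectorized over the whole grid; a full EMT
state transition graph plus Morse graph costs ≈1.5 ms, which is what makes
10⁴-address ensembles a desk-scale computation.

The Morse graph keeps the recurrent components (strongly connected
components containing an edge, via scipy's sparse condensation; networkx
recomputes them independently in the test suite). Annotations: `FP` for a
self-looped singleton, `XC` for a larger component with at least one
constant coordinate, `FC` otherwise — `FC` is defined for closure and has
never been observed for these networks, consistent with the survey's finding
that all attractors are fixed points. A component is stable iff no other
recurrent component is reachable from it; since every terminal component of
the condensation is recurrent, this equals "no outgoing condensation edge".

## Factor parameter graphs

For a gene with `q` inputs and `p` outputs, a candidate region is a
threshold ordering plus, per threshold, the set of input combinations whose
Λ exceeds it. Because `L_e < U_e`, each such "above" set must be an up-set
of the Boolean lattice `{L,U}^q`, and the `p` sets must be nested; the
search therefore enumerates nested chains of monotone cuts (3/6/20 cuts for
q = 1/2/3) instead of the raw `2^(p·2^q)` sign patterns. Each chain is then
certified by a linear program in log coordinates: variables
`log L_e, log U_e` and one free variable per decay-scaled threshold,
maximizing a common slack margin over all strict inequalities. The region is
realizable iff the optimal margin is positive (threshold 1e-9; margins at
the optimum are O(1), so the tolerance is purely numerical). Feasibility is
independent of which out-edge owns which rank, so chains are solved once per
(q, p) signature and reused across orderings — Zeb1's 4242-region graph
enumerates in about two seconds. A brute-force path that LP-filters *all*
raw patterns exists for small signatures and serves as the enumeration
oracle in tests.

Canonical region order (threshold orderings lexicographic by out-edge index,
then sign pattern as an ascending integer) reproduces the conventional
A1…A6/B1…B6 listing for Ovol2 and gives stable addresses for seeded
sampling. Factor-graph adjacency joins regions whose inequality sets differ
in exactly one sign: a single pattern-entry flip at fixed ordering, or an
adjacent transposition of two thresholds whose sign rows coincide (the only
transposition crossing a single codimension-1 wall).

**Essentiality.** A region is essential iff (a) every threshold has some
combination above and some below it, and (b) for every input edge there are
two combinations differing only in that edge with different sign columns.
Failing (a) silences an out-edge, failing (b) an in-edge; either way the
dynamics collapse to a subnetwork's. For Ovol2 this leaves exactly A4 and
B4. Condition (b) is the natural formalization of "the edge carries no
information"; for single-threshold nodes it is implied by (a) only when
q = 1, and tests verify it strictly shrinks the set for every multi-input
EMT gene.

**Layers.** A region's layer is 1 + the number of (threshold, combination)
pairs with Λ above — the count of actuation inequalities satisfied, a proxy
for the gene's qualitative expression level. This rule was chosen because it
is the unique simple grouping that yields the expected layer counts for all
four surveyed genes (5 for Ovol2 and TGFβ, 13 for Snail1, 25 for Zeb1) and
puts the all-below/all-above regions alone in the extreme layers; a
graph-distance layering of the factor graph would be the main alternative
reading and agrees on those anchors.

## Product graphs and sampling

The parameter graph is the product of the factor graphs; sizes are exact
Python integers end to end (the EMT full product is 21,990,528,000 and the
all-essential product 21,563,136 — a 1020-fold reduction). Addresses decode
from flat indices by mixed radix in gene order. Uniform sampling draws each
factor independently; a survey restriction pins one gene's component to a
layer of its factor graph. Exhaustive iteration exists behind a work bound
(default 10⁶) because a full EMT scan is cluster-scale.

The surveyed ensembles are "X-general": gene X full, all other genes
essential — the construction that isolates how dynamics respond to X's
actuation level while the rest of the network stays fully functional. The
intersection of the four X-general graphs is the essential graph.

## EMT phenotyping and surveys

A stable fixed point is epithelial iff its label matches (0,0,\*,\*,\*,2)
and mesenchymal iff (3,3,\*,\*,\*,0). Intermediate states are graded by the
taxicab distance of the (Zeb1, Snail1, Ovol2) projection from the E corner
with Ovol2 reversed — the unique reading that partitions the 4×4×3
projection cube into nine diagonals; distances from E and M always sum
to 8.

Default survey conditions: 2000 addresses per layer, seed 0, proportions
over parameter nodes (each region weighted equally, not by Lebesgue volume —
the survey's claims are about counts of qualitative parameter regimes). Per
layer the survey records monostable-E/M, E/M-present, per-diagonal
occupancy (monostable and any), the k-stability histogram, and any stable
non-FP component (never seen). At n = 2000 a proportion's three-standard-
error half-width is ≤ 3.4 percentage points, which is the tolerance used in
tests together with integer-percent rounding. Sampled domain occupancy is
reported as a lower bound on the number of the 576 cells that can host a
stable fixed point; the exact occupancy counts require full X-general scans
(~10⁸ Morse graphs) and are out of desk scope.

## Parameter instantiation and the ODE oracle

The slack-LP optimum exponentiates to a concrete interior parameter point of
any region (decay rates 1, thresholds `exp(τ_k)`); optional jitter within an
eighth of the certified margin yields distinct interior points, and reading
the sign pattern back off the numbers must return the original region. Two
independent numeric checks close the loop:

- a numeric state-transition oracle evaluates every step function at cell
  representative points (geometric midpoints between consecutive thresholds,
  half the lowest / twice the highest threshold at the boundary) and must
  reproduce the combinatorial graph edge-for-edge on a corpus of random 2–3
  gene networks;
- a stiff-safe Hill ODE (coefficient ≥ 50, LSODA, rtol 1e-8, steady state at
  derivative norm < 1e-6·(1+state norm), bounded ratio evaluation to avoid
  overflow) started at each predicted stable-FP cell center must settle in
  that cell. Agreement is checked to be monotone in the Hill coefficient
  (violations at 50 must not appear at 200); the minimal coefficient at
  which a region's dynamics match is region-dependent and treated
  empirically. The oracle deliberately checks stable-FP containment only:
  unstable structure is not claimed to be observable.

## What the generators do and do not emulate

The random-network corpus exercises every code path of the combinatorial
pipeline on exhaustively checkable instances, but its networks are tiny
(≤3 genes) and its parameters are LP-interior points, not biologically
calibrated rates. Passing tests therefore establish the correctness of the
combinatorial reduction and its equivalence to steep-Hill dynamics — not
that real EMT kinetics occupy any particular region, and not how dynamics
behave at moderate Hill coefficients, near region boundaries, or under
logics beyond pure products.

## Known limitations

- Pure-product logic only; product-of-sums is reserved in the data model but
  rejected at parse time.
- Nodes with no inputs or no outputs have no factor graph (none occur in the
  study networks).
- Stochastic survey numbers carry sampling error by design; exact
  full-enumeration panel heights and occupancy counts are out of scope.
- The survey treats parameter regions as equiprobable; no claim is made
  about the measure of biologically realizable parameters.
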