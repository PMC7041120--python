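# switchgraph

Combinatorial dynamics of switching-system gene regulatory networks, applied
to multistability in the epithelial–mesenchymal transition (EMT).

## The problem

Cells transitioning between epithelial (E) and mesenchymal (M) phenotypes can
stall in intermediate E/M states, with consequences for development, wound
healing and cancer metastasis. The core regulatory circuit — Zeb1, Snail1,
miR200, miR34a, TGFβ and Ovol2 wired by 12 activating/repressing edges — has
dozens of unknown kinetic parameters, so classical bifurcation analysis (one
or two parameters at a time) cannot say how prevalent multistability is
*across* parameter space.

`switchgraph` takes the switching-system route instead. Each gene obeys

```
dx_i/dt = -γ_i x_i + Λ_i(σ±(x_j), ...),
```

where each input contributes a step function σ⁺/σ⁻ jumping between a low
level `L_ij` and a high level `U_ij` at a threshold `θ_ij`, and Λ_i is the
product of its inputs. Because the nonlinearity is piecewise constant, the
positive parameter orthant (dimension `n + 3k` for `n` genes and `k` edges;
42 for the EMT circuit) decomposes into **finitely many inequality regions**.
Within one region the dynamics reduce to a **state transition graph** on the
grid of phase-space cells cut out by the thresholds, and its condensation
onto recurrent components — the **Morse graph** — lists every attractor:
fixed points `FP(s_1,…,s_n)`, unstable partial cycles `XC`, and (never
observed here) full cycles `FC`.

The library provides, module by module:

- `network` — parse/validate networks in a one-line-per-gene text format,
  discretized phase space and cell adjacency;
- `factor` — per-gene **factor parameter graphs**: every realizable
  combination of threshold ordering and production-vs-threshold sign pattern,
  decided by an exact log-space linear feasibility test, with essentiality
  and layer classification;
- `product` — exact big-integer product parameter graphs (full, essential,
  or single-gene-general), mixed-radix indexing, seeded uniform sampling;
- `dynamics` — fast STG construction from the combinatorial wall rules and
  Morse graphs via strongly-connected-component condensation;
- `emt` — E/M/intermediate phenotyping of fixed points on the nine diagonals
  of the (Zeb1, Snail1, Ovol2) projection, layered multistability surveys,
  k-stability spectra, domain occupancy, CSV/JSON reports;
- `fixtures` — builders for the EMT and toggle-switch networks, random small
  networks, exact parameter instantiation inside any region, and a steep-Hill
  ODE oracle.

## Worked example

```bash
python examples/03_parameter_graph_sizes.py
```

prints

```
EMT network: 6 genes, 12 edges
parameter-space dimension: 42
phase-space cells: 576

Zeb1   :  4242 regions (2292 essential), 25 layers
Snail1 :   300 regions (  84 essential), 13 layers
miR200 :    40 regions (  14 essential),  9 layers
miR34a :     6 regions (   2 essential),  5 layers
TGFb   :     6 regions (   2 essential),  5 layers
Ovol2  :    12 regions (   2 essential),  5 layers

full parameter graph:      21,990,528,000 nodes
essential parameter graph: 21,563,136 nodes
reduction factor:          1,020x
```

Each line is one gene's factor parameter graph: the count of realizable
inequality regions for that gene's slice of parameter space, how many are
*essential* (every edge still carries information), and how many actuation
*layers* (qualitative expression levels) they span. The product of the six
counts is the number of parameter regions of the whole circuit — about
22 billion, shrinking a thousand-fold when restricted to essential regions.

`examples/04_emt_layer_survey.py` then samples Morse graphs per TGFβ layer
and shows the biology: the E state exists in *every* sampled parameter node
at low TGFβ, E and M always coexist at intermediate TGFβ, and at maximal
TGFβ the E state still survives in ~20% of parameter nodes while complete
EMT (monostable M) is guaranteed in only ~25%. Every attractor encountered
is a fixed point; oscillations occur only as unstable components.

The other examples cover the toggle switch (9 parameter regions, central
bistability), the twelve Ovol2 inequality regions, and the Hill-ODE
cross-check of the combinatorial predictions.

A thin CLI wraps the same calls, e.g.
`switchgraph pg-size --network emt --mode essential` or
`switchgraph survey --gene TGFb --n 2000 --seed 0 --out report/`.

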