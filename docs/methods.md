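# Methods

`petsorb` models the batch adsorption of two rifamycin antibiotics —
rifampicin (RIF) and rifaximin (RIX) — onto recycled PET fibers, and wraps
the full computational workflow of such a study: a mechanistic simulator of
the experimental campaign, classical isotherm/kinetic/thermodynamic fits,
neuroevolution of a feed-forward surrogate of removal efficiency,
surrogate-based process optimization, and Shapley-value attribution.

## The batch mass balance

Every quantity derives from the batch mass balance between the initial
concentration `c0` (mg/L) and the residual concentration `c` (mg/L) in a
volume `V` (default 0.025 L) contacted with adsorbent mass `m`:

    q = (c0 - c) * V / m        (capacity, mg/g)
    R = 100 * (c0 - c) / c0     (removal, %)

`AdsorptionRecord` enforces these identities to 1e-6 relative whenever a
record carries more than one of `c`, `q`, `R`; inconsistent records are
rejected at construction, not at analysis time.

## The synthetic campaign

No raw dataset is publicly deposited for this system, so the generator
emulates the one-factor-at-a-time (OFAT) campaign itself: for each
antibiotic, one factor is scanned while the others stay at the base point
(pH 2.0, dose 0.4 g/L, 180 min, 21.1 mg/L, 22 °C), over pH 2.0–6.5,
dose 0.4–20 g/L, time 5–1440 min, c0 4–67 mg/L and T ∈ {10, 22, 50} °C —
98 points in total across both antibiotics, matching the scale of the
97-experiment campaign it stands in for. Scan levels beyond the stated
endpoints (interior pH/dose/c0 levels, log-spaced interior times) are our
choice; the exact original design is not tabulated anywhere, so the grid is
an emulation, not a replica.

Each simulated capacity is a product of four mechanistic factors:

1. **Depletion-coupled Langmuir equilibrium.** The isotherm
   `q = q_max·K_L·c/(1+K_L·c)` is solved *jointly* with the batch mass
   balance `c = c0 − q·dose`, i.e. the positive root of
   `K_L·dose·q² − (1+K_L·c0+q_max·K_L·dose)·q + q_max·K_L·c0 = 0`.
   This is what makes q fall and R rise as dose grows, the signature
   trade-off of batch experiments; evaluating the isotherm at fixed `c0`
   would miss it entirely.
2. **Van't Hoff temperature correction.**
   `K_L(T) = K_L_ref·exp(−(ΔH/R)(1/T − 1/T_ref))` with `T_ref = 295.15 K`.
3. **Pseudo-second-order kinetics.** The fractional approach to
   equilibrium after contact time t is `k₂·q_e·t/(1+k₂·q_e·t)`.
4. **pH attenuation.** `exp(−λ·(pH−2))`, anchored at the most favorable
   pH 2. The decay constants (λ = 0.08 for RIF, 0.01 for RIX) are
   synthetic calibration constants chosen so that RIF loses capacity
   markedly with pH while RIX is nearly pH-insensitive; only endpoint
   behavior is documented for the real system, not a functional form.

Default mechanistic constants are the fitted values for this system:
q_max 44.84 / 15.63 mg/g, K_L 0.0731 / 0.1141 L/mg, ΔH 0.41 / 0.07 kJ/mol,
k₂ 0.0019 / 0.0031 g/(mg·min) for RIF / RIX. Measurement error is
multiplicative Gaussian with CV 5% by default (spectrophotometric error
scales with signal); capacities are truncated so `q ≥ 0` and
`c_eq ∈ [0, c0]`.

**What the generator does not emulate:** co-solute (ionic-strength)
effects, desorption, adsorbent aging, systematic instrument drift, and any
interaction between factors beyond what the multiplicative mechanism
implies. Tests passing on this generator therefore certify the *estimators*
(fits recover known parameters, the optimizer finds known optima), not the
field accuracy of the mechanism itself.

One known self-inconsistency is accepted rather than patched: because the
kinetic fraction increases with `q_e` (hence with `c0`), simulated removal
at the 180-min base time *rises* slightly over c0 ≈ 4→12 mg/L before
falling; the "higher concentration, lower efficiency" trend holds from
12 mg/L upward and as an overall negative rank correlation, and that is
what the tests assert.

## Model fitting

Isotherms (Langmuir, Freundlich `q = K_F·c^(1/n)`, Temkin `q = B·ln(A_T·c)`)
and kinetics (PFO `q_e(1−e^(−k₁t))`, PSO) are fitted by bounded nonlinear
least squares (`scipy.optimize.curve_fit`), never by linearized regression —
linearizations (Lineweaver–Burk, log–log, semi-log, half-time heuristics)
serve only as deterministic initializers. Bounds are positivity with
`q_max ≤ 10·max(q_obs)`. Goodness statistics: `R² = 1 − SSE/SST`,
`RMSD = √(SSE/n)`, `χ² = Σ(obs−pred)²/pred` over positive predictions.
Model selection is highest R², ties by RMSD then χ².

The intraparticle-diffusion model is fitted piecewise in `(√t, q)` space
with two regions; the breakpoint is the split (≥ 3 points per side)
minimizing the pooled SSE of the two ordinary regressions, scanned
exhaustively. On exactly-linear data every split ties and the first
admissible one is kept. The region-II intercept is reported in mg/g (it is
an adsorbed amount, whatever unit convention tables use).

Thermodynamics uses the standard sign convention throughout:
`ΔG⁰ = −RT·lnK`, van't Hoff slope `−ΔH⁰/R`, intercept `ΔS⁰/R`, and the
per-temperature identity `ΔS⁰ = (ΔH⁰ − ΔG⁰)/T`. K values are taken as
supplied (dimensionless by convention); no unit conversion is attempted,
because ΔG is only defined up to the standard-state choice implicit in K's
units and the per-temperature K values behind published ΔG tables for this
system are not available.

## Neuroevolution of the surrogate

The surrogate maps seven min–max-normalized features (pH, dose, time, c0,
temperature, one-hot RIF, one-hot RIX) to removal %. Architecture space:
1–5 dense hidden layers of 1–20 ReLU units, linear output, L1 kernel
penalty 0.01. Training is full-batch Adam (lr 0.05) on MSE + L1, with a
0.2 validation split, early stopping (patience 20, max 200 epochs) and
best-validation weight restoration. The network is plain numpy: at these
data sizes (tens of rows) full-batch numpy training is faster than any
framework round-trip and bit-reproducible under a seed.

The search is DE/current-to-best/bin over an 8-gene genome in `[0,1]⁸`
(1 layer-count gene, 5 width genes, plus the individual's own F and Cr):

    v = x_i + F·(x_best − x_i) + F·(x_r1 − x_r2)

with binomial crossover (one forced donor gene), clip repair to the box,
and greedy `≤` selection. F and Cr self-adapt jDE-style: initialized at
0.5/0.9, each resampled uniformly (F ∈ [0.1,1], Cr ∈ [0,1]) with
probability 0.1 when the individual reproduces, and inherited only if the
trial survives. The population updates in place, so an accepted trial can
serve as "best" within the same generation — this asynchronous variant
measurably accelerates convergence at small budgets and is the package's
deliberate choice. Fitness is the final penalized training loss (a config
switch to pure MSE is deliberately absent: the penalty is part of the loss
being optimized, and using the same scalar for selection keeps the search
consistent with training). Decoded topologies are cached per run, since
the topology and training seed fully determine the trained network.

Width genes beyond the decoded layer count are silently ignored ("junk
DNA"), which keeps the genome fixed-length under a varying layer count.
Reference-scale searches use population 20 (≈2.5× genome dimension,
standard DE practice), 30 generations, 10 independent runs; tests and the
acceptance script run scaled-down searches (population 10, 6 generations,
1–3 runs) that already reach R² ≥ 0.9 on the synthetic campaign — the
guarantees asserted are about the search mechanism, not a particular
budget.

## Process optimization and attribution

Process optimization reuses the same DE engine over the 5 continuous
conditions normalized to `[0,1]⁵` (the antibiotic one-hot held fixed),
maximizing the surrogate's predicted removal; results are decoded to
original units and are always inside the experimental bounds (clip
repair). The *reported* optimum removal is clipped to the physical
[0, 100] % range. **Limitation:** the OFAT campaign never visits
combined-extreme conditions, so the surrogate is unconstrained there and
the optimizer can exploit extrapolation artifacts (optima at implausible
corners with predicted removal at the 100% cap). This is inherent to
surrogate optimization on OFAT designs, and is surfaced rather than
masked; sanity-check optima against the mechanistic expectation (acidic
pH, low concentration).

Shapley attribution treats features as players whose coalition value is
the model prediction with out-of-coalition features set to a single
background reference (training-set means; the one-hot pair set to the
analyzed antibiotic, and attributed as one grouped player). With ≤ 7
players the 2⁷ coalitions are enumerated exhaustively, so the efficiency
axiom `Σφ = f(x) − f(background)` holds to machine precision; a
permutation-sampling estimator of the same functional is provided as a
cross-check and for larger player counts. A single-reference background
keeps the enumeration exact; richer background distributions would average
these attributions over references.

Under the synthetic OFAT conditions the *ordering* of feature importances
is seed-dependent: dose dominates strongly, while the pH and c0
attributions are of comparable magnitude (exact Shapley applied to the
mechanistic model itself gives mean |φ| ≈ 1.9 vs 1.4 %-points at the
default design). The robust, mechanism-backed attribution findings —
asserted in tests — are directional: high initial concentration receives a
negative attribution, and the optimizer prefers acidic pH and low c0.

## Numerical and reproducibility choices

- Single master seed everywhere; every stochastic stage draws a child seed
  from it (`numpy` Generator), so full pipeline runs are bit-reproducible.
- Train/test split is `floor(0.7·n)` by seeded permutation (97 → 67/30).
- Min–max normalization stores its bounds and is an exact bijection;
  constant continuous columns are rejected rather than silently mapped.
- Degenerate inputs fail loudly: non-finite training loss aborts with the
  topology named; constant kinetic series, zero-variance observations and
  sub-minimal point counts raise typed errors before any fitting.
- MAPE is reported as a fraction (0.18, not 18%).
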