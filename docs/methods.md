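# Methods

`biapath` models the conversion of L-DOPA into the benzylisoquinoline
alkaloid precursor tetrahydropapaveroline (THP) by three enzyme pathway
topologies, and provides the surrounding quantitative machinery: Monte-Carlo
parameter ensembles, Michaelis–Menten characterization of bifunctional
DHPAAS variants, deterministic mass/stoichiometry bookkeeping, and
active-site signature classification of AAAD-family sequences. This note
records the models, the defaults, and the design decisions behind them.

## Pathway model

State variables (all mM, time in hours): L-DOPA `S`, dopamine `DA`, DHPAA
`AL`, THP `T`, plus two cumulative bookkeeping terms, `fed` (L-DOPA
delivered by the feed) and `drained` (DHPAA lost to side reactions). THP
forms by spontaneous Pictet–Spengler condensation of one dopamine with one
DHPAA, so one THP carries two DOPA equivalents. The combination
`S + DA + AL + 2T + drained − fed` is exactly conserved by the ODE
right-hand side; its residual along a trajectory is the model's primary
regression diagnostic (target < 1e−6 relative to total input, typically
~1e−12 at the default tolerances).

Topologies:

* **DDC–MAO (nonsymmetrical)** — DDC decarboxylates S→DA; MAO oxidises
  DA→AL. MAO is promiscuous, so a fixed competing-amine pool inhibits it in
  every MAO model.
* **DDC–DHPAAS (symmetrical)** — DDC produces DA and DHPAAS produces AL in
  parallel from S.
* **Single bifunctional DHPAAS** — one enzyme supplies both products,
  partitioned by `phi_aldehyde` ∈ [0,1] (the fraction of total flux through
  the aldehyde branch; the measured "% DHPAAS activity" of a variant ÷ 100).

Rate laws. All enzymatic velocities are irreversible Michaelis–Menten with
competitive inhibition, `v = Vmax·S/(Km·(1+Σ I/Ki) + S)`. The supplementary
equations of the original analysis are not public, so these are the
simplest forms consistent with "competitive inhibition" for MAO and with
product feedback inhibition; they are declared model decisions, not
reproduced equations. When feedback is enabled: dopamine inhibits DDC (and
the DHPAAS decarboxylation branch via the shared site), dopamine and DHPAA
inhibit DHPAAS, DHPAA inhibits MAO. THP itself exerts no feedback (nothing
in the source system indicates it). Condensation is elementary second-order
mass action `k_cond·DA·AL`; DHPAA drain is first-order `k_drain·AL` (the
minimal model for loss of a reactive aldehyde with no mechanism specified).
The bifunctional enzyme is one Michaelis–Menten site whose velocity is
split `phi : (1−phi)` — one active site, one substrate, constant partition.
H2O2, CO2, NH4+ and O2 are not state variables: they do not feed back on
the modelled dynamics (O2 assumed non-limiting), and the cumulative
aldehyde flux recovers H2O2 post hoc if needed.

Feeding. L-DOPA enters at a constant `feed_rate` until the cumulative cap
(`feed_cap`, default 100 mM) is delivered. The switch is event-aware: the
integrator runs with an event on `fed == feed_cap`, stops at the crossing,
pins `fed` to the cap, and restarts without feed — so the cap is never
overshot and the conservation ledger stays exact.

Solver. `scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 1e−8,
atol 1e−10, dense output evaluated on a uniform 501-point grid over
[0, 50] h by default. Integration failure raises a `SolverError` carrying
the solver diagnostics; tiny negative concentrations from round-off
(< 100·atol) are clipped to zero, anything larger is an error.

Yield. `thp_yield_pct = 100·2·T(t_end) / (S(0)+DA(0)+AL(0)+2·T(0)+fed_total)`
— a molar yield on the DOPA-equivalent basis, which reproduces the worked
conversions (9.45 µM THP from 1 mM L-DOPA → 1.89%; 219 µM from 1.875 mM →
23% at two significant figures) and is bounded by [0, 100] by conservation.

A structural property worth noting: for the single-enzyme pathway with
fixed total velocity and no drain, the yield over a scan of
`phi_aldehyde ∈ {0.05,…,0.95}` is symmetric about and maximised at
phi = 0.5 — the quantitative form of the observation that balancing the
two condensation partners is what matters.

## Monte-Carlo ensembles

Each scenario draws the named parameters independently per iteration —
uniform on a linear scale, log-uniform for parameters whose plausible span
exceeds an order of magnitude (Km, Vmax, Ki, k_cond, k_drain) — integrates
0–50 h, and records the yield. Draws follow the listed range order with a
named `numpy` Generator (PCG64), so a seed fully reproduces an ensemble;
scenario comparisons spawn independent child streams from one master
`SeedSequence`. Failed integrations are excluded and counted, never
imputed; >1% failures flags a warning, 100% is a hard error. Quartiles use
the linear-interpolation percentile convention.

The published parameter table behind the original 10,000-iteration
ensembles is not public, so the shipped `fig2-grid` preset is an explicit
stand-in with literature-plausible ranges; the ensemble layer is therefore
validated on *ordering* claims, not median values:

| parameter | range | scale | rationale |
|---|---|---|---|
| DDC, DHPAAS Vmax | 1–100 mM/h | log | soluble, well-expressed PLP enzymes |
| MAO Vmax | 0.05–5 mM/h | log | membrane flavoenzyme, poor heterologous specific activity |
| all Km | 0.01–1 mM | log | spans the measured 41.7 µM DHPAAS Km |
| all Ki | 0.01–1 mM | log | product inhibition of the same site class |
| k_cond | 0.01–1 mM⁻¹h⁻¹ | log | spontaneous Pictet–Spengler is slow at culture pH |
| k_drain | 0.1–10 h⁻¹ | log | DHPAA is a highly reactive aldehyde |
| feed_rate | 0.5–4 mM/h | linear | reaches the 100 mM cap within 25–200 h |
| amine_pool | 20 mM (fixed) | — | E. coli polyamine pool competing at MAO |

Under this table the qualitative comparisons hold with margins well above
median sampling noise at 200 iterations per scenario across independent
seeds: the symmetrical pathway outyields the MAO pathway once drain and
feedback are active (feedback self-balances the parallel branches while
throttling the serial MAO route at its first step), and enabling drain
lowers the median within both topologies. Default iteration count for
exploratory runs is 10,000; the shipped analyses and checks use 200–500 per
scenario, which keeps the full grid under a minute per seed while leaving
the orderings stable.

## Enzyme kinetics

`fit_mm` fits `v = Vmax·S/(Km+S)` by nonlinear least squares
(`scipy.optimize.curve_fit`, positivity bounds, Vmax₀ = max rate,
Km₀ = median substrate), with `kcat = Vmax/E₀` when the enzyme content is
given (for specific activities in nmol·min⁻¹·mg⁻¹, E₀ is nmol enzyme per mg
protein). Datasets need ≥4 distinct substrate levels; the default synthetic
grid is an 8-point 2-fold dilution series centred on Km.

Outliers: iterative internally-studentized-residual elimination (hat matrix
from the fit Jacobian), removing the single worst point per refit while
|r| > 3, capped at 20% of the data. The original analysis names outlier
elimination without an algorithm; this is a standard, fully specified
substitute, so published CI endpoints are checked only by coverage, not
point equality.

Confidence intervals are profile likelihood at the SSR F-threshold
`SSR(θ) = SSR_min·(1 + F(1, n−2; 0.95)/(n−2))` — chosen over the asymptotic
normal approximation because measured Km intervals of this assay class are
visibly asymmetric. Profiling Km is cheap (the conditional Vmax is linear,
hence closed-form); profiling Vmax uses a bounded 1-D minimisation over
log Km. Bounds are bracketed geometrically and solved by Brent's method; a
profile that never crosses the threshold is flagged unbounded rather than
silently truncated, and a numerically perfect fit collapses the interval.
Coverage at the nominal 95% level runs at ~91–92% over 200 synthetic
replicates with 5% relative noise and n = 16 — within the expected band for
profile intervals at this n.

The bifunctional partition is
`pct_aas = 100·v_aas/(v_aas + v_ddc)`, reported at two significant figures
(the convention of the published table): the four measured Vmax pairs give
95, 67, 22 and 5.9% synthase flux from wild type to triple variant.

## Chemistry bookkeeping

Embedded IUPAC 2021 standard atomic weights and principal-isotope
monoisotopic masses; electron mass 0.000548579909 u. Formulas are parsed
from Hill notation with strict validation (unknown symbols and zero counts
rejected) and round-trip canonically. Adduct m/z adds/removes hydrogen
*atoms* then corrects by one electron mass per unit charge; `[M−3H]+` means
loss of three H atoms then one electron — the protonated quinone of the
4H-oxidised catechol — which reproduces the observed oxidised-THP ion at
m/z 284.0917. A consequence of the electron bookkeeping:
mz(M+H) − mz(M−H) = 2 proton masses (2×1.0072765 u) exactly.

µM↔mg/L conversions use the average mass (THP C16H17NO4: 287.315 g/mol).
Core operations return full precision; printed-value reproduction applies
significant-figure rounding at the caller. One printed pair (9.45 µM,
2.71 mg/L) carries independent rounding in both numbers — the exact product
is 2.7151 — so checks compare it at one unit in the last printed digit.

## Residue signatures

Queries are globally aligned to a numbering reference with
`Bio.Align.PairwiseAligner`: BLOSUM62, gap open 10, extend 1 (a gap of
length L scores −(10+L)), end gaps penalised, ties broken by the aligner's
deterministic enumeration order. The alignment layer is verified against an
exhaustive all-paths enumeration oracle on short sequences. Reference
positions are 1-based; a query gap at a triad position yields an
undetermined marker.

Classification rule: (F79, Y80, N192) → DHPAAS-like; (Y79, F80, H192) →
DDC-like; any other combination of F/Y at 79–80 with N/H at 192 →
intermediate, with a note recording which positions match which archetype
(e.g. the Y79–Y80 motif of some Drosophila isoform-X2 sequences); gaps, X,
or non-archetype residues → undetermined. No quantitative activity
prediction is attached to mixed triads — the mapping from triad to
partition percentage is only anchored at the measured variants.

The packaged reference is a labelled synthetic stand-in (random sequence
with the synthase triad planted); real accession numbering works the same
way if the user supplies the sequence.

## Synthetic data

Generators are pure functions of their spec and seed. Noise is
multiplicative (CV-based) throughout, because fluorometric and LC-MS signal
error scales with intensity; coverage targets are defined under that model.
Truth sidecars accompany every generated dataset. What the generators do
*not* emulate: substrate inhibition at high L-DOPA (observed but
unquantified in the source system), instrument drift or plate effects,
compartmentalization/transport, sequence indels in the motif families
(substitutions only, by default), and any raw chromatogram structure.
Passing tests therefore demonstrate correctness of the estimators and
simulators under the stated model, not robustness to those real-data
features.

## Problem sizes and determinism

Default shipped analyses use: 501-point trajectories over 50 h; 200–500
Monte-Carlo iterations per scenario; 200 replicates for CI coverage;
200-sequence motif families. Every stochastic step takes an explicit seed,
and the acceptance script threads one `--seed` through all of them.

## Known limitations

* Rate-law forms and feedback targets are declared modelling choices; if the
  original supplementary equations differ, medians (not the ordering logic)
  would shift.
* The ensemble validates orderings only; absolute yield distributions are
  functions of the stand-in ranges.
* Profile CIs assume i.i.d. Gaussian residuals; replicate correlation is
  not modelled.
* `percent_aas` compares two maximal velocities measured by different
  assays (H2O2 fluorometry vs. initial dopamine rate); any systematic
  inter-assay bias propagates directly into the partition.
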