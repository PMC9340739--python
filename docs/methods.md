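# Methods

`pahflow` implements an integrated model chain for asking how international
trade redistributes the health burden of polycyclic aromatic hydrocarbon
(PAH) emissions: an emission inventory, environmentally extended
multi-regional input-output (EE-MRIO) accounting, a linear source-receptor
transport step, a lifetime lung-cancer risk model, and structural
decomposition of temporal change.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Emission inventory

Sector emissions are a sum of products over combustion and process sources,

    E_im = Σ_k FC_im^k · EF_im^k + Σ_p AR_im^p · EF_im^p ,

with fuel consumption `FC` (by energy type k), process activity rates `AR`
(product output of process p) and matching emission factors `EF`.  The
inventory is linear in every input, which the tests assert directly.
Natural sources (wildfire, deforestation) are carried as a per-region
scalar: they are gridded into the base concentration scenario but excluded
from the MRIO linkage, because they are not tied to economic activity.

Emission-factor uncertainty is propagated by Monte Carlo: each factor is
multiplied by an independent lognormal draw with median 1 and log-scale
sigma (default 0.3, a factor-~2 95% spread typical of PAH emission
factors), and the empirical central interval of the recomputed totals is
reported.  With the truth itself drawn from that same distribution, the
nominal 95% interval covers it at exactly the nominal rate in the
large-draw limit; the test suite verifies 93–97% coverage over 200
repetitions.  The inventory carries the 16 priority-PAH congener labels,
but only benzo[a]pyrene (BaP) — the congener dominating carcinogenicity —
is propagated to transport and health.

## EE-MRIO four-perspective accounting

For R regions with S sectors, the table holds intermediate flows `Z`
(N×N, N = R·S), final demand `Fd` (N×R), primary inputs `v` and total
output `x`, satisfying row balance `x = Z·1 + Fd·1` and column balance
`x = Zᵀ·1 + v` to 1e-8 relative.  Direct input coefficients
`a_ij = z_ij / x_j` give the Leontief inverse `L = (I−A)⁻¹`; direct output
coefficients `b_ij = z_ij / x_i` give the Ghosh inverse `G = (I−B)⁻¹`.
Columns (rows) with zero output get zero coefficients rather than an
error — empty sectors occur in real tables.  Inverses are computed by a
direct solve after checking the spectral radius; the truncated Neumann
series is retained as a test oracle only.

With emission intensity `u = E / x` (zero where x is zero) and `U, V, Y`
the diagonal expansions of intensity, primary inputs and final sales,

    Q_I = V G U ,   Q_S = U L Y ,   Q_C = U L F ,

allocate the same emitted mass to primary suppliers, final sellers and
final consumers; the production perspective is the diagonal of the
emissions themselves.  Each matrix is collapsed to a region-by-region
`Q[m, n]` (emitted in m, driven by n): all four perspectives conserve the
global anthropogenic total, and row sums always reproduce production
emissions per emitting region.  For `Q_I` the emitting region is read from
the `U` index and the driving region from the `V` index, making the
`Q[m, n]` semantics uniform across perspectives.

Net flows are `net[m, n] = Q[m, n] − Q[n, m]`; a region is a net importer
when the burden its driver causes in other regions exceeds the burden it
suffers from others.  The headline "total net inflow" sums the positive
pairwise flows; the sum of positive national net positions is reported
alongside, since the two conventions differ.

Price conversion uses origin-region deflation: all monetary rows of a
region are divided by its price index and the primary-input row is
recomputed as the column-balance residual, the minimal scheme that
guarantees a balanced constant-price table.  Regional aggregation is
applied after footprint computation, by block sums over a total mapping.

## Transport surrogate

A chemical-transport model enters this analysis only as a black-box linear
map from an annual emission grid to an annual-mean surface concentration
grid, evaluated once per scenario, followed by per-cell ratio attribution.
The surrogate preserves exactly those properties and nothing else: a
nonnegative operator `c = amplitude · blur(shift(e))` (Gaussian plume
spread, zonal advection shift, dilution amplitude), with parameters that
differ between years to stand in for meteorological change.  Gas–particle
partitioning, oxidation, deposition and re-emission are deliberately not
represented; nor is any phase split of the concentration.  The fractional
contribution of a scenario is `c_scenario / c_base` per cell (0 where the
base is 0, since such cells carry no burden); linearity makes fractions of
an emission partition sum to 1.

## Lifetime lung-cancer risk

Exposure to the annual-mean concentration c (µg m⁻³) is assumed constant
over a 70-year lifetime.  With URR the unit relative risk at 100 µg m⁻³
years of cumulative exposure,

    rr(c) = URR^(c·70/100) ,   PAF = (rr − 1)/rr ,

and the lifetime deaths in a cell are PAF times the cell's population
share of the region's cumulative lung-cancer death pool
`Σ_y LR_my/10⁵ · P_my` over the 70-year horizon.  URR is 1.3 in Asia,
1.13 in Europe, 1.16 in North America and 1.2 (the world average)
everywhere else; the synthetic world uses the world value throughout since
its regions map to no real macro-area.  The lung-cancer rate is
region-constant within a region (sub-regional rate heterogeneity is not
modelled); population is spread over cells by a fixed weight field and
held constant over the projection horizon unless a growth rate is
configured.  Scenario deaths are base deaths times the concentration
fraction, so attribution inherits the transport step's additivity.  PAF is
stored as a fraction in [0, 1) and formatted as percent only in reports.

A `dose_response="linear"` mode replaces PAF by its small-exposure limit
`ln(URR)·c·70/100`, computed directly from concentration (not as rr − 1,
which would lose precision at ambient exposures).  It exists to verify the
decomposition's linear limit and is not used for reported burdens.

## Structural decomposition

Each trade perspective factorises into six drivers, e.g. for consumption

    Q_C = K · Teff · L · M · R · P ,

with K emission factors (emissions per unit energy), Teff energy
efficiency (energy per unit output), L (or G) the production structure,
M (or the sale/primary-input share matrices) the structure of demand,
R (W, S) the per-capita level and P the population.  Process-source
emissions are folded into K — K is emissions per unit of combined
fuel-plus-process activity — so that K·Teff equals the emission intensity
u exactly.  Structure matrices have unit column (or region-row) sums by
construction.

The change between two years is attributed by the two-polar decomposition:
for factor i, the average of `(F₁..Fᵢ₋₁)₀ ΔFᵢ (Fᵢ₊₁..F₆)_t` and
`(F₁..Fᵢ₋₁)_t ΔFᵢ (Fᵢ₊₁..F₆)₀`.  Both polar forms telescope, so the
contributions sum to ΔQ at machine precision, for matrices as well as
totals; decomposing t→0 negates every contribution.  The mean over all
6! = 720 elementary orderings is implemented as a cross-check oracle; the
two coincide exactly for two factors and differ by bounded amounts
otherwise, both being complete.

The burden change adds two non-economic drivers.  Each socioeconomic
driver's death term re-grids its emission contribution with the emitting
regions' spatial weights and evaluates

    ΔD_Qθ = ½[(D(k₀, Q₀+ΔQ_θ) − D(k₀, Q₀)) + (D(k_t, Q_t) − D(k_t, Q_t−ΔQ_θ))] ,

the average of forward (add the driver's change to the start year) and
backward (remove it from the end year) control-variate branches.  The
meteorology term swaps the kernel year at fixed emissions, averaged over
both emission states; the mortality term swaps the rate year at fixed
exposure, averaged over both exposure states.  Socioeconomic and
meteorology terms hold mortality at a configurable reference year
(default: the start year), avoiding double counting with the mortality
term.  Because PAF is nonlinear, the terms do not close exactly: the
residual is an explicit output and is never re-allocated.  Under a linear
dose-response with kernel and mortality fixed the closure is exact, which
the tests verify to 1e-8; under the default settings the residual on the
default synthetic world is a few percent of the total change.

## Synthetic world

The generator emulates the statistical and algebraic structure the
analysis assumes — not real trade magnitudes or real PAH spatial patterns.
It works from primitive factors per year (input coefficients, demand
shares and per-capita levels, population, emission and energy intensities,
kernel parameters, mortality rates); every derived object is a pure
function of the primitives, so perturbing one primitive and re-deriving
keeps every balance identity intact and makes single-driver experiments
exact.

Key constructions and defaults:

* **Size.**  4 regions × 5 sectors × 18×36 grid × 2 years: small enough
  for sub-second end-to-end runs, large enough to exercise aggregation.
  These are also the problem sizes used by the test suite and the
  acceptance script.
* **Productivity and balance.**  Flow patterns are lognormal
  (guaranteeing positivity with realistic skew); input-coefficient columns
  are rescaled to sums in [0.35, 0.65], which bounds the spectral radius
  below 0.9 and keeps primary inputs positive.  Output solves the Leontief
  system for drawn final demand, so both balance identities hold by
  construction.
* **Producer/consumer roles.**  Producer regions get ~4× the emission
  intensity and supply a boosted share of intermediates and of consumer
  regions' final demand; consumer regions get 4× per-capita final demand.
  This forces consumer regions to be net importers of embodied emissions
  in all three trade perspectives — the recoverable ground truth behind
  the qualitative pattern tests.
* **Temporal drift.**  Between years, emission factors decline (×0.92/yr),
  energy efficiency worsens (×1.06/yr), per-capita demand (×1.05/yr),
  population (×1.03/yr) and mortality rates (×1.05/yr) grow, demand and
  production structures jitter, and the kernel's shift and amplitude
  change (×1.08/yr) — so every decomposition factor has a nonzero true
  change.  Natural emissions are fixed at 17.5% of base-year anthropogenic
  regional totals (≈15% of the total), constant across years.
* **Concentration scale.**  The kernel amplitude is anchored so the
  base-year mean concentration is 0.5 ng m⁻³, a typical ambient
  annual-mean BaP level.  This keeps rr − 1 small, so the default
  nonlinear decomposition residual stays at the few-percent level.
* **Grids.**  Regions are contiguous longitude strips; emission and
  population weights are independent smoothed random fields normalised to
  sum 1 per region.

Because natural emissions are proportional to base-year anthropogenic
totals with the same spatial weights, the anthropogenic concentration
fraction is uniform (85.1%) in the base year — a known, intended
simplification.

What passing tests on this world do **not** show: realism of trade
magnitudes, spatial emission patterns, chemistry-driven transport
asymmetries, phase partitioning, cohort or latency effects in the risk
model, or the real-world 13-region aggregation map.  They do show that the
accounting identities, attribution closures and decomposition
completeness the analysis relies on hold exactly, and that the pipeline
recovers structure that is embedded by construction.

## Numerical conventions

* Balance and conservation tolerances: 1e-8 relative; gridding and
  attribution closure: 1e-9; SDA completeness: machine precision,
  asserted at 1e-8 or tighter.
* Zero-output sectors, zero-base-concentration cells and zero final
  demand are conventions (zero results), not errors; zero population or
  zero regional demand in the factorisation is an error because per-capita
  levels become undefined.
* Matrix inverses via `numpy.linalg.solve`; spectral radius ≥ 1 raises a
  non-productive-economy error before any solve.
* All randomness flows from a single `numpy` generator per world seed;
  fixed seed means bit-identical bundles, files and manifests.
* NetCDF output uses the scipy backend (NetCDF3); all tabular formats are
  CSV with 17-significant-digit floats, so round-trips are bit-exact.
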