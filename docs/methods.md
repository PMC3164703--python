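# Methods

## The model family and its assumptions

The package models transcriptional regulation in the melanocyte lineage
as a one-step process: binding and unbinding of transcription factors to
DNA are taken to be fast compared with protein synthesis and turnover,
so each regulatory input enters the synthesis term at its
quasi-equilibrium occupancy.  With first-order binding this yields the
Hill-like forms `act(x, k) = kx/(1+kx)` and `rep(x, k) = 1/(1+kx)`; the
Hill coefficient is fixed at 1 throughout.  Steeper, switch-like
behaviour is supplied where the biology demands it by two explicit
Heaviside gates on the Factor-Y feedback loop rather than by Hill
exponents: `Θ(M_eff − M*)` gates Factor-Y production and `Θ(Y − Y*)`
gates Y's activation of *mitfa*.  This is the minimal placement that
stabilises the Mitfa-off state at low Mitfa or low Y — without it, any
trace of Mitfa ignites the positive feedback, and the undifferentiated
state of the *sox10* mutant would be unstable, contradicting the
near-total absence of melanocytes in that genotype.  Gates are
inclusive at the boundary; a steep-Hill `soft_gate` is available for
solver-smoothness experiments but is not used by the default path.

mRNA and protein are not distinguished: each species is a single
"gene product" concentration in nM.  Exogenous inputs are Factor A (a
composite of poorly characterised *sox10* enhancer inputs, constant
from its onset) and Factor B (a transient pulse inducing Factor Z, the
weak Sox10/Mitfa-independent activator of differentiation genes for
which Sox9b is the identified biological candidate).  H represents
Mitfa-recruited Hdac-complex *activity*, not *hdac1* transcript:
*hdac1* is maternal-plus-zygotic and unlikely to be transcriptionally
regulated by Mitfa, so the Mitfa dependence is placed on complex
recruitment.

Where several activators converge on one promoter (the two *sox10*
activation routes; Mitfa and Factor Z on the differentiation genes),
their occupancies combine additively and are capped at 1, so that `c_g`
remains the true maximal synthesis rate.  Hdac repression multiplies
each activation term it gates separately (`ξ` on the Mitfa term, `φ` on
the Factor-A term), matching the drawn arrows of the full network.

Three nested variants are exposed.  The full model (C) contains
everything; variant B removes the Hdac gate on the Factor-A route
(`φ = 0`), the thresholds, and the Factor-B/Z branch; variant A further
removes H and Y.  The reductions are implemented by parameter masking
of a single right-hand side, so nesting is exact to machine precision —
a property the test suite asserts on random states.  Species removed by
a reduction decay inertly (`x' = −d·x`) and are identically zero from
the standard zero initial condition; this keeps the reduced systems
literally equal to the masked full system on arbitrary states.

Mutant genotypes are *activity maskings*: a null allele scales the
species' downstream influence to zero while the transcript itself keeps
evolving.  This reproduces the observed persistence of *sox10* and
*mitfa* transcripts in the corresponding mutants, and lets the same
machinery express morpholino knockdowns (fractional `factorZ_scale`),
chemical Hdac inhibition (time windows during which H exerts no
repression; windows are half-open `[start, end)`), and mRNA injection
or rescue (exogenous pulses added to the effective activity).

## Reference parameters

No published numeric parameter set is recoverable for these models, so
the package ships a reference set calibrated once by the implementer
and then frozen (see the changelog in `src/melgrn/reference.py`).
Scale choices: turnover rates of order 0.2/hr give hours-scale dynamics
across the 24–96 hpf window; synthesis rates are sized so saturating
expression sits near 1 nM; the thresholds are `M* = Y* = 0.01 nM`; the
detection threshold linking concentration to "detectable by in situ
hybridisation" is a declared convention, `theta_det = 0.01 nM`, the
same scale as the feedback thresholds.  Affinities are of order 1–10
/nM except the three repressive couplings `φ = ξ = 30 /nM` (Hdac on the
two *sox10* activation routes) and `ρ = 30 /nM` (Sox10 on the
differentiation genes), which must be strong for wild-type *sox10* to
fall two orders of magnitude below detection while Factor A persists,
and for Sox10 to keep differentiation genes silent at injection-scale
concentrations.  The *tyrp1b* input `μ_T = 0.025 /nM` is deliberately
weak: *tyrp1b* integrates Mitfa slowly, which is what delays its onset
after *sox10*-only injection to the later assay time.  Factor A is
constant from 18 hpf; Factor B is on over 12–30 hpf with an exponential
tail — the pulse precedes the Factor-A onset so that the Z-driven
derepression transient in *mitfa* mutants appears before Sox10
accumulates and represses it.

Calibration targeted the three wild-type behaviour criteria — Mitfa
maintained above `theta_det` after 60 hpf, an interior Sox10 peak at
least `r_min = 5`-fold above its final level (the declared
quantification of an "appreciable" transient; no published number
exists), and Sox10 below detection at 96 hpf — plus the mutant, rescue,
Hdac-window and knockdown contracts, and was then frozen: every test
treats the set as a fixture.

## Numerics

Time integration is explicit Euler on a fixed grid, default
`t ∈ [0, 96]` hpf with `dt = 0.01` hr.  Euler can undershoot zero near
the non-negative boundary; negative intermediates are clipped to zero
and clip events counted in the trajectory.  A step that would change
any species by more than half of the larger of its saturation bound
`c_g/d_g` and its current level aborts with an error naming the species
— the default step sits two orders of magnitude below that limit for
reference rates.  Against an adaptive RK45 reference solution
(`rtol 1e-8`, step capped well below the gate-switching scale), the
default-step Euler solution of the wild-type reference run agrees to
0.63% max error (per species, relative to that species' scale); the
test suite enforces 2%.

Steady states are found by exploiting the piecewise-smooth structure:
within a fixed assignment of the two gate values (at most four
regimes), the algebraic system given the late-time input values is
triangular — H, Y and S are explicit in M, and Z, D, T explicit in the
rest — so fixed points reduce to 1-D root finding for M (dense scan
plus bisection to `xtol 1e-14`), followed by a regime self-consistency
check with a boundary guard of 1e-6 nM, deduplication at 1e-6 nM, and a
residual bound of 1e-10 nM/hr.  Stability is classified from the
eigenvalues of a central-difference Jacobian with the gates frozen at
the regime (the correct linearisation away from gate boundaries);
points within the boundary guard are reported as undetermined.  Every
stable state is cross-validated against the integrator: ±1%
perturbations must return within 1e-3 nM over a late-time horizon.
Variant A's fixed point is additionally cross-checked against an
independent symbolic solution in the test suite.

Parameter sweeps vary two affinities on log-spaced grids (default 21×21
over two orders of magnitude, centred geometrically on the reference
value) and integrate all grid points simultaneously by broadcasting the
right-hand side over a batch axis; steady levels are late-time values
at a 240 hr horizon (many turnover times) and the Sox10 maximum is
tracked along the trajectory by full re-integration, not approximation.
Failed grid points are recorded invalid, never fatal.  A point is
acceptable when `M_ss ≥ theta_det`, `S_ss < theta_det` and
`S_max/max(S_ss, 1e-6) ≥ r_min` (points with `S_ss < 1e-6` count as
satisfying the peak requirement when `S_max` is detectable).

## The synthetic observation layer

Real readouts enter the original analyses as per-cell detection scores
(20 pigmented cells in each of 5 embryos per time point) and as
qPCR-style percent-of-wild-type fold changes.  The generator emulates
both.  Each scored cell draws an independent log-normal multiplier with
median 1 and coefficient of variation 0.3 (a declared noise model — the
source data report raw detection only) and is positive when the
multiplied trajectory value reaches `theta_det`; counts are therefore
binomial with the log-normal tail probability, which the test suite
verifies by goodness of fit.  Scored times default to 30–51 hpf in 3 hr
steps, bracketing the window in which wild-type melanocytes go from
all-positive to none.  Fold-change replicates multiply the exact
trajectory ratio by `exp(N(0, 0.25))`.  All randomness flows through a
single named seed; bundles are byte-reproducible and carry a manifest
with a configuration hash.

What passing these tests shows — and does not show: the observation
model captures detection thresholds and multiplicative reporter noise,
but not cell-to-cell lineage heterogeneity, spatial position along the
migration routes, staging error between embryos, or probe-specific
in-situ sensitivity; agreement of the synthetic series' shape with the
modelled trajectory is a consistency check of the pipeline, not
evidence about real embryos.

## Design choices where the design was open

* **Composition of multiple activators.**  Additive-with-cap was chosen
  over multiplicative (AND) logic because the two *sox10* routes and
  the two differentiation-gene inputs are biologically alternative
  (either suffices), and the cap preserves `c_g` as the maximal rate.
* **Both Factor-Y directions are parameterised** (`δ_MY` Mitfa→Y,
  `δ_YM` Y→M).  Sweep defaults follow the respective robustness-figure
  conventions: variant B varies `δ_YM`, variant C varies `δ_MY`,
  alongside their gate affinities.
* **Factor A is constant** from its onset in the reference set; the
  pulse type supports a decaying A for exploration.
* **Rescue classification** uses the switch coordinates (M, D), which
  separate the two attractors; species upstream of the switch (Sox10
  itself) may still be relaxing after a long exogenous pulse without
  bearing on the attractor identity.
* **Hdac-window melanisation contrast** is evaluated up to the window
  end — the stage at which treated embryos were assessed — because
  after washout the model's differentiation output converges to the
  same steady level in treated and control runs.
* **Overexpression doses** default to `init_M = 8 nM` (ten times the
  wild-type steady Mitfa level) and `init_S = (115/35)·init_M`,
  mirroring the injected-RNA mass ratio of the corresponding
  experiments; injected material enters as an initial condition and
  decays at the species' turnover rate.  The repression outcome depends
  on the Sox10:Mitfa *ratio*, which is configurable.
* **Genotype-response monotonicity.**  The differentiation output D is
  strictly monotone in `mitfa_activity` and `factorZ_scale`.  It is
  *not* monotone in `sox10_activity` above the ignition point: any
  functional Sox10 ignites Mitfa and raises D's time-integrated output
  far above the *sox10*-null residual, but beyond ignition additional
  Sox10 is a mild net repressor of D — that is the feed-forward
  repression motif itself.  The property tests assert exactly this
  structure (strict monotonicity on the Mitfa/Z axes; loss-of-function
  ordering on the Sox10 axis).

## Known limitations

Deterministic ODEs only: no stochastic kinetics, no cell migration or
spatial structure, no iridophore branch, no promoter-sequence
modelling.  mRNA/protein are collapsed into one species per gene, so
translation delays are absorbed into effective affinities (visible in
the deliberately weak `μ_T`).  Hard Heaviside gates make the
right-hand side discontinuous; all shipped analyses handle this via
regime freezing, but external ODE solvers applied naively to the full
model should cap their step size or use the `soft_gate` alternative.
The reference parameter set is a calibrated representative of the
qualitative regime, not a fit to measured quantities; conclusions drawn
from it are structural (which variants can or cannot reproduce the
behaviour criteria, and over how much parameter space), not numerical
predictions for real embryos.
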