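# Methods

## The model

`casparks` simulates elementary Ca²⁺ release events — sparks and quarks —
in a 2D patch of cardiac-myocyte cytoplasm. Three coupled pieces:

**1. Cytosolic free Ca²⁺.** A space-fractional reaction–diffusion balance

    ∂c/∂t = Dx ∂^β c/∂x^β + Dy ∂^β c/∂y^β
            + J_dye + J_buffer + J_pump + J_clustered + J_rogue

with anomalous order β = 2.25 (short-jump subdiffusive transport in the
crowded cytoplasm), Dx = 300 and Dy = 150 (printed as µm² s⁻¹; formally
µm^β s⁻¹ for the fractional operator) reflecting the longitudinal/
transverse anisotropy of the myofilament lattice. J_dye and J_buffer are
mass-action binding to the fluorescent indicator (Rhod-2 or Fluo-4 AM)
and to the endogenous stationary buffers (calmodulin, troponin, SR and SL
membrane sites); J_pump is a Hill-type SERCA flux, thresholded off at or
below the resting level of 0.1 µM. Release appears as point (Dirac)
sources at the RyR unit positions with strength
σ = 0.64·I·([Ca]_lumen − [Ca]_cyto)/(2F), I = 0.7 pA mM⁻¹ for a clustered
CRU and 0.07 pA mM⁻¹ for a rogue unit; the 0.64 factor is the 2D
projection of the 3D point release.

**2. Per-JSR luminal Ca²⁺.** Each junctional-SR site is a well-mixed
compartment (volume 10⁻¹¹ µl) with free Ca²⁺ depleted by the identical
molar flux its open units inject into the cytosol, buffered by
calsequestrin and the luminal dye Fluo-5N, and refilled from the
network SR: J_refill = ([Ca]_NSR − [Ca]_lumen)/τ, [Ca]_NSR = 1.0 mM,
τ = 10 ms.

**3. Stochastic RyR gating.** Each site holds 2 CRUs (22 channels) and 8
rogue units (3 channels) placed at random on a 0.1 µm sub-grid inside a
0.6 µm footprint. A closed unit opens in a step with probability
P = P_cyto·Φ_lumen, where P_cyto = 1 − (1 − p₁)^n couples the n channels
(p₁ = 1 − e^(−p_ryr(c)·dt), with p_ryr a Hill hazard of the local
cytosolic Ca²⁺) and Φ_lumen = φ^m regulates by luminal load
(φ = (c_lumen/1 mM)^ν; m = 1 rogue, m = 10 clustered). Open units release
for a fixed 20 ms (rogue) or 10 ms (CRU), then close into a refractory
period.

## Parameters that matter

| parameter | default | units | provenance / rationale |
|---|---|---|---|
| β | 2.25 | – | anomalous subdiffusion order |
| Dx, Dy | 300, 150 | µm^β s⁻¹ | anisotropic cytosolic transport |
| mesh | 0.025 (5×5 µm), 0.1 (20×20 µm) | µm | single-site vs lattice protocols |
| dye/buffer kinetics | table in `config.py` | µM, µM⁻¹s⁻¹, s⁻¹ | standard indicator/buffer values |
| SERCA v_max, K, h | 208, 0.184, 3.9 | µM s⁻¹, µM, – | modelling-lineage values; **not printed in the source model** |
| I_clustered, I_rogue | 0.7, 0.07 | pA mM⁻¹ | unit currents per driving mM |
| T_clustered, T_rogue | 10, 20 | ms | fixed release durations |
| τ_refill, [Ca]_NSR, V_JSR | 10 ms, 1.0 mM, 10⁻¹¹ µl | | luminal refill and store size |
| p_max, K_p, γ | 150 s⁻¹, 0.25 µM, 12 | | **calibrated** (below) |
| ν (φ exponent) | 0.092 | – | **calibrated** (below) |
| refractory | 300 | ms | spark-restitution scale (below) |
| m_rogue, m_clustered | 1, 10 | – | luminal regulation coefficients |

### Calibrated gating constants

The single-channel hazard p_ryr and the φ power are cited but not printed
in the source model, so they are pinned by the published observables
(`scripts/calibrate.py` reproduces the sweep):

* **ν = 0.092** comes from the ratio of the published spontaneous spark
  frequencies at 1.0 mM vs 0.2 mM luminal load (12.2 vs ≈1.2 per 100 µm
  per s): Φ_clustered scales that rate by φ^10 = (0.2)^(10ν) ≈ 0.23.
* **γ = 12, K_p = 0.25 µM, p_max = 150 s⁻¹** jointly set (i) the resting
  per-channel hazard (≈2.5·10⁻³ s⁻¹, fixing the spontaneous spark rate),
  and (ii) a steep CICR activation so that the 0.1–0.2 µM elevation a
  quark produces at a same-site CRU can trigger it. A shallow curve
  (e.g. Hill slope ≈1.6 with K ≈ 15 µM) cannot do both: the quark signal
  would raise the CRU hazard only a few-fold and essentially no spark
  would ever be quark-triggered.
* **Refractory 300 ms**: after a spark the site-local Ca²⁺ stays above
  the CICR activation range for ~250 ms (set by the slow troponin
  off-rate, 20 s⁻¹). Shorter refractory periods let sites re-fire into
  their own residual Ca²⁺ and the lattice degenerates into continuous
  waves. 300 ms matches the restitution of spark sites observed in
  myocytes and leaves spontaneous statistics untouched (mean inter-spark
  interval per site ≫ 1 s).

There is a structural ceiling worth knowing: with 2×22 clustered vs 8×3
rogue channels sharing one hazard curve, the QCR-triggered fraction of
sparks cannot exceed 24/(44+24) ≈ 35% even if every quark triggers a
spark. The published 34.7% sits at that ceiling; the calibrated model
operates at ≈30% with moderate site-to-site coupling.

## Numerics

* **Operator.** Shifted (one-node) Grünwald–Letnikov weights,
  normalized (g_k = (−1)^k C(β,k), stable recurrence), assembled as a
  dense matrix per grid line. Default is the symmetrized (Riesz-like)
  mean of left- and right-sided forms: its Fourier symbol has negative
  real part for all orders in (1, 2.25] (unconditional implicit
  stability) and it preserves the mirror symmetry of a point release.
  Left-only and the printed-formula (`paper_literal`) weight modes are
  retained for auditing, as is an order-(β−1) discretization switch.
* **Boundary.** Zero flux by even reflection of the field about each
  edge; a diagonal correction zeroes each row sum exactly so constants
  are in the operator's kernel despite the finite weight window.
* **Time stepping.** Lie splitting: stochastic gating → release-source
  evaluation → coupled implicit reactions → implicit direction-split
  diffusion (dense LU per line, factorizations cached per dt) → luminal
  update. The point-source deposition is integrated *inside* the implicit
  diffusion solve; splitting it into the reaction stage makes the
  source-cell amplitude first-order dt-dependent (≈12% per halving),
  whereas the integrated form converges (<0.1% between dt = 12.5 and
  6.25 µs).
* **Reactions.** Free and bound species are advanced by one coupled
  backward-Euler step: each bound species is eliminated through its exact
  frozen-c update and the resulting scalar equation is solved by Newton
  per cell (numba kernel, numpy fallback; verified against LSODA to
  1e-9). A sequential free-then-bound splitting is *unstable* here
  because the buffering power exceeds one (calsequestrin alone is ≈3.3).
* **Pump clamp.** The explicit pump update never pulls a cell below the
  0.1 µM threshold at which it switches off, making the resting state an
  exact fixed point.
* **Luminal refill** uses an exponential-integrator weight, exact for
  the buffer-free compartment.
* **Adaptive dt.** Dyadic ladder between dt_min (12.5 µs single-site,
  50 µs lattice) and dt_max, limited by the realized relative field
  change (≤5%), the per-step gating probability (≤0.2), and pending
  open/close/forced event times; new openings force the floor. The
  fractional stencil is not an M-matrix, so transient undershoots up to
  ~0.5% of the field peak occur and are clipped at zero; the run aborts
  only if the undershoot exceeds 2% of the peak.
* **Degenerate inputs.** β = 2 reproduces a classical anisotropic
  diffusion solver (verified against the Gaussian Green's function);
  empty species lists, zero-duration events and event-free logs are all
  defined.

## Observables

Fluorescence is the Ca-bound dye concentration (no optical blur by
default). ΔF/F0 uses the pre-event baseline. **t67** is the width of the
interval during which |ΔF| ≥ 67% of its peak — a duration-at-67%-of-peak,
the temporal analogue of FWHM. The metric is isolated in
`observables.t67_duration` so an alternative convention can be swapped in
one place. Event statistics come from the simulator's ground-truth event
log: CRU openings at one site merging within a 20 ms window form one
spark (quantal units = distinct CRUs), a spark is QCR-triggered when a
same-site rogue opening precedes its first CRU opening within the window,
and rogue-only episodes are quarks. Frequencies are normalized per 100 µm
of pooled scan line (all lattice rows) per second. An image-based
threshold detector (ΔF/F0 ≥ 0.2) provides an independent cross-check on
line-scan images.

## What the synthetic conditions do and do not show

All validation inputs are generated internally: the model *is* the data
generator. The single-quark protocol (forced 20 ms rogue opening,
spontaneous gating disabled) is deterministic and matches the published
QCR/QCD trace metrics where the printed parameters determine them. Two
published values are not reproduced and appear unreachable from the
printed parameter set: the cytosolic quark amplitude (we obtain
ΔF/F0 ≈ 0.090 vs 0.065 ± 0.006 — the absolute scale is set by the
2D-projection depth convention, fixed here a priori as a unit-depth
slab), and the QCD t67 (25.3 vs 22.5 ± 1.9 ms — the luminal recovery is
rate-limited by τ_refill times the calsequestrin buffering power ≈ 4.3,
i.e. a ≈43 ms free-Ca time constant; a 22.5 ms t67 requires a faster
recovery than those parameters allow). Lattice statistics are verified at
a scaled problem size (10×10 µm, n = 5 replicates, 2 s) chosen so the
whole suite runs on a laptop-class single core; the 20×20 µm, n = 10
protocol of the original study is available through the presets.

Real line-scan data additionally carry photon noise, optical blurring and
motion — none of which are modelled — so passing these checks validates
the numerical model, not the imaging chain.

## Known limitations

* 2D only; no intra-SR diffusion between JSR sites; NSR is an infinite
  reservoir.
* One hazard curve for all RyR channels; no Markov-state inactivation.
* The fractional operator at β > 2 does not generate a positive
  semigroup; small negative lobes are intrinsic and clipped.
* SERCA constants are lineage defaults, not values from the source model.
* Fixed release durations and currents; no flux regulation by cluster
  size.
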