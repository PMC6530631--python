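# Methods

`cerescaffold` reconstructs and simulates a block of mouse cerebellar
cortex plus its deep-nuclei (DCN) target as a *scaffold*: cell placement,
connectome construction, point-neuron dynamics and analysis are separate,
independently replaceable stages. This note records the model, the choices
made where the design was genuinely open, and what the package does and
does not establish.

## Volume and coordinate frame

The reference volume is a 400 × 400 µm² cortical base, 330 µm tall
(granular layer 150 µm, Purkinje-cell layer 30 µm, molecular layer
150 µm), with a 200 × 200 × 600 µm³ DCN block centred underneath
(y < 0). Axes are fixed package-wide: `x` parasagittal, `y` vertical
(0 at the granular-layer bottom), `z` transversal — the direction parallel
fibers run. Basket cells occupy the lower half of the molecular layer and
stellate cells the upper half.

## Cell placement

Seven populations are placed from the configured densities (cells/µm³;
planar cells/µm² for Purkinje cells):

* **Walk populations (GrC, GoC, BC, SC).** Each layer is cut into
  sublayers of height 1.5 × soma diameter. Within a sublayer, a bounded
  self-avoiding random walk places each soma one soma diameter plus a
  scatter term `s` from the previous one along a uniform random direction,
  with `s` drawn from a normal distribution centred on
  ε = (3/(4π·density))^⅓ − r_soma, truncated to [0.75 ε, 1.25 ε]. A
  candidate that leaves the region or comes within one soma diameter of any
  placed soma is re-drawn (50 tries), after which the walk restarts from a
  random point of the *remaining free region* (tracked on a fine grid —
  the same distribution as rejection sampling over the rectangle, reached
  in far fewer draws); when restarts stop finding room the remaining free
  cells are swept until no further soma fits. This saturation sweep is what
  lets the granule layer approach its geometric packing limit: at the
  reference density the layer asks for a 57% area fraction, above the ~55%
  random-parking limit, so placement saturates at ~94% of the density
  target (~88.2k granule cells placed of 93.6k requested) — the same
  shortfall the reference census shows. A numba kernel accelerates the
  walk; a pure-Python fallback implements the identical algorithm.
* **Vertical coordinates** are uniform within the sublayer, re-drawn
  against already-placed somata of the same population (3-D grid hash), so
  the minimum inter-soma distance ≥ 2 r_soma holds in full 3-D, not just
  within a sublayer. Cross-population overlap is deliberately not
  prevented.
* **Glomeruli** are mossy-fiber terminals, not migrating somata; they are
  placed uniformly at random with non-overlap by rejection. (Walk-placing
  them chains them at ~11 µm spacing, leaving voids in which ~5% of granule
  cells find no glomerulus within dendritic reach and the mean dendrite
  length cannot fall below ~17 µm; uniform placement reproduces the
  published ~12 µm.)
* **Purkinje cells** sit on a near-square planar grid (pitch ≈ 47 µm,
  derived from the planar density, kept ≥ the 30 µm dendritic-slab width so
  neighbouring parasagittal slabs do not overlap), with alternating-row x
  offsets equivalent to a ~5° angular shift between adjacent cells, small
  positional jitter, and vertical noise inside the 30 µm layer.
* **DCN cells** (n = 12) are uniform random with non-overlap.
* **Ascending axons.** Every granule cell gets an ascending-axon height
  from a Gaussian (181 ± 66 µm) truncated to (0, pia − soma height]; the
  tip height is also the height at which the cell's parallel fiber runs
  transversally.

Placement quality is validated by Gaussian KDE of 3-D pair-wise inter-soma
distances (fixed bandwidth per population: Silverman's rule for the large
homogeneous populations; 8 µm for the 69–72-cell Purkinje lattice, whose
multimodal maxima Silverman's ~18 µm oversmooths away). Homogeneous
populations give a single maximum (granule cells ≈ 180–190 µm); the
Purkinje lattice gives maxima near 50, 140 and 267 µm. The granule
distance density is broad-topped, so its KDE argmax wanders by several µm
between subsamples; the acceptance script averages it over placement seeds.

## Connectome

Sixteen connection types are built in two steps: **geometric candidates**
(axonal field ∩ dendritic field, with fields as spheres, cylinders, boxes,
thin slabs and parallel-fiber lines bounded to 400 µm along z) and
**pruning** to a configured convergence (afferents per target) or
divergence (efferents per source) by sampling without replacement with
probability ∝ exp(−Σ(Δaxis/λ_axis)²) via exponential race keys —
reproducible under a fixed seed, and exact: every target with enough
candidates ends at exactly the configured in-degree. Golgi-to-granule
inhibition is not geometric: Golgi→glomerulus edges are fused with
glomerulus→granule edges (relational join, duplicates collapsed), so a
Golgi cell inhibits exactly the granule cells driven by the glomeruli its
axon reaches. Stored edges carry the 3-D inter-soma distance.

Key geometric choices (all in config):

* granule dendrites reach ≤ 40 µm, convergence 4; the pruning decay (8 µm)
  is calibrated so the mean edge length reproduces the experimental
  ~12–13 µm dendrite length;
* the ascending axon contacts a Purkinje cell only if it passes within
  5 µm of the cell's dendritic plane (the plane is thin; the 30 µm "width"
  is the non-overlap envelope between neighbouring cells) — this yields
  ~20% of granule cells eligible, as observed;
* stellate axons run transversally ("on-beam", ±150 µm in z, ±30 µm in x),
  basket axons sagittally ("off-beam"); an orthogonal-plexus variant swaps
  the two;
* every local Purkinje cell converges on each DCN cell (the volume holds
  far fewer Purkinje cells than the biological convergence).

Convergence/divergence targets that the source tables do not state are
configuration inputs. Where the literature gives a number it is used
(4 glomeruli per granule cell); the remainder (Golgi and molecular-layer
interneuron in-degrees, ascending-axon and parallel-fiber in-degrees, the
Golgi→glomerulus divergence of 12) were calibrated once so that the
assembled network reproduces the published population firing regime —
granule cells ~2–3 Hz baseline / ~114 Hz excited during the burst,
Purkinje cells ~255 Hz excited, interneurons ~30 Hz baseline, DCN cells
~16–20 Hz baseline and silenced by convergent Purkinje inhibition. They
are calibration constants of this reconstruction, not measurements.

## Network dynamics

All non-glomerulus cells are conductance-based leaky integrate-and-fire
neurons,

    C_m dV/dt = −(C_m/τ_m)(V − E_L) + I_e + g_exc(E_exc − V) + g_inh(E_inh − V),

with per-type parameters (C_m, τ_m, E_L, Δt_ref, I_e, V_r, V_th, τ_exc,
τ_inh) from the reference tables, E_exc = 0 mV and E_inh = −85 mV
(exposed in config). Conductances decay exponentially and jump by |w| on
delayed spike arrival; the weight's sign selects the channel. Integration:
exact exponential decay for conductances, exponential-Euler for the
membrane, fixed Δt = 0.1 ms; threshold detection at step boundaries, spike
stamped at end of step, V reset and clamped for the refractory period;
delays round to the nearest step (min one). Isolated neurons match the
closed-form rate 1000/(Δt_ref + τ_m ln((E_L+I_eR−V_r)/(E_L+I_eR−V_th)))
within one spike per second (Golgi ≈ 9.8 Hz, Purkinje ≈ 36 Hz, DCN
≈ 25.8 Hz; granule cells are silent without input). Glomeruli are parrot
relays: their imposed spike trains are injected into the delayed delivery
queue unaltered and copied verbatim to the output record.

Protocols: the default run is 1 s — 1 Hz Poisson background per
glomerulus, and from 300 ms a 50 ms, 150 Hz burst (regular train by
default; Poisson optional) on the glomeruli of the stimulated volume. The
stimulated volume is a **vertical 140 µm-radius column** through the
granular layer: a 140 µm sphere centred inside a 150 µm-thick layer can
cover at most ~35% of glomeruli, whereas the column covers ~38.5%,
matching the reported 2,932/7,070 activated glomeruli and the quoted
0.012 mm³ activated volume. The centre-surround protocol stimulates the 40
glomeruli nearest the centre, paired with an identical run with
Golgi→granule inhibition off; granule rates 0–20 ms (T1) and 20–40 ms (T2)
after onset enter EI = FR_con(T2) − FR_inoff(T2), CS = FR_con(T1) − EI on
a 10 µm pixel grid, CS normalised by max |CS|, centre = CS > 0.5,
surround = CS < −0.5. The oscillation protocol is 5 s of 5 Hz background
with the parallel-fiber→Golgi weight raised to 30.4 nS. Switch-offs zero
whole connection types reversibly.

## Analysis conventions

PSTHs use left-closed 3 ms bins. A cell is *excited* if its during-burst
rate at least doubles its baseline (granule cells must additionally fire
more than one spike during the burst), *inhibited* if it at least halves;
silent-baseline cells can only be excited. Purkinje *pause*: the first
inter-spike interval after stimulus end exceeds mean + 2 sd of the
pre-stimulus ISIs (the mean term keeps the literal 2-sd rule from flagging
every interval of a perfectly regular train). Correlograms are
mean-subtracted, normalised correlations of binned population counts
(10 ms bins, ±2 s lags); the coherence index is C = Σ|A_n|/len(A) and the
dominant frequency is the reciprocal of the first positive-lag local
maximum.

## Problem sizes

Tests run the full pipeline on reduced volumes (base area scaled by
2.5–10%, densities and rules unchanged) and the acceptance checks on the
full reference volume: five placement seeds for the census statistics,
three full default-protocol simulations (medians reported), and the
oscillation run on a half-area volume over 5 s.

## Known limitations

* **DCN onset gap.** The earliest burst-evoked inhibition can reach a DCN
  cell 10.4 ms after burst onset (glomerulus→granule 4 ms + ascending
  axon→Purkinje 2 ms + Purkinje→DCN 4 ms). A DCN cell free-running at
  ~16–20 Hz therefore fires one autorhythmic spike shortly after onset
  whenever its phase falls in that window — and because all DCN cells
  share the same self-averaging Purkinje input and all membranes start at
  E_L, that phase is essentially a deterministic (and fragile) function of
  the configuration. Under this calibration it lands just after onset, so
  the during-burst DCN count is one spike per cell rather than zero; the
  silencing mechanism itself is robust (complete pause from ~+2 ms of the
  first Purkinje volley to ~90 ms after the burst). A reported exact zero
  requires the phase numerology to land clean.
* **Slow oscillations.** Under the oscillation protocol the granular layer
  settles into an asynchronous balanced state with weak fast fluctuations
  (~15–35 Hz, the delayed-feedback resonance of the granule–Golgi loop).
  No configuration of the unprinted convergence ratios explored produced a
  ~2 Hz collective rhythm: every membrane and synaptic time constant in
  the model is ≤ 21 ms, and the loop carries no slow process (adaptation,
  short-term plasticity, or rate-modulated input) that could set a ~0.5 s
  timescale.
* The synthetic volume is periodic in nothing: edges lose afferents
  (logged as shortfalls), so border cells run slightly cooler than bulk
  cells.
* Point neurons, static synapses, no inferior olive, no plasticity; these
  are outside the scaffold's scope by design.
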