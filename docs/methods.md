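# Methods

## The model

`bulbsparse` simulates the first synaptic stage of olfaction: the
reciprocal mitral-granule circuit of the olfactory bulb, reduced to a
one-dimensional tract.  Odors arrive as integer glomerular activation
strengths (0-4); each glomerulus drives five mitral cells (MCs), and
every MC extends two 1.5 mm lateral dendrites along the tract.  Granule
cells (GCs), outnumbering MCs 20:1, form reciprocal dendrodendritic
synapses with the dendrite segments that pass their position.  The
default census is 100 glomeruli / 500 MCs / 10,000 GCs
(glom:MC:GC = 1:5:100); the reduced desk-scale preset keeps the same
ratios at 20 glomeruli / 100 MCs / 2,000 GCs.

Each reciprocal contact carries two independently plastic components:
an excitatory MC→GC component and an inhibitory GC→MC component.  A
component's weight is slaved to a state variable p ∈ [0, 50] through

    w = g_max · S(p),    S(p) = 1 / (1 + exp((25 − p) / 3)),

and every presynaptic event moves p by Δ determined by the
instantaneous presynaptic interspike interval: Δ = +1 for ISI ≤ 33 ms
(LTP, rates ≥ 30 Hz), Δ = −1 for 33 < ISI < 250 ms (LTD, 4-30 Hz),
Δ = 0 for ISI ≥ 250 ms (≤ 4 Hz).  Updates that would leave [0, 50] are
ignored; all weights start at zero (p = 0).  A component therefore
travels between the fully depressed and fully potentiated states over
50 consecutive spikes of the appropriate frequency.

"Presynaptic" is interpreted per component: the excitatory component
sees the times at which a backpropagating action potential (bAP)
reaches its dendrite segment; the inhibitory component sees the somatic
spike times of its granule cell.

## Reduced neuron and synapse dynamics

Multicompartment biophysics is out of scope here; both cell types are
conductance-based leaky integrate-and-fire units integrated by forward
Euler.  This preserves what the plasticity rule keys on — the three
firing-rate regimes — and the mechanism chain that produces synaptic
columns: strong input → high-frequency MC firing → bAPs potentiate
excitatory components along the dendrites → GCs fire at high frequency
→ inhibitory components potentiate → local GABA accumulates and blocks
bAPs far from the soma → distal components see lower event rates and
depress.

Key quantitative choices (units, default, rationale):

- **Membrane**: MC τ = 20 ms, g_leak = 10 nS, rest/reset −60 mV,
  threshold −52 mV, refractory 2 ms; GC τ = 20 ms, g_leak = 0.3 nS,
  rest −65 mV, threshold −50 mV, refractory 5 ms.  The depolarized MC
  rest puts level-2 inputs ~2 mV below threshold, so they fire only
  with noise and are the first to be silenced by inhibition, while
  levels 3-4 remain suprathreshold with a ~10 mV margin.
- **Input conversion**: aggregate conductance
  g(s) = coefficient · 10 nS · (s/4)³.  The ceiling (10 nS at strength
  4, unit concentration) is the reference aggregate input; the cubic
  exponent places the strength-2/strength-3 boundary across the firing
  threshold (verified by `calibrate_thresholds`, which bisects the
  threshold if a custom configuration breaks the separation).
- **Sniffing**: each sniff (4-10 Hz; default 5 Hz) delivers an
  alpha-shaped conductance transient (rise 40 ms) scaled by g(s); the
  waveform itself is a modelling choice, only its strength scaling is
  constrained.
- **Synapses**: lumped AMPA+NMDA excitation with a single 30 ms decay
  (no NMDA voltage dependence), GABA-A inhibition with 18 ms decay;
  ceilings g_max_exc = 4 nS, g_max_inh = 1 nS per component.
- **bAP gating**: spikes propagate at 0.5 mm/ms and stop at the first
  segment where the cumulative inhibitory conductance along the path
  reaches 35 nS — a deterministic cumulative-inhibition block.
- **Somatic inhibition**: each GC spike adds its component weight,
  attenuated by exp(−d/2 mm) and scaled by 0.25, to the MC's somatic
  GABA conductance, which saturates at 3 nS.  The saturation models
  shunting: it lets lateral inhibition silence noise-driven and weak
  cells (small threshold margin) without dragging strongly driven cells
  into the 4-30 Hz depression band, which would otherwise erode their
  excitatory weights and collapse the granule field.
- **Background**: independent Poisson conductance kicks per cell
  (MC: 4 nS at 30 Hz with a fast 4 ms decay, one spike per effective
  kick; GC: 1 nS at 0.5 Hz), producing ~2 Hz spontaneous MC firing.
  At that rate the ISI distribution is dominated by the LTD band, so p
  stays pinned at its floor during rest — rest periods are
  plasticity-neutral, as the rate-boundary reading of the rule intends.
- **Integration**: dt = 0.1 ms by default; the reduced preset uses
  0.5 ms, which resolves the 33/250 ms plasticity boundaries and the
  ~10 ms burst ISIs with large margin while keeping multi-minute
  training sweeps tractable on one core.

## Odor panels

The reference glomerular maps behind the 72-odor panel are not
deposited, so `generate_panel` draws them: each odor activates a
configurable fraction (default 0.25) of the responsive glomeruli at
levels 1-4 (default level probabilities 0.35/0.30/0.20/0.15), with at
least one glomerulus at level ≥ 3 so every odor is suprathreshold
somewhere.  Exactly `n_responsive` glomerulus columns are nonzero; at
the default scale (100, 72, 74) this reproduces the 370/130 split of
mitral cells with and without odor input.  Pairs of odors can be forced
into a target band of Pearson similarity by mutating one odor away from
a shared template one glomerulus at a time.  The sparsity and strength
histogram of the real maps are unpublished; both are exposed as
parameters rather than fixed.

## Protocols and analysis

A protocol is 5 s rest, then each experienced odor for 5 s with a 5 s
trailing rest (presented low-to-high total input strength by default;
total strength = summed strength vector, ties broken by index), then
the probe ("new") odor for 5 s.  The naive control presents only the
probe, with its onset padded to match the experience condition, and the
same network and simulation seeds are reused across conditions so only
protocol content differs.  Plasticity is never reset between phases.

Analysis quantities:

- **Population sparseness** S over per-cell mean rates,
  S = (1 − (Σr_i/N)²/(Σr_i²/N)) / (1 − 1/N).  The standard
  population-sparseness bracket reading is used; it gives S = 0 for a
  uniform population and S = 1 for a one-hot population.  All-zero
  windows return NaN and propagate as missing data.
- **Per-sniff traces** evaluate S in each sniff's window; a cumulative
  variant grows the window from odor onset ("one period of odor
  input") and is the input to the half-time fit because it is far less
  noisy at desk scale.
- **Coherence** K_ij = ΣXY/√(ΣX·ΣY) over binarized 20 ms bins.  The
  square-root normalization of the underlying normalized
  cross-correlation construction is used — without the root, K would
  not be bounded by 1 nor equal 1 for identical trains.  Pairs with an
  empty train contribute 0.  The network coherence is the mean over
  distinct pairs.
- **Between-response correlation** C_xy: per-cell Pearson correlation
  of per-sniff spike counts to two odors, averaged over cells;
  zero-variance cells are skipped and counted.
- **Half-time of sparseness** S_1/2: bounded least-squares fit of
  S(t) = A2 + (A1−A2)/(1+(t/x0)^h) with a free Hill exponent
  (initialization: endpoints of the trace, x0 at the interpolated
  half-range crossing, h = 2); S_1/2 is the time at which the fit
  crosses the midpoint of its asymptotes (= x0).  The formula's
  exponent is typeset ambiguously in the source description; a flag
  allows fixing it instead.  Degenerate or non-convergent fits are
  flagged and fall back to the raw trace's half-range crossing.
- **Odor similarity**: Pearson correlation of the per-MC strength
  vectors (each MC inherits its home glomerulus's strength).

## What the synthetic conditions do and do not show

The desk-scale experiments (reduced preset, 8-10 synthetic odors,
counts {0,1,3,5}, 5 seeds, two probe odors) reproduce the experience
effects as trends: last-sniff mitral sparseness rises with the number
of prior odors, granule sparseness falls, network coherence and
between-response correlation fall, mean component weights rise, and a
single prior odor shortens the mean sparseness half-time.  The
first-sniff effects are larger than the last-sniff effects, as in the
full-scale phenomenology.  Because the reduced network's sparseness
dynamic range is compressed (traces move within roughly 0.78-0.93
rather than from near zero), the half-time effect is resolvable in the
condition means but not reliably seed-by-seed; the trend assertions are
therefore made on seed-means.  Synthetic panels share only the
summary statistics of real glomerular maps (integer levels, sparsity,
pairwise correlation); passing trends here demonstrate the mechanism,
not quantitative agreement with any real odor set.

## Numerical and degenerate-input conventions

ISI boundaries are classified exactly as stated (33 ms → LTP side,
250 ms → no-change side).  Simultaneous presynaptic events cannot occur
within a component (one spike per cell per step).  GCs left without
contacts by density thinning are attached to their nearest segment, so
the census is exact and no cell is isolated.  Networks, panels, sniff
trains and epochs are bit-reproducible for a fixed seed; one master
seed is split into labelled child streams (`split_seed`).  Nonfinite
membrane state raises a simulation error naming the first offending
cell and time.

## Known limitations

No channel kinetics, dendritic cable properties, gap junctions,
periglomerular or tufted cells; NMDA voltage dependence omitted; one
plasticity site per contact on the granule side; the 1-D tract ignores
3-D glomerular geometry (adequate for sparse, segregated inputs, which
is the regime simulated here).  GC-to-MC convergence statistics are
free parameters (mean contacts per GC defaults to 6).  Full-scale
(500 MC) multi-odor training runs are supported but slow on one core;
all shipped experiments use the reduced preset.
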