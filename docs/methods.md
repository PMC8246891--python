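# Methods

## The model

`bgsim` simulates the primate basal ganglia as a network of leaky
integrate-and-fire (LIF) neurons spanning five nuclei — striatal medium spiny
neurons (MSN) and fast-spiking interneurons (FSI), the subthalamic nucleus
(STN), and the external and internal globus pallidus (GPe, GPi) — driven by
three extrinsic Poisson input populations: cortico-striatal neurons (CSN,
2 Hz baseline), pyramidal-tract neurons (PTN, 15 Hz) and the
centromedian/parafascicular thalamus (CM/Pf, 4 Hz).

Subthreshold dynamics follow

    tau_m dV/dt = -V + V_in(t),          V_in = V_C + sum of PSPs,

with all resting potentials shifted to 0 mV. When V reaches the nucleus
threshold theta, a spike is emitted, V resets to 0 and the neuron is
refractory for t_ref = 2 ms (V clamped, synaptic state still evolving).
Synapses inject *potentials*, not currents: each arriving spike starts an
alpha-function PSP

    f_n(t) = s * A_n * (t / tau_n) * exp(1 - t / tau_n)

per receptor type n (AMPA and NMDA for glutamatergic contacts, GABA_A for
GABAergic ones; s = +1 / -1). Peak amplitudes are A_AMPA = 1 mV,
A_NMDA = 0.025 mV, A_GABAA = 0.25 mV. The published kinetic constants are
PSP *half-times* D_n (5, 100, 5 ms); "half-time" is read by default as the
decay time from the kernel peak to half the peak, giving
tau_n = D_n / 1.6783 (the root of u e^(1-u) = 1/2, minus one). The
alternative exponential-half-life reading tau_n = D_n / ln 2 can be selected
with `FixedParams.half_time_mode = "log2"`; the two differ by ~18% in
tau and change no qualitative behaviour.

### Connectivity

For a projection Y -> X the expected number of synapses per target neuron is

    nu(Y->X) = P(Y->X) * (n_Y / n_X) * alpha(Y->X),

where alpha is the mean bouton count per source axon, P the fraction of Y
neurons projecting, and n_Y / n_X the population ratio (afferent alphas are
normalized to 12,000-neuron input pools). With redundancy rho = 3 synaptic
contacts per axon per target dendritic tree, each target neuron is wired to
nu / rho distinct source neurons; the fractional part is realized as a
Bernoulli draw, so the expectation is exact. Redundancy enters the dynamics
as a weight multiplier (w = gamma * rho) rather than duplicated synapse rows
— exactly equivalent under the linearity of the PSP sum, and cheaper.

Dendrites are single-compartment finite cables with sealed ends. A synapse
at fractional position p on a cable of electrotonic length
L = l * sqrt((4/d) * (R_i/R_m)) is attenuated by
gamma = cosh(L(1-p)) / cosh(L). Synapse locations are set to the midpoint of
their published intervals.

Populations are divided into *channels* (competing action options, 1/5000 of
the real counts per channel). Focused projections connect channel to
channel; diffuse ones (STN and CM/Pf efferents) connect all to all. CSN and
PTN have one input pool per channel; CM/Pf is a single shared pool.

Default graph: 12 internal projections (MSN->{MSN,GPe,GPi}, FSI->{MSN,FSI},
STN->{MSN,FSI,GPe,GPi}, GPe->{STN,GPe,GPi}) and 10 afferent ones
(CSN->{MSN,FSI}, PTN->{MSN,FSI,STN}, CM/Pf->all five nuclei). Pallido-
striatal feedback (GPe->MSN/FSI) has published projection fractions but no
published bouton counts; those edges are accepted from a configuration file
when an alpha is supplied but are not part of the default graph. The
hyperdirect PTN->STN bouton count is likewise unpublished; the package
defaults its range to the 0–1 band of the other small re-scaled afferents
(PTN->FSI, CM/Pf->STN). Synapse locations without published intervals
(FSI->FSI, STN->MSN/FSI, CM/Pf->STN/GPe/GPi, PTN->FSI) default to the full
dendrite, midpoint 0.5. Autapses are excluded in MSN->MSN, FSI->FSI and
GPe->GPe. Transmission delays default to 1 ms on every edge and are
configurable per projection.

### Numerics

Clock-driven integration with dt = 0.1 ms. The alpha kernel is implemented
as two coupled first-order states with an exact exponential update per step,
and the membrane equation uses its exact propagator with V_in held constant
over the step; the only discretization effects are the stepwise-constant
drive, threshold detection at step boundaries, and delays quantized to dt
(minimum one step). Halving dt changes population rates by well under 2% on
desk-scale fixtures. Spike delivery uses a ring buffer indexed by arrival
step; the numba-compiled kernel is deterministic given the pre-drawn input
spike trains, so runs are bit-reproducible per seed.

## Parameter sampling and population scaling

The anatomical degrees of freedom (bouton counts, synapse locations, firing
thresholds) are published as optimized *intervals*, not point values.
`sample_parameterization` draws each ranged parameter uniformly inside its
interval, which satisfies the anatomical objective by construction.

Tonic inputs V_C (one per nucleus) are the free parameters of the
population-to-spiking translation and have no published intervals. Sampled
parameterizations initialize them from a first-order steady-state estimate:
the stationary mean synaptic drive onto each nucleus is computed with every
population at a target rest rate (MSN 0.3, FSI 10, STN 20, GPe 60, GPi
70 Hz — the centres of the plausible striatal bands and typical awake
primate pallidal/subthalamic values), the constant-drive LIF rate formula
ISI = t_ref + tau_m ln(mu/(mu - theta)) is inverted for the required total
mean drive mu, and V_C is the difference, minus a per-nucleus fluctuation
margin (4, 1, 1.5, 0, 0 mV for MSN, FSI, STN, GPe, GPi) that compensates
for shot-noise-driven firing in the near-threshold populations. The margins
were fixed once from pilot rest runs and are not tuned per seed; a +-0.5 mV
uniform jitter keeps sampled models from being deterministic functions of
the anatomy draw. This is an initialization, not a calibration: the
hypersphere grid search below remains the precise instrument.

`scale_populations` shrinks every nucleus and input pool by a common factor
(rounded, minimum one neuron) for desk-scale work, rescaling each alpha so
that nu — and therefore every neuron's expected synaptic input — is
preserved exactly. Anatomical validation converts the stored alpha back to
its full-scale equivalent before range-checking. When a scaled source pool
is smaller than the required number of distinct sources, the builder falls
back to sampling with replacement and logs a warning; in-degree (synapse
count) is preserved either way.

## Physiological scoring and calibration

The physiological-value objective compares simulated mean rates against
per-(condition, nucleus) intervals: five rest comparisons plus a battery of
nine emulated antagonist injections — in GPe: AMPA, NMDA, AMPA+NMDA,
GABA_A; in GPi: AMPA, NMDA, AMPA+NMDA, GABA_A, AMPA+NMDA+GABA_A — each
realized by zeroing that receptor's contribution onto the target nucleus.
The score F counts satisfied comparisons (0–14). The published rest
intervals retained as defaults are MSN [0.05, 1] Hz and FSI [7.8, 14] Hz;
the remaining intervals are figure-level in the source literature and must
be supplied by configuration (fixtures generate synthetic tables instead).
The exact membership of the nine-condition battery is reconstructed from
the published figure groupings and is fully configurable.

Calibration evaluates F on a regular 5-D grid of tonic inputs and returns
the most central fully-plausible point: the feasible grid point whose
distance to the nearest infeasible grid point (Euclidean in grid units by
default; Chebyshev — the literal cube test — as an option) is maximal.
Ties break toward the componentwise median of the feasible set, then
lexicographically, making the result deterministic. Grid-boundary points
have no recorded infeasible neighbours beyond the grid, so planted-region
recovery is exact only for regions interior to the grid; an empty feasible
set is reported with the best score achieved rather than raised.

Blocking every receptor in a nucleus removes all synaptic variance, so its
neurons relax to clock-like tonic firing (near-zero ISI CV) — the expected
signature of complete pharmacological isolation. Deactivation effects add
nearly linearly as long as rates stay away from the 0 Hz floor; combined
blocks that silence a nucleus saturate and break additivity.

## Action-selection benchmarks

A channel's salience s in [0, 1] maps linearly onto the firing rate of a
500-neuron activated subset (scaled with the model) of its CSN pool
(2 -> 20 Hz) and PTN pool (15 -> 46 Hz); CM/Pf stays constant (4 Hz unless
swept). Selection is read at the GPi: e_i = max(0, 1 - y_i / y_rest),
e_w = max_i e_i, d_w = (sum e_i - e_w) / sum e_i (undefined when no channel
is selected; undefined conditions are excluded from the distortion sum).
The default grid tests both saliences over 0..1 in steps of 0.1 (121
conditions), so the analytic optimum is e_sigma = 121 with d_sigma = 0.
Models use three channels with the third held at baseline. The winner label
is "both" when |e_1 - e_2| < 0.1 (absolute rule); the 5%-relative rule is
selectable. The rest reference y_rest is measured from an unstimulated run
of the same network and held fixed across CM/Pf levels, so thalamic sweeps
quantify erosion of selectivity against a common baseline.

Circuit disruptions: replacing MSN->MSN or FSI->MSN synapses by independent
Poisson processes at the measured rest rate of the source population (same
synapse count, weights and delays; independence across synapses is assumed,
as nothing in the source constrains shared rate fluctuations), and
rewiring STN->GPi or STN->GPe from diffuse to focused with unchanged
in-degree expectation.

Input-sensitivity sweeps activate subsets of one input population (default
sizes 250–4,000, scaled) across that population's printed rate span and
classify each nucleus response as up/down/flat from a linear fit pooled
over seeds: a trend requires the fitted total change to exceed
max(0.05 Hz, 10% of the baseline response). The absolute floor sits above
the pooled rate-estimation noise but below the sub-1 Hz dynamic range of
the MSNs, whose suppression by thalamic drive would otherwise be
unclassifiable. The significance criterion behind the published flat
entries is not stated; this rule is the package's own operationalization.

## Desk-scale fixtures and what the tests show

`make_fixture` samples a parameterization, scales it (default 0.05: ~550
neurons per channel-set instead of ~11,000), and derives a plausibility
table from a pilot run of the sampled model itself (intervals at +-20% of
the measured rates, with a 0.5 Hz absolute floor), guaranteeing a non-empty
feasible calibration region. Fixtures therefore exercise the full scoring
and calibration machinery but do not reproduce the original models' exact
rates: passing tests demonstrate the machinery and the circuit-level
directional phenomena (cortical drive selecting channels, thalamic drive
suppressing selection, disruption effects on efficiency and distortion),
not quantitative agreement with any specific published parameterization,
whose point values are not in the open tables.

Directional benchmarks run at scales 0.05–0.08 with 1.4–2 s simulations
(half warm-up), three channels and 3x3 salience grids, sized so the whole
suite completes in minutes on one CPU; each direction is required in at
least 4 of 5 seeds. Two caveats at these sizes: the STN holds only 2–3
neurons per channel, so focused/diffuse rewiring tests use the largest
fixture scale; and the distortion change under striatal-inhibition removal
(as opposed to its efficiency change, which reproduces robustly) is within
seed noise and is not asserted.

## Known limitations

- All neurons of a nucleus share thresholds, tonic inputs and in-degree
  statistics; simulated rate and CV distributions are accordingly narrower
  than in vivo ones.
- NMDA kernels have no voltage dependence (magnesium block is not
  modelled); synapses drive potentials, not conductances.
- No spatial geometry: delays are per-projection constants, not
  distance-dependent.
- The spectrum estimator uses a single untapered 10-s window (1 ms bins) of
  the summed population spike counts; band peaks of single-window
  periodograms fluctuate with the chi-squared statistics of the estimator.
- Dopamine, plasticity and Parkinsonian perturbations are out of scope.
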