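# Methods

## Scope and philosophy

`neocolumn` is a reduced re-implementation of the canonical
neocortical-column forward model used to interpret MEG/EEG primary
current sources.  It keeps the features that determine the measurable
observables — layered pyramidal populations with long, aligned apical
dendrites; somatic basket inhibition; layer-specific proximal/distal
exogenous drive; the dipole, LFP, CSD and spiking read-outs — while
deliberately simplifying the single-cell biophysics to a minimal
channel set that spikes, adapts and rests stably.  It is a scientific
tool for studying *mechanisms of signal generation*, not a fit to any
recorded dataset.

## Cell templates

| class | compartments | apical z-extent |
|---|---|---|
| L2/3 pyramidal | soma, 2 basal, 3 apical | 390 µm |
| L5 pyramidal | soma, 2 basal, 4 apical | 850 µm |
| L2/3, L5 basket | soma only | — |

Passive parameters: C_m = 1 µF/cm², R_a = 200 Ω·cm, v_rest = −65 mV.
Compartment geometry is not constrained by any published morphology;
the trees are the smallest that distinguish proximal vs distal
targeting and give L5 a longer apical axis than L2/3 (which sets the
relative layer contributions to the dipole).

Active mechanisms (gbar in mS/cm²): pyramidal soma
{leak 0.05, Na 150, K_dr 100, K_m 1}; pyramidal dendrites
{leak 0.05, Na 15, K_dr 10, K_m 0.5}; L5 apical compartments
additionally {Ca_L 0.5 (squared activation gate), K_Ca 2 driven by a
first-order Ca pool (rest 0.05 µM, τ 50 ms)}; baskets
{leak 0.1, Na 150, K_dr 100}.  Na/K kinetics follow the standard
Traub-style rate functions; K_m is the usual slow muscarinic gate
(τ ≈ 150 ms near rest), giving spike-frequency adaptation.  The Ca_L
activation gate is squared specifically so the resting Ca window
current is negligible and the Ca pool rests near its floor.

**Rest balancing.**  Rather than tuning conductances until the cell
happens to rest at −65 mV, each compartment's leak reversal is solved
at build time so the summed window currents vanish exactly at v_rest.
The resting state is therefore an exact fixed point: an undriven
network stays flat to machine precision, which makes "dipole baseline
= 0" a structural property instead of a numerical accident.

Synapse kinetics (rise/decay ms, reversal mV): AMPA 0.5/5, 0;
NMDA 1/20, 0 with the Jahr–Stevens Mg block (slope 0.062 /mV,
[Mg]/3.57); GABA_A 0.5/5, −80; GABA_B 1/20, −80.  The bi-exponential
kernel is peak-normalised so a configured weight is the peak
conductance in µS — this makes the worked example's weight table
directly interpretable.  A weight delivered to a multi-compartment
site group is split evenly across the group.

## Network

Pyramidal cells sit on a 10×10, 100-µm grid per layer (L5 somata at
z = 0 µm, L2/3 at z = 1000 µm); 35 basket cells interleave on a
sparser grid offset by half a spacing.  The default connectivity table
contains, per layer, recurrent pyramidal AMPA+NMDA excitation, a
pyramidal→basket→pyramidal loop (GABA_A at the soma plus slower
GABA_B), basket↔basket inhibition, and L2/3→L5 feedforward excitation.
Pair weights fall off in-plane as exp(−d²/λ²) (λ = 300 µm excitatory,
500 µm inhibitory); autapses are removed.  Weights (0.25–50 ×10⁻³ µS)
were chosen once so that the undriven network is silent and the
worked-example drive produces a transient, non-runaway response.

## Drives

One independent drive unit per targeted cell (no shared-input
correlation).  Seeding: drive *k* on trial *j* draws from a stream
seeded with `master + 1000·j + k`, so trials are independent and every
result is a pure function of (network, settings).

* evoked: `numspikes` draws from N(μ, σ²); negative draws are
  resampled (events are causal); σ = 0 degenerates to exactly μ.
* rhythmic: burst centers on a `1000/rate` ms comb from `t_start`,
  jittered N(0, σ²) per unit; bursts emit `numspikes` events at 10-ms
  spacing, shrunk to fit one inter-burst interval.
* poisson: count ~ Poisson(rate·T), times uniform.
* tonic: constant nA injection at the soma over a window.

Proximal drives attach to basal+proximal-apical pyramidal sites and
basket somata; distal drives to apical tufts (optionally L2/3 basket
somata, on by default — exposed as `target_distal_basket`).

## Numerics

Backward Euler on each cell's tree for voltage (dense per-cell solve,
batched over cells of a class; unconditionally stable), exponential
Euler for gates using step-start voltage, exact exponential decay of
the synaptic state pair.  dt = 0.025 ms by default (dt ≤ 0.1 ms
enforced).  Conductances are frozen over a step, so the voltage update
is linear; the NMDA Mg factor uses the step-start voltage.  Spike
detection: upward 0 mV soma crossing, 3 ms refractory — detection
only.  Events are delivered on the first time-grid point at or after
emission + delay (≤ dt of quantisation).  A displaced passive
compartment matches its closed-form exponential decay within 0.5% at
the default dt; halving dt moves a subthreshold driven voltage trace
by well under 1 mV.

Dipole: p(t) = Σ over parent–child pairs of i_axial·Δz, with Δz the
signed pial-axis separation of compartment centers; nA·µm → nAm via
10⁻⁶ (µm → m).  Deep-to-superficial current is positive, so proximal
excitation deflects the aggregate dipole upward and distal excitation
downward.  LFP: point-source sum φ = Σ I_tm/(4πσr), σ = 0.3 S/m,
with membrane currents obtained from axial inflow (Kirchhoff), which
makes per-cell current conservation exact.  CSD: −σ·Δ²φ/h² on a
uniform vertical electrode grid (h in µm, as supplied).  Optional
dipole post-processing (Hamming smoothing, default 30 samples; user
scaling) returns copies that keep the raw record.

Spectra: Welch with 1-s Hamming segments (or the longest the record
allows), 50% overlap, linear detrend.  Band peak extraction breaks
ties toward the lower frequency.  RMSE resamples the target onto the
simulation grid by linear interpolation.

## Optimization

Evoked drives are optimized sequentially in order of μ, each over its
own window [μ−3σ, μ+3σ] clipped to [0, tstop], with bounded
Nelder–Mead and a per-drive share of the simulation budget; the best
evaluated vector is kept and the input network is returned when no
candidate improves the full-window RMSE.  Windows are disjoint and
drive-local by construction; overlapping-response interactions are
only resolved through the final full-window comparison — a known
simplification.  On single-cell synthetic targets the procedure
recovers a 5-ms μ perturbation to well under 2 ms and a perturbed
weight to a few percent within 20–50 simulations.

## Problem sizes used in the shipped checks

The bundled tests and the acceptance script use the full 270-cell
column for the worked-example ERP (100 ms) and the alpha workflow
(2 s, 10 bursts/s, σ = 20 ms jitter, weak 3×10⁻³ µS AMPA weights onto
pyramidal cells only), a reduced 3×3-grid column for contract tests
(determinism, null connections, drive targeting), and single-cell
networks for closed-form and optimizer checks.  Drive statistics use
10,000 drive units.

## What the synthetic data does and does not show

All inputs are generated by the package itself: seeded drive trains,
synthetic target waveforms (sums of Gaussians), and synthetic
potential profiles for the CSD identities.  Passing tests therefore
demonstrate internal correctness (units, sign conventions, stated
statistical moments, convergence, determinism) and qualitative
workflow behaviour (alpha peak in band, proximal-drive polarity) — not
agreement with recorded MEG/EEG data, which would require the original
published biophysics and real source-localised waveforms.

## Known limitations

* Channel kinetics and morphologies are reduced stand-ins; absolute
  dipole magnitudes are smaller than published column models and are
  meant to be used with the user scaling factor.
* Point-source LFP only (no line sources); infinite homogeneous medium.
* No cell-level parallelism; trial-level parallelism only, via the
  `trial_map` hook.
* No shared-input correlation across drive units.
* Rhythmic drives use a jittered-burst generator; beta/gamma variants
  are parameter choices of the same generator, not separately tuned
  workflows.
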