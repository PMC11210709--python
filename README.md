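# neocolumn

A reduced, biophysically principled simulator of a neocortical column
that generates the **primary current dipole** underlying MEG/EEG
signals, together with the multiscale observables needed to interpret
them: spiking, extracellular local field potentials (LFP) and laminar
current-source density (CSD).

## Who it is for

Researchers who want a circuit-level account of non-invasive
electrophysiology: what pattern of layer-specific synaptic input to a
cortical column produces a measured evoked response or a low-frequency
rhythm?  The package is a scripting library plus a small CLI; no
recorded data is required — all inputs are model parameters and
(optionally) a target source waveform in nAm.

## The model

The column holds, per layer (L2/3 and L5), 100 pyramidal cells on a
10×10 grid (100 µm spacing) and 35 interleaved basket interneurons —
270 cells in total.  Pyramidal cells are small compartmental trees
(soma, two basal dendrites, an apical chain; the L5 apical axis is
longer than the L2/3 one) with conductance-based membrane dynamics
(transient Na⁺, delayed-rectifier K⁺, slow muscarinic K⁺, and on L5
apical dendrites an L-type Ca²⁺ current with a Ca²⁺-activated K⁺
current).  Basket cells are single-compartment Na⁺/K⁺ point neurons.
Synapses (AMPA, NMDA with Mg²⁺ block, GABA_A, GABA_B) are
bi-exponential conductances normalised so a weight is the peak
conductance in µS.

Exogenous **drives** deliver layer-specific spike trains:

* *evoked* — per targeted cell, `numspikes` events drawn from
  N(μ, σ²), for stimulus-locked responses;
* *rhythmic* — jittered 10-ms-spaced spike bursts on a regular comb
  (e.g. 10 bursts/s → alpha);
* *poisson* — homogeneous Poisson trains;
* *tonic* — constant soma current injection.

Proximal drives target basal/proximal-apical dendrites and basket
somata ("feedforward"); distal drives target the apical tufts
("feedback").

The net primary dipole is the axial intracellular current in the
pyramidal dendrites weighted by the pial-axis separation it crosses,

    p(t) = Σ_pairs i_axial(t) · Δz   (nA·µm → nAm),

summed per layer, with current flowing toward the pia counted
positive.  Voltages integrate by backward Euler on each cell's tree
(dt = 0.025 ms by default); gates by exponential Euler.  LFP uses the
point-source approximation φ = Σ I/(4πσr); CSD is −σ times the second
depth-difference of the laminar LFP.

## Worked example

```python
import neocolumn as nc

net = nc.default_network()           # the canonical 270-cell column
net.add_evoked_drive(
    name="evprox1", mu=20.0, sigma=2.0, numspikes=1, location="proximal",
    weights_ampa={"L2_basket": 0.09, "L2_pyramidal": 0.02,
                  "L5_basket": 0.2, "L5_pyramidal": 8e-3},
    synaptic_delays={"L2_basket": 0.1, "L2_pyramidal": 0.1,
                     "L5_basket": 1.0, "L5_pyramidal": 1.0})
dpl = nc.simulate_dipole(net, tstop=100.0)[0]
print(f"{dpl.times[-1]:.1f} ms, peak {dpl.aggregate.max()*1000:.3f} "
      f"/ trough {dpl.aggregate.min()*1000:.3f} (x1e-3 nAm)")
```

prints

```
100.0 ms, peak 0.871 / trough -8.643 (x1e-3 nAm)
```

— the brief proximal ("feedforward thalamocortical") input at ~20 ms
drives an initial upward deflection followed by a deeper inhibition-
shaped downward lobe; `dpl.layers["L2"]` / `["L5"]` hold the per-layer
decomposition and `dpl.smooth().scale(...)` mimic the usual
post-processing.  The same network run for 2 s with weak proximal +
distal 10-Hz jittered burst drives (`neocolumn.fixtures.alpha_network`)
yields an aggregate-dipole spectrum peaking at 10 Hz, inside the
8–10 Hz alpha band.

A CLI wraps the same workflows:

```bash
neocolumn make-fixtures                 # examples/evprox1.json, alpha.json, target
neocolumn simulate --config examples/evprox1.json --out-dir out --seed 1
neocolumn psd --dipole out/dipole.txt
```

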