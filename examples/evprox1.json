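{
 "schema_version": 1,
 "templates": null,
 "network": {
  "builder": {
   "grid_shape": [
    10,
    10
   ],
   "n_basket": 35
  },
  "populations": null,
  "connectivity": null,
  "drives": [
   {
    "name": "evprox1",
    "kind": "evoked",
    "location": "proximal",
    "mu": 20.0,
    "sigma": 2.0,
    "numspikes": 1,
    "burst_rate": null,
    "rate": null,
    "amplitudes": {},
    "t_start": 0.0,
    "t_stop": null,
    "weights": {
     "ampa": {
      "L2_basket": 0.09,
      "L2_pyramidal": 0.02,
      "L5_basket": 0.2,
      "L5_pyramidal": 0.008
     }
    },
    "synaptic_delays": {
     "L2_basket": 0.1,
     "L2_pyramidal": 0.1,
     "L5_basket": 1.0,
     "L5_pyramidal": 1.0
    },
    "seed": null,
    "target_distal_basket": true
   }
  ]
 },
 "simulation": {
  "tstop": 100.0,
  "dt": 0.025,
  "n_trials": 1,
  "master_seed": 0,
  "record_voltages": false
 },
 "outputs": {
  "out_dir": "out",
  "dipole_file": "dipole.txt",
  "spikes_file": "spikes.txt",
  "lfp_file": "lfp.txt",
  "smoothing_window_ms": 0.0,
  "scaling": 1.0
 },
 "optimization": null
}
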