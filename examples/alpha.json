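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
    "name": "alpha_prox",
    "kind": "rhythmic",
    "location": "proximal",
    "mu": null,
    "sigma": 20.0,
    "numspikes": 2,
    "burst_rate": 10.0,
    "rate": null,
    "amplitudes": {},
    "t_start": 50.0,
    "t_stop": 2000.0,
    "weights": {
     "ampa": {
      "L2_pyramidal": 0.003,
      "L5_pyramidal": 0.003
     }
    },
    "synaptic_delays": {
     "L2_pyramidal": 0.1,
     "L5_pyramidal": 1.0
    },
    "seed": null,
    "target_distal_basket": false
   },
   {
    "name": "alpha_dist",
    "kind": "rhythmic",
    "location": "distal",
    "mu": null,
    "sigma": 20.0,
    "numspikes": 2,
    "burst_rate": 10.0,
    "rate": null,
    "amplitudes": {},
    "t_start": 50.0,
    "t_stop": 2000.0,
    "weights": {
     "ampa": {
      "L2_pyramidal": 0.003,
      "L5_pyramidal": 0.003
     }
    },
    "synaptic_delays": {
     "L2_pyramidal": 0.1,
     "L5_pyramidal": 1.0
    },
    "seed": null,
    "target_distal_basket": false
   }
  ]
 },
 "simulation": {
  "tstop": 2000.0,
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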