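# Desk-scale synthetic-world configuration for the analysis drivers.
# The archival constants (h = 4500 km, 1000 folds) are the library defaults;
# here h is matched to the synthetic world's spatial correlation structure
# and the fold count is reduced to 25 for desk-scale runtime.
seed: 1
n_folds: 25
h_km: 1200.0
taus: [0.1, 0.5, 0.9]
variables: [ET, TS, TAP]
dates_per_person: 0.002
out_dir: results
world:
  grid_nlat: 36
  grid_nlon: 60
  n_societies: 340
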