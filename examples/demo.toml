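# Demo configuration: a small two-group multilayer run that completes in a
# few minutes on one CPU.  Region/volume counts are reduced from the
# study-sized defaults (90 regions, 210 volumes) to keep the demo quick.

seed = 7
log_level = "INFO"

[sim]
n_subjects = 4
n_regions = 30
n_volumes = 120
tr_seconds = 2.0
n_modules = 3
switch_nodes = [0, 10]
n_switches = 3
within_module_corr = 0.85

[ml]
window = 20
step = 0.95
omegas = [1.0]
gammas = [1.0]
n_repeats = 5
seed = 7

[scn]
sparsity_min = 0.1
sparsity_max = 0.4
sparsity_step = 0.05
n_perm = 200
n_random = 5
seed = 7

[dcm]
prior_sd = 0.125
n_restarts = 2
segment_length = 64
seed = 7
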