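# brainnetkit

Cross-scale brain-network analysis from regional MRI tables, built for
resting-state studies that compare a patient cohort against controls at
three levels at once:

1. **Structural covariance networks (SCN).** Edges are between-subject
   Pearson correlations of regional gray-matter volume (age and sex
   regressed out). Networks are binarized over a sparsity grid
   (0.05–0.40, step 0.01), summarized by graph metrics — Cp, Lp, the
   normalized indices γ, λ and small-worldness σ = γ/λ against
   degree-preserving random nulls, global/local/nodal efficiency, degree,
   betweenness — integrated into threshold-free AUCs, and compared between
   groups by a label-permutation test with BH-FDR over regions.
2. **Multilayer temporal networks.** Sliding-window (20 TR, 0.95-TR step)
   dynamic functional connectivity forms the layers; a generalized Louvain
   optimizer maximizes the multislice modularity
   Q = (1/2μ) Σ [A_ijs − γ k_is k_js/2m_s] δ(g_is, g_js) + (ω coupling) and
   each node's *switching rate* — the fraction of adjacent windows where its
   module changes — is averaged over repeated optimizations and compared
   between groups per (ω, γ) setting.
3. **Spectral effective connectivity.** A fully connected six-region linear
   stochastic model dx/dt = A x + v, observed through a canonical
   hemodynamic response, is fit to Welch cross-spectra by penalized least
   squares; the directed couplings A (Hz) are compared edge-wise between
   groups.

A synthetic-data module generates every input with known ground truth —
factor-structured GMV cohorts, modular band-limited BOLD with planted
module-switching nodes, and BOLD from a known coupling matrix — so each
estimator is validated by recovery, calibration and enumeration-oracle
tests rather than by fixture files.

## Worked example

```python
import numpy as np
import brainnetkit as bk

# structural arm: two cohorts from one factor model
spec = bk.GmvCohortSpec(n_group1=40, n_group2=40, n_regions=20, n_factors=3,
                        perturbed_regions=(4,), perturbation_scale=0.3, seed=1)
table = bk.residualize_covariates(bk.generate_gmv_cohort(spec))
net = bk.build_group_scn(table, 1)
from brainnetkit.scn import scn_metric_curves
gm, _ = scn_metric_curves(net, grid=np.arange(0.10, 0.41, 0.05), n_random=10,
                          seed=0, global_metrics=("Cp", "Lp", "Sigma"),
                          nodal_metrics=())
print("group-1 SCN AUCs:", {k: round(v, 3) for k, v in gm.auc.items()})

# functional arm: recover planted switching nodes
bold = bk.DynamicBoldSpec(n_subjects=8, n_regions=90, n_volumes=210,
                          switch_nodes=(5, 20, 35),
                          switch_epochs=(30, 60, 90, 120, 150, 180), seed=2)
subjects, truth = bk.generate_dynamic_bold(bold)
res = bk.run_switching_analysis([s.to_numpy() for s in subjects],
                                omegas=(1.0,), gammas=(1.0,),
                                n_repeats=5, seed=3)
rates = res["rates"][:, 0, :].mean(axis=0)
print("mean Q:", round(res["q"].mean(), 3))
print("top-3 switching nodes:", np.argsort(-rates)[:3].tolist())
```

prints

```
group-1 SCN AUCs: {'Cp': 0.22, 'Lp': 0.413, 'Sigma': 1.67}
mean Q: 0.389
top-3 switching nodes: [5, 20, 35]
```

The Sigma AUC of 1.67 over a grid of width 0.3 means the mean
small-worldness across sparsities is well above 1 (the modular factor
structure is small-world); Q ≈ 0.39 says the window layers are strongly
modular; and the three highest group-mean switching rates are exactly the
three nodes whose module membership was planted to change six times.

A command-line pipeline wraps the same functions
(`brainnetkit simulate gmv|bold|dcm`, `brainnetkit scn run`,
`brainnetkit multilayer run`, `brainnetkit dcm fit`,
`brainnetkit stats table1`, `brainnetkit report`); every stage reads a TOML
config, accepts a `--seed` override, and writes plain CSV/TSV/JSON outputs
with a manifest recording the config hash and seed.

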