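# ensaxs

SAXS analysis of coarse-grained conformer ensembles: Debye scattering
profiles, Bayesian maximum-entropy (BME) ensemble reweighting, and the
downstream characterization used in integrative studies of flexible,
multidomain proteins.

## The problem

Intrinsically disordered regions make proteins like HP1α — a dimeric
chromatin protein with a disordered N-tail, a folded chromodomain (CD), a
disordered hinge and a dimerizing chromo shadow domain (CSD) — a poor fit for
single-structure modelling. A measured SAXS profile reflects a weighted
average over a broad conformational ensemble. Given an ensemble of candidate
conformers (e.g. snapshots from coarse-grained MD) with per-snapshot
calculated profiles *I<sub>j</sub>(q)*, BME finds ensemble weights *w* on the
simplex minimizing

```
L(w) = χ²(w)/2 − θ S(w)

χ²(w) = Σᵢ ( (Σⱼ wⱼ Iⱼᵢ − I_exp,i) / σᵢ )²
S(w)  = −Σⱼ wⱼ log(wⱼ / w⁰ⱼ)
```

where *w⁰* are the prior (uniform) weights, θ trades data fit against
departure from the prior, and φ_eff = exp *S(w)* reports the effective
fraction of the ensemble still contributing. The reweighted ensemble is then
characterized by weighted residue–residue contact maps (11 Å CG-bead rule),
weight-modified GROMOS clustering, Guinier/P(r)/D<sub>max</sub> statistics,
and EOM-style genetic-algorithm sub-ensemble selection. A synthetic-ensemble
generator with known ground truth (rigid CD/CSD-like cores, flexible tails,
phosphoserine-driven compaction bias) stands in for MD trajectories and
measured data, so every stage is testable against truth.

## Worked example

```python
import numpy as np
from ensaxs import (
    MixtureSpec, MaxEntReweighting, delta_csd_topology, default_q_grid,
    make_mixture_ensemble, make_target_profile, radius_of_gyration,
)

# 150-conformer mixture: 70% compact (kappa=5), 30% extended (kappa=0)
spec = MixtureSpec(topology=delta_csd_topology(phosphorylated=True),
                   n_conformers=150, seed=7)
ensemble, labels = make_mixture_ensemble(spec)
fr = np.array(spec.fractions); counts = np.bincount(labels)
w_true = fr[labels] / counts[labels]
target = make_target_profile(ensemble, w_true, default_q_grid(),
                             noise_frac=0.01, seed=3)

model = MaxEntReweighting.from_ensemble(ensemble, target)
scan = model.theta_scan(np.geomspace(0.1, 1e4, 12))
theta = scan.select_elbow()            # 2.31 on this run
result = model.fit(theta)
rg = np.array([radius_of_gyration(c) for c in ensemble])
print(f"theta          {theta:.2f}")
print(f"mean Rg truth  {w_true @ rg:.2f}  reweighted {result.weights @ rg:.2f}")
print(f"compact weight {result.weights[labels == 0].sum():.3f}")
print(f"phi_eff {result.phi_eff:.3f}  reduced chi2 {result.chi2_reduced:.3f}")
```

Output from this run:

```
theta          2.31
mean Rg truth  16.67  reweighted 16.83
compact weight 0.723
phi_eff 0.883  reduced chi2 0.812
```

The reweighted mean radius of gyration lands within 1% of the ground truth,
and the summed weight on the compact subpopulation (0.72) recovers the true
70/30 mixing ratio; φ_eff = 0.88 says the fit was achieved with a mild
departure from the uniform prior.

The same flow is available from the shell:

```bash
ensaxs run-all --outdir out --seed 5          # full pipeline + manifest
ensaxs simulate-ensemble --n 100 --out e.pdb  # individual stages
ensaxs calc-saxs e.pdb --out avg.dat
ensaxs reweight e.pdb target.dat --theta 20 --weights-out w.tsv
ensaxs guinier target.dat
```

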