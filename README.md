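# fibrilbind

Cooperative nearest-neighbor ligand binding to protein fibrils: closed-form
binding isotherms, exact 1-D lattice statistical mechanics, assay-curve
fitting, and PET detection-limit calculations.

## The problem

Amyloid fibrils — tau paired helical filaments in Alzheimer's disease, for
example — present thousands of equivalent, shallow binding sites in a linear
array. Cryo-EM structures show PET tracers such as MK-6240 and GTP-1 bound in
long stacks, each ligand touching its neighbors more than the protein. Yet
measured concentration-response curves of these tracers look non-cooperative
(Hill coefficient 1), and some competition assays even look biphasic.

`fibrilbind` implements the model that reconciles these observations: a 1-D
lattice gas (Ising-type) with per-site binding and nearest-neighbor
cooperativity. It is aimed at people who fit radioligand saturation and
competition assays on fibrils, design tracers, or want to know how cheaply a
fibril can be lit up in a PET scan.

## The model

Each of a fibril's N sites is empty or holds one molecule. Per-site binding
contributes ΔG_L = −k_B T ln([L]/K_D); two ligands on adjacent sites add a
stacking energy C_L, with Boltzmann factor α_L = exp(−C_L/k_B T) (α_L > 1 is
favorable). In the infinite-lattice limit the transfer matrix gives the
saturation isotherm

    f_L = [(α_L c − 1) + √((α_L c − 1)² + 4c)] / (2 √((α_L c − 1)² + 4c)),
    c = [L]/K_D,

with midpoint EC50 = K_D/α_L: cooperativity buys apparent affinity. A
competition assay adds an inhibitor (activity [I]/K_I, self-stacking α_I,
cross-stacking χ). When the lattice is saturated the 3-state problem reduces
to a 2-state one, giving the same functional form in x = [I]/IC50 with shape
parameter β = χ²/(α_L α_I):

* β = 1 — a plain hyperbola (Hill n = 1) despite real cooperativity;
* β < 1 — steep displacement;
* β > 3 — a biphasic plateau at f_L = 1/2 (neighbors alternate L/I along
  the fibril).

The midpoint obeys IC50 = EC50_I·[L]/EC50_L — Cheng–Prusoff without the
"+1", because no empty sites remain. For detection, a fibril appears in a
PET voxel when λ·n_L·[F] ≥ M, i.e. n_L ≥ n_C = M/(λ[F]); without
cooperativity the needed free-ligand concentration is
[L]_min = K_D·n_C/(N − n_C), far below K_D when n_C ≪ N.

## Worked example

Simulate a 12-point saturation assay (K_D = 1 nM, α_L = 10, B_max = 1000
CPM, 5 % proportional noise) and refit it:

```python
import fibrilbind as fb
from fibrilbind.assay_io import ExperimentDesign, NoiseModel, generate_saturation_dataset
from fibrilbind.fitting import SignalModel, fit_saturation

curve = generate_saturation_dataset(
    fb.SaturationParams(kd=1e-9, alpha_l=10.0),
    SignalModel(bmax=1000.0),
    ExperimentDesign(1e-12, 1e-7, 12, "log"),
    NoiseModel("gaussian_proportional", 0.05, seed=7),
)
res = fit_saturation(curve, fix_ns=0.0, fix_baseline=0.0)
for name in ("kd", "alpha_l", "bmax"):
    lo, hi = res.conf_interval(name)
    print(f"{name:8s} {res.estimates[name]:.3e}  95% CI [{lo:.3e}, {hi:.3e}]")
```

prints

```
kd       1.006e-09  95% CI [9.582e-10, 1.057e-09]
alpha_l  9.788e+00  95% CI [9.088e+00, 1.054e+01]
bmax     1.005e+03  95% CI [9.761e+02, 1.034e+03]
```

— the generating values are recovered, and the fitted EC50 = K_D/α_L is
1.03e-10 M, ten-fold below the per-site K_D.

The same workflows are available from the shell. A detection-limit report
for an F-18 tracer (half-life 109.8 min) against fibrils at 100 copies per
voxel, threshold 100 counts/min:

```
$ fibrilbind detect -m 100 --half-life 109.8 --fibril-conc 100 \
      --n-sites 1000 --kd 1e-9 --conc-l 2e-10
critical_count	158.408
min_detectable_conc_M	1.882241e-10
mean_bound_count	166.6667
mean_criterion_met	True
detection_probability	0.754286
```

At one fifth of K_D the mean bound count already clears the critical count;
the tail probability accounts for per-fibril fluctuations. Other subcommands:
`isotherm` (tabulate curves), `lattice` (exact occupancies and bound-count
distributions), `mcmc` (seeded heat-bath sampling with exact cross-check),
`simulate` (synthetic curves), `fit` (model or Hill fits).

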