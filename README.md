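# condyn — time-windowed brain connectome inference from longitudinal biomarkers

Neurodegenerative diseases such as Alzheimer's progressively *decouple* the
brain's connectome: as grey matter atrophies, the effective connectivity
between regions decays. Direct longitudinal measurements of a patient's
connectome do not exist, but regional molecular biomarkers (amyloid-beta,
tau, glucose metabolism from PET) are observed repeatedly, and their spread
is well described by network diffusion: the regional burden vector x(t)
obeys

    dx/dt = −β L x + s(t)

where L = D − A is the graph Laplacian of the connectome adjacency A, β a
diffusivity, and s(t) an optional accumulation/clearance/propagation (ACP)
source (zero, linear `r·t`, or exponential `a(e^{ξt}−1)`).

`condyn` treats the connectome of a **short time window** as a latent
random variable and infers its distribution from that window's biomarker
sequence with a variational autoencoder-style scheme:

* **Latent.** A positive vector φ with log φ ~ N(ν, ΨΨ′) (Ψ lower
  triangular, fixed positive diagonal) defines the rank-one adjacency
  A = φφ′ − Diag(φφ′) and Laplacian L = Diag(A1) − A, which always
  satisfies L·1 = 0 and is positive semidefinite.
* **Decoder.** Observations are reconstructed with the rank-one diffusion
  solution f(t) = e^{−tβλ̄} (φ′x₀/φ′φ) φ, where λ̄ = φ′Lφ/φ′φ is the
  Rayleigh quotient of φ itself — closed form, no eigendecomposition or
  matrix exponential in the training loop.
* **Encoder constraint.** A soft least-squares condition ties the observed
  projection y_t = x₀′x_t to (φ′x_t)²/φ′φ, regularizing the otherwise
  underdetermined rank-one initial-value problem.
* **Objective.** Maximize the ELBO: Monte-Carlo reconstruction +
  constraint likelihood minus the closed-form Gaussian KL to a prior
  N(0, Σ) on log φ. Gradients are analytic; the optimizer is a small
  adaptive-moment scheme.

Per-window posteriors yield adjacency estimates Â = (1/M) Σ φ_k φ_k′/(φ_k′φ_k)
(diagonal zeroed). Downstream analyses compare an "early" and a "late"
window per cohort: top-K Laplacian eigenvalues (diffusion stability),
early−late adjacency difference matrices and their largest cells
(decoupling candidates, scored by precision/recall against a known
perturbation), and piecewise diffusion *meta-models* that chain one
Laplacian per window and are calibrated by grid search over (β, r, a, ξ).

Synthetic cohort generators with known ground truth stand in for clinical
PET data: flat noisy trajectories (healthy-young homeostasis), staggered
logistic accumulation curves (4-region pathological cohorts), and an
82-region tau cohort whose generating adjacency loses weight on chosen
rows/columns at a known rate (`A(t) = A₀ − rate·t`, clipped at zero).

## Worked example

Fit early/late windows to a healthy and a pathological 4-region amyloid
cohort (30 subjects, 4 timepoints) and compare the top-3 Laplacian
eigenvalues of the inferred connectomes:

```python
import numpy as np
from condyn import (PriorSpec, TrainingConfig, infer_dynamics, top_k_eigenvalues,
                    make_pathological_av45, make_healthy_av45)

times = np.linspace(0.0, 1.0, 4)
cfg = TrainingConfig(seed=0)
for name, cohort in [("healthy-young", make_healthy_av45(30, times, seed=0)),
                     ("pathological", make_pathological_av45(30, times, seed=0))]:
    fits = infer_dynamics(cohort, PriorSpec.identity(4), cfg)
    early = top_k_eigenvalues(fits[0].laplacian, 3)
    late = top_k_eigenvalues(fits[1].laplacian, 3)
    print(f"{name:14s} early {np.round(early, 4)}  late {np.round(late, 4)}")
```

prints

```
healthy-young  early [1.0034 0.9921 0.9864]  late [1.0092 0.9903 0.9771]
pathological   early [1.0737 1.0628 0.5843]  late [1.0031 0.9913 0.9829]
```

The pathological cohort's early window — while regions become abnormal in
sequence and the regional pattern is still rotating — carries a clearly
larger top eigenvalue than its settled late window (1.074 vs 1.003): the
inferred diffusion dynamics are less stable early in the disease course.
The healthy cohort shows no such ordering (1.003 vs 1.009); flat noisy
homeostasis gives statistically indistinguishable windows.

The same pipeline is available from a shell:

```
condyn simulate --family tau-decoupling --regions 82 --subjects 20 --seed 7 --out data/
condyn fit data/biomarkers.csv --epochs 300 --seed 7 --out fit/
condyn report eigen fit/adjacency_early.tsv fit/adjacency_late.tsv --top-k 3
condyn report decouple fit/adjacency_early.tsv fit/adjacency_late.tsv \
       --k 10 --truth data/truth.json
condyn metamodel data/biomarkers.csv --source zero \
       --early fit/adjacency_early.tsv --late fit/adjacency_late.tsv
```

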