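# netflux

Measuring information flow in cellular networks from expression data.

Cells relay environmental events through signal-transduction pathways
(ligand → receptor → kinase cascade → transcription factor) and onward
through gene regulatory networks (GRNs). How *strongly* a signal
propagates along these wires — and how that strength changes between,
say, normal and diseased cells — is hard to observe directly. `netflux`
estimates it indirectly: it identifies linear network models from
expression matrices and then computes certified input-to-output system
gains, the **signal transductivity** (extracellular signal → protein/TF)
and the **information transductivity** (gene → gene).

## Model and method

For temporal data (equispaced time points) a coupled pathway is modeled
by the linear recursion

    y(t+1) = C y(t) + H + B u(t) + w(t)

with protein expressions *y*, interaction matrix *C*, basal levels *H*,
extracellular signals *u* bound through *B*, and noise/residual *w*.
Subtracting the basal-only recursion isolates the input-driven
*information flow* ỹ(t+1) = Σ_{j≤t} C^{t−j} B u(j). Its worst-case
l₂ amplification is the transductivity: the smallest ρ such that

    [[CᵀPC − P + DᵀD,  CᵀPB],
     [BᵀPC,            BᵀPB − ρI]] ⪯ 0   for some P = Pᵀ ≻ 0

(the discrete-time bounded real lemma; D selects the output protein).
`netflux` minimizes ρ by bisection, constructing each Lyapunov
certificate P from the bounded-real Riccati equation and validating it
against the explicit block, and reports the amplitude gain √ρ_min (the
H∞ norm) together with the raw energy bound ρ_min. An independent
frequency-sweep oracle, max_ω σ_max(D(e^{iω}I − C)⁻¹B), cross-checks
every certified gain.

For single-time-point sample data the model is the static fixed point
y(k) = C y(k) + H + B u(k) + w(k), the transfer matrix is
T = D(I − C)⁻¹B, and the transductivity is σ_max(T) (the absolute value
for a scalar channel). A GRN is the square analogue x(t+1) = A x(t) +
v(t); the gain from gene *j* to gene *i* is computed by rearranging A
into a single-input/single-output subsystem in which x_j acts as the
input.

Model parameters are identified node by node with recursive least
squares (innovation ε = y − φᵀθ, covariance update
P ← P − PφφᵀP/(1 + φᵀPφ), parameter update θ ← θ + Pφε), run in
warm-started rounds until convergence. A synthetic-data module
generates ground-truth networks and datasets so the entire pipeline is
testable without any external download.

## Worked example: a differential two-condition comparison

Two cascades share one ligand (`ligand → R → K1 → TF1` and
`ligand → K2 → TF2`); the "disease" condition halves the K1 → TF1
coupling. We sample 500 noisy static observations per condition, refit
each model, and compare per-protein transductivities:

```python
import numpy as np
from netflux import (PathwayModel, SynthScenario, generate_dataset,
                     fit_static_pathway, transductivity_table,
                     compare_conditions, perturb_edge)

C = np.zeros((5, 5)); C[1, 0] = 0.7; C[2, 1] = 0.6; C[4, 3] = 0.5
B = np.zeros((5, 1)); B[0, 0] = 1.0; B[3, 0] = 0.9
normal = PathwayModel(C=C, H=np.zeros(5), B=B,
                      node_ids=["R", "K1", "TF1", "K2", "TF2"],
                      input_ids=["ligand"], semantics="static")
disease = perturb_edge(normal, "K1", "TF1", 0.5)

sc = SynthScenario(n_nodes=5, n_inputs=1, noise_sigma=0.05,
                   n_observations=500, mode="sample", seed=11)
tables = {}
for label, model in [("normal", normal), ("disease", disease)]:
    fitted = fit_static_pathway(generate_dataset(model, sc)).model
    tables[label] = transductivity_table(fitted)
print(tables["normal"][["channel", "mode", "gain"]].to_string(index=False))
cmp = compare_conditions(tables["normal"], tables["disease"],
                         labels=("normal", "disease"))
print(cmp[["channel", "gain_normal", "gain_disease", "ratio", "flag"]]
      .to_string(index=False))
```

which prints

```
         channel       mode     gain
  all-signals->R static_svd 1.000314
 all-signals->K1 static_svd 0.701706
all-signals->TF1 static_svd 0.418300
 all-signals->K2 static_svd 0.900105
all-signals->TF2 static_svd 0.452051

         channel  gain_normal  gain_disease    ratio                   flag
all-signals->TF1     0.418300      0.207788 0.496745 loss-of-transductivity
 all-signals->K1     0.701706      0.701706 1.000000              unchanged
all-signals->TF2     0.452051      0.452051 1.000000              unchanged
  all-signals->R     1.000314      1.000314 1.000000              unchanged
 all-signals->K2     0.900105      0.900105 1.000000              unchanged
```

The estimated gains track the ground truth (e.g. TF1's true normal gain
is 1.0 · 0.7 · 0.6 = 0.42, the path product), and the comparison flags
exactly the protein downstream of the weakened edge, with ratio ≈ 0.5.

The same workflow is available from the shell:

```sh
netflux synth --nodes 8 --inputs 2 --mode sample --seed 1 --out-prefix run
netflux fit --expression run.expr.tsv --mode sample \
        --input-id u1 --input-id u2 --out-prefix run.fit
netflux transduce --model run.fit.model.json --out run.gains.tsv
netflux compare --table-a normal.gains.tsv --table-b disease.gains.tsv \
        --out diff.tsv
```

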