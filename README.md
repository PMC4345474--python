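# meshlift

**Fidelity augmentation for finite-element simulations**: solve a physics
problem on a cheap, coarse mesh, then use a Gaussian-process surrogate trained
on coarse-mesh solutions to predict what a refined-mesh solution would look
like — at a small fraction of the cost of actually refining.

The built-in physics is a 2-D model of endovascular drug delivery from a
drug-coated balloon. An arterial cross-section (annulus, lumen radius
R = 3 mm, wall thickness W = 0.5 mm) receives a transient zotarolimus flux on
its lumen-facing (mural) surface while the balloon is inflated (30 s); free
drug then diffuses across the wall, reversibly binds to saturable tissue
sites, and drains through a perfect sink at the adventitia:

    ∂C/∂t = D_w ∇²C − k_a C (B_M − B) + k_d B
    ∂B/∂t =          k_a C (B_M − B) − k_d B

Free (C) and bound (B) concentration fields are extracted 1 h after
inflation. The package is aimed at researchers in computational physiology
and medical-device modelling who want to evaluate this style of
machine-learning fidelity lift on their own solvers — external node/solution
tables are accepted alongside the built-in model.

## How the learning works

1. **Hierarchy** — the annulus is Delaunay-triangulated (baseline, L0) and
   refined three times by longest-edge bisection (L1–L3). Bisection never
   moves a node, so node sets nest exactly across levels.
2. **Features** — for each baseline node: distances to its J nearest
   neighbours (cityblock, euclidean or mahalanobis metric), the coarse
   solution at those neighbours, and at the node itself — q = 2J+1 features.
3. **Surrogate** — ordinary Kriging with the product correlation
   `R(x,x′) = Π_j exp(−θ_j |Δx_j|²)`; θ estimated by concentrated maximum
   likelihood via the DIRECT global optimizer, all algebra through the
   Cholesky factor A with A′A = R.
4. **Evaluation** — trained on L0 features → L1 targets, deployed on L1
   features, scored against the L3 "truth"; anchored by the reference errors
   RMSE₀₃ (baseline vs truth) and RMSE₁₃ (Refinement 1 vs truth), with
   5-fold, 10-shuffle cross-validation reporting training fidelity.

## Worked example

`examples/02_balloon_transport.py` solves the transport problem on a
600-element baseline mesh:

```
association rate k_a = 9.618 m^3/(mol s) (from Da = 50000), dissociation rate k_d = 0.3135 1/s
peak flux J_b(0) = 4.565e-06 mol/(m^2 s); released dose 1.156e-04 kg/m^2

at t = 1 h (concentrations in mol/m^3 = mmol/l):
  free  drug: max 0.1255, near-mural mean 0.1115
  bound drug: max 0.2826 of capacity B_M = 0.356
  outer boundary (sink) free drug: 0
```

Bound drug approaches its saturation capacity near the lumen and decays
across the wall; free drug has largely cleared through the adventitial sink.

`examples/04_fidelity_experiment.py` runs the learning pipeline end to end on
a reduced hierarchy and prints the tidy RMSE table (mol m⁻³):

```
output_kind    metric  J  rmse_cv_mean  rmse_pred_vs_truth  rmse_03  rmse_13
       free cityblock 10      0.003868            0.003204 0.015440 0.006155
      bound cityblock 10      0.005991            0.009916 0.017366 0.008884
```

`rmse_03`/`rmse_13` are the raw baseline and Refinement-1 errors against the
Refinement-3 truth; `rmse_pred_vs_truth` is the deployed surrogate scored on
the same node set as `rmse_13` (directly comparable); `rmse_cv_mean` is the
cross-validated held-out error on the training targets — a different
quantity, reported separately. Refinement ordering (rmse_13 < rmse_03) holds
throughout; whether the deployed surrogate *beats* rmse_13 depends strongly
on mesh density — see `docs/methods.md` for the scale study.

The other examples cover mesh refinement (`01`) and surrogate fitting on
draws from a known Gaussian process (`03`). A thin CLI mirrors the library:

```bash
meshlift mesh --target-elements 5300 --refinements 3 --seed 1 -o outdir/
meshlift solve --mesh outdir/L0.msh --t-end 3600 -o L0_fields.csv
meshlift features --mesh outdir/L0.msh --field L0_fields.csv --J 50 -o feats.csv
meshlift run --config experiment.yaml
```

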