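# geoclique

Non-rigid registration of articulated body scans by **geodesic-compatibility
maximal-clique search** and robust skinned-model inverse kinematics.

## The problem

Aligning two surface scans of the same articulated body (a person in two
poses, a scan against a template model) starts from candidate point
correspondences produced by local feature matching — and those candidates
are contaminated by outliers that wreck any naive fit. Euclidean
side-lengths between correspondences change under articulation, so the
consistency checks used in rigid registration do not transfer. What *is*
stable is the **geodesic** distance along the surface: an articulated,
near-isometric deformation barely changes it.

`geoclique` turns that observation into an outlier filter and a full
registration pipeline, aimed at researchers working on human (or other
articulated-body) surface data who need reliable sparse correspondences and
pose estimates from noisy candidate matches.

## The method

For correspondences $c_i = (p_i^s, p_i^t)$ between source and target
surfaces:

1. **Geodesic difference** $S_{ij} = \lvert D_s(p_i^s, p_j^s) - D_t(p_i^t,
   p_j^t) \rvert$ — near zero for two correct pairs.
2. **First-order compatibility** $SC_{ij} = \exp(-S_{ij}^2 / d^2)$,
   binarized at a hard threshold: $C_{ij} = 1$ iff $SC_{ij} > \tau_{cmp}$
   (defaults $d = 0.05$ m, $\tau_{cmp} = 0.99$; use $0.999$ for slight
   motions with many matches).
3. **Second-order compatibility** $SC^2_{ij} = C_{ij} \sum_k C_{ik} C_{kj}$:
   the number of correspondences jointly compatible with both. Among $m$
   mutual inliers every entry is at least $m - 2$; outliers collect almost
   no joint support.
4. **Maximal cliques** of the binarized graph (Bron–Kerbosch with pivoting
   over a degeneracy ordering) are mutually consistent correspondence sets;
   node-guided selection keeps, per node, only its heaviest clique by
   summed $SC^2$ weight.
5. **Articulated fit** per hypothesis: a closed-form Kabsch/SVD rigid
   estimate from torso-labeled pairs ($R_0 = V U^\top$ with determinant
   correction), then minimization of

   $$E(\theta) = \sum_i \rho\big(\lVert M_i(\theta) - p_i \rVert\big)
     + \lambda_{\theta} \lVert \theta \rVert^2,\qquad
     \rho(s) = \frac{s^2}{s^2 + \sigma},$$

   over joint angles and the global rigid transform with L-BFGS
   (Geman–McClure robust loss, graduated non-convexity). Hypotheses are
   ranked by $D_{knn}$, the summed squared nearest-neighbor distance from
   the data to the deformed model, and the winner is refined with a
   consensus-expanded correspondence set plus a dense nearest-neighbor
   coupling.

Everything is testable without external datasets: a bundled tube-limb
humanoid (16 joints, hard skinning) articulates as an *exact* isometry of
its mesh edge graph, and the synthetic-scene generator plants poses,
Gaussian noise, and outlier correspondences with full ground truth.

## Worked example

```bash
python examples/04_register_scene.py
```

```
hypotheses evaluated:    5
winning clique size:     39
D_knn of winner:         0.0102 m^2
correspondence precision:   1.000
vertex RMSE:                 0.55 mm
```

A planted scene (0.6 rad random pose, 2 mm vertex noise, 30 % outlier
correspondences) is registered end to end. The winning clique's 39 pairs
are all planted inliers (precision 1.0 under the 5 cm correctness rule),
and the fitted model surface lands within 0.55 mm RMSE of the noiseless
ground truth. The other examples walk through the individual stages:
geodesic stability (`01`), the compatibility graph (`02`), clique
hypotheses (`03`), and the robust-vs-squared loss ablation (`05`).

The same pipeline is scriptable from the shell:

```bash
geoclique synth --out scene --seed 0
geoclique register --source scene/source.ply --target scene/target.ply \
    --model scene/model.npz --corrs scene/correspondences.tsv \
    --scene-dir scene --out run0
geoclique eval --result-dir run0 --scene-dir scene
```

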