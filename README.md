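# quadjrf

Tools for asking whether the **quadrate** — the cranial half of the jaw
joint in non-mammalian vertebrates — is oriented along the **joint reaction
force (JRF)** it must resist during biting. The package reconstructs jaw
muscle forces in 3D from attachment-site surface meshes, estimates joint and
bite reactions for unilateral crushing bites by rigid-body statics,
quantifies the correspondence of the quadrate's structural axis with the JRF
direction using cosine similarity against Monte-Carlo nulls, and tests
whether JRF orientation can be predicted from quadrate orientation across a
clade with phylogenetic generalized least squares (PGLS). It is aimed at
comparative biomechanists and functional morphologists working on archosaur
(especially suchian/crocodylian) feeding systems, but the machinery is
general to any taxon with a quadrate-bearing jaw joint.

## The model

For each muscle with origin/insertion attachment areas A_or and A_ins
(mm², from triangulated surface meshes) and absolute fascicle length
l_f (origin–insertion centroid chord × relative fascicle length):

- frustum volume  V = (l_f/3)·(A_or + A_ins + √(A_or·A_ins))
- physiological cross-section  PCSA = (V/l_f)·cos θ  (θ = pennation angle)
- muscle force  F = PCSA · T_specific  (default T_specific = 30 N/cm²)
- line of action  v = origin centroid − insertion centroid

Each force is distributed over the attachment-site vertices in proportion to
nodal area weights (one third of each incident triangle's area per vertex),
every nodal load pointing at the opposite attachment's centroid. The cranium
is then balanced as a rigid body on three supports — working-side joint,
balancing-side joint, bite point — and the 3-fold statically indeterminate
reaction system is resolved by the minimum-norm equilibrium solution
(pseudoinverse of the 6×9 equilibrium matrix).

Orientation correspondence is the dot product v̂_Q · v̂_JRF = cos θ of the
quadrate's unit structural axis (ventral articular surface → otic condyle)
and the unit JRF. It is tested per individual against ~1350 uniform random
directions, per sample by an empirical p-value from 10,000 resampled mean
dot products (add-one estimator, floor 1/(N+1)), across bite positions by a
variance F-test, and across the clade by component-wise PGLS under Brownian
motion, with maximum-likelihood ancestral states for phylomorphospaces.

A synthetic-data module generates skull "specimens" whose quadrate axis
rotates from dorsoventral to oblique as a flattening parameter φ evolves by
Brownian motion on a pure-birth tree, with muscle resultants tracking the
axis at a controllable angular offset δ — so every stage can be exercised
end-to-end with known ground truth.

## Worked example

```sh
quadjrf synth --out demo --n-taxa 11 --seed 7
quadjrf run --config demo/config.yaml
```

This writes `demo/results/{muscles.csv, jrf.csv, similarity.csv,
sample_test.json, pgls.csv, ancestral.csv, ancestral_corr.csv}`. For seed 7
the similarity table summarizes to:

```
bite_position  role         mean dot   sd       min      max
caudal         balancing    0.934      0.0044   0.926    0.940
caudal         working      0.881      0.0201   0.851    0.913
rostral        balancing    0.953      0.0081   0.936    0.963
rostral        working      0.953      0.0096   0.935    0.966
```

Rostral bites (long outlever, low bite force, high joint load) match the
quadrate axis best and most consistently; caudal working-side JRFs are
weaker and noticeably more variable — the variance F-test reports F = 12.7
with the caudal group in the numerator (p ≈ 2e-7), and every group-level
empirical p-value sits at the 0.0001 resampling floor. `jrf.csv` shows the
mechanical cause: moving the bite caudally raises mean bite force from
~83 N to ~254 N while the working-side joint reaction falls from ~257 N to
~119 N, destabilizing its direction.

The same analysis runs on real data: per-specimen STL/OBJ/PLY attachment
meshes, a `name,x,y,z` landmark CSV, a per-muscle parameter CSV, a Newick
time tree, and a YAML config (see `demo/config.yaml` for the schema;
`quadjrf validate --config ...` checks it before any compute).

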