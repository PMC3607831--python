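# scnmap — seed-based structural covariance network mapping

`scnmap` maps **structural covariance networks (SCNs)** from voxel-based
morphometry data: sets of brain voxels whose gray-matter (GM) volume
covaries, across subjects, with the mean GM volume of a small seed region.
It is built for the classic cross-sectional aging design — three age groups
(young / middle-aged / old), eight canonical network seeds (primary visual,
auditory and motor cortex; speech and semantic areas; salience, executive
control and default-mode nodes) — and answers two questions per network:

1. **Where is the network, per group?**  For each in-mask voxel *v*, an
   ordinary-least-squares fit of

   `GM_v = β0 + β1·seed + β2·gender + ε`

   gives the seed coefficient's Student *t* and the partial correlation
   `r = t / √(t² + ν)` (ν = n − p residual d.o.f.).  Positive-covariance
   maps are thresholded at family-wise error (FWE) *P* < 0.05 — Bonferroni
   or Freedman–Lane permutation max-T — with a cluster-extent criterion, and
   summarized as tables of cluster peaks (MNI mm, extent, maxT) and as
   hemispheric voxel counts (ipsilateral / contralateral / midline /
   whole-brain) whose trend across age groups is tagged qualitatively
   (contracting, flat, inverted-V, ...).

2. **Does the covariance *slope* differ between two groups?**  Pooling two
   groups, the interaction model

   `V_i = β0 + β1·V_j + β2·Group + β3·(V_j × Group) + ε`

   (treatment-coded Group, gender confound, single pooled error) is fit at
   every voxel; the *t* map of β3 — the slope difference — is thresholded
   the same way.

Because real cohorts of preprocessed (segmented, normalized, modulated,
smoothed) GM images are large and external, the package ships a first-class
**synthetic-cohort generator**: smooth anatomical baseline, planted
networks (sphere-union loading maps driven by latent factors, with
group-dependent amplitudes and optional factor sharing between networks), a
gender confound map, and spatially smoothed Gaussian noise — all
reproducible bit-for-bit from one seed, with ground truth (truth masks,
factors, planted slopes) returned alongside.  Every pipeline stage is
validated against this ground truth.

## Worked example

A complete run from the command line (the same stages are available as
library functions in `scnmap.pipeline`):

```sh
cat > cfg.yaml <<EOF
out_dir: run
rng_seed: 42
simulate_n_per_group: 80
extent_k: 10
EOF
scnmap simulate  -c cfg.yaml   # 240 synthetic subjects + covariates + truth
scnmap map       -c cfg.yaml   # 8 seeds x 3 groups: t/beta/partial-r maps,
                               # FWE-thresholded maps, cluster tables
scnmap summarize -c cfg.yaml   # extent trajectories + bar charts
scnmap contrast  -c cfg.yaml   # pairwise slope-difference cluster tables
```

`run/summary/trajectories.tsv` then contains (excerpt):

```
seed	group	ipsilateral	contralateral	midline	wholebrain	shape
R_calcarine	Y	366	370	0	736	flat
R_calcarine	M	394	384	0	778	flat
R_calcarine	O	393	388	0	781	flat
R_heschl	Y	550	496	0	1046	contracting-then-flat
R_heschl	M	394	392	0	786	contracting-then-flat
R_heschl	O	384	376	0	760	contracting-then-flat
R_precentral	Y	249	238	0	487	inverted-V
R_precentral	M	408	397	0	805	inverted-V
R_precentral	O	249	242	0	491	inverted-V
```

Reading: the visual (calcarine-seeded) network's extent is stable across
age groups; the auditory network contracts sharply from young to
middle-aged and then plateaus; the motor network is largest in the
middle-aged group (inverted V) — exactly the trajectories planted by the
generator preset.  `run/contrasts/R_angular_Y_vs_M_clusters.tsv` shows the
planted default-mode slope difference:

```
Contrast	x	y	z	hemisphere	region	voxel_size	maxT
Y > M	33.0	39.0	27.0	right		234	12.004671296142906
```

a 234-voxel right-prefrontal cluster (peak t = 12.0 at MNI 33, 39, 27,
inside the planted sphere at 30, 38, 24) where the young group's
covariance slope with the right angular seed exceeds the middle-aged
group's.  The same contrast for the stable visual network returns an empty
table.  Every output carries a JSON sidecar with the config hash, RNG
seed, software version and threshold provenance.

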