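# Methods

## Problem setting

Expanded-tissue light-sheet imaging resolves single synapses optically:
presynaptic active zones, genetically restricted postsynaptic markers and gap
junction proteins appear as punctate clusters of a few hundred to a few
thousand voxels, riding on neuron masks whose fluorescent signal is
interrupted by gaps in label expression. This package reconstructs
connectivity from such data in five stages: neuron-mask post-processing,
punctate instance segmentation, colocalization analysis, blockwise
execution, and evaluation. A synthetic phantom generator supplies ground
truth for all of it.

All grids are z,y,x ordered, 0-based; bounding boxes are inclusive on both
ends; voxel sizes are nanometres per axis (the native acquisition grid is
anisotropic, e.g. 180 × 104 × 104 nm in z,y,x). The thresholding rule is
`foreground = value ≥ t` everywhere. Foreground connectivity is
26-adjacency (background 6) so thin diagonal neurites survive; it is
configurable.

## Neuron-mask post-processing

Chain: intensity threshold → gap bridging → morphological closing →
connected components → size filter (≥ 2000 voxels kept) → binary mask.

* **Threshold.** Otsu maximizes the between-class variance over all occupied
  gray levels under the ≥ convention; ties resolve to the lowest integer
  threshold realizing the optimal partition. Li's minimum-cross-entropy
  threshold comes from scikit-image. A constant volume is a degenerate input
  (error advising a manual value).
* **Gap bridging.** The field describes "a flexible 3D component connecting
  algorithm"; the concrete algorithm here is: per round, label components at
  26-connectivity, compute for every component pair the minimum Euclidean
  voxel-centre distance (exhaustive over surface voxels, KD-tree
  accelerated), and when it is ≤ `max_gap_voxels` (default 20) rasterize the
  3D line segment between a deterministic arg-min voxel pair (first by raster
  order), dilated by `bridge_radius` (default 1). Up to `iterations` rounds
  (default 4) or until a round adds nothing. The operation is monotone
  (never removes foreground) and component count never increases. Distance is
  measured in isotropic voxel units because the gap length is stated in
  voxels; an anisotropic variant is a config switch.
* **Closing.** One 3×3×3 morphological closing connects voxels separated by a
  single voxel; the volume is padded by one voxel so the operation stays
  extensive at the border.

## Synapse instance segmentation

`detect_sites` = probability map → threshold at 0.8 → watershed → size gate.

* **Probability providers.** The trained 3D U-Net of a production pipeline is
  replaced by a provider interface: `scaled_intensity` rescales raw
  intensity as `clip((v − lo)/(hi − lo), 0, 1)` with lo/hi given or taken
  from the 1st/99.9th percentiles (a degenerate range maps to all-zero);
  `external_model` wraps any callable, so a trained network slots in without
  the package shipping weights. The default pipeline configuration fixes
  lo = 0, hi = 255 (the 8-bit dynamic range): on sparse, zero-background
  volumes a high percentile degenerates to 0, and an explicit range keeps
  per-block classification identical to the global run.
* **Watershed seeding** is unspecified in the field description; the
  deterministic choice here: local maxima of the Euclidean distance
  transform (plateau-inclusive), visited by descending distance then raster
  order, greedily suppressed so no two seeds within one connected component
  lie closer than `min_seed_separation` (default 3 voxels). Suppression is
  per component — never across components — which is what makes blockwise
  detection bit-identical to the global computation. Flooding runs on the
  negated distance transform restricted to the foreground at 26-adjacency,
  so the output labels partition the foreground exactly.
* **Size gates** are inclusive-keep at the stated value ("smaller than X
  removed"): presynaptic 400 voxels, postsynaptic and gap-junction 200.
  "Pixels" in the source counts are read as 3D voxels.
* Site centroids are unweighted voxel centroids, independent of provider
  scaling.

## Connectivity

* **Assignment**: site → neuron when `overlap/|site| ≥ 0.5`, inclusive.
* **Contact**: a Connection is emitted per (pre, post) pair when
  `overlap/|query| ≥ 0.001`, inclusive; the *query* is the postsynaptic site
  in workflow 2 and the presynaptic site in workflow 3, making the two
  workflows symmetric. A post site touching several pre sites yields one
  Connection per pair (polyadic synapses), so connection counts can exceed
  distinct-presynaptic-site counts.
* Contact requires genuine voxel overlap by default
  (`contact_dilation_voxels = 0`); a dilation switch accommodates
  apposed-but-not-overlapping label pairs, since antibody geometry can
  separate pre- and postsynaptic signals.
* The neuron-2 "membrane" in workflow 3 is the full binary neuron mask (whole
  neurites are masked, not a hollow shell).
* Workflows: (1) detect + assign; (2) detect both markers, assign presyn to
  neuron 1, contacts from neuron-2 post sites, then count distinct connected
  presyn sites; (3) assigned presyn sites vs the neuron-2 mask; (4) detect
  only. The postsynaptic channel in workflow 2 is assumed to be
  neuron-2-specific by construction (genetically restricted label), so no
  additional mask test is applied to post sites.

## Blockwise execution

Volumes are tiled by ceil division into cubes (default edge 512) whose cores
partition the volume; each block is processed on a halo-padded crop (default
halo 64).

* **Connected components**: per-block labelings are merged by union-find over
  voxels shared between overlapping padded regions. With halo ≥ 1 every
  foreground adjacency is witnessed inside at least one padded block, so the
  merged partition equals the global partition for *any* input — not only
  when objects are halo-sized.
* **Detection**: each instance is owned by the block whose core contains its
  centroid (half-open core boxes make ownership unique); owned instances are
  written into a global label volume, relabeled in raster order, and the
  downstream assignment/contact analysis runs on the merged result. The
  result equals the unblocked pipeline whenever each site fits within the
  halo of its owning block; a heuristic warns when the halo looks small for
  the configured size gate, and sites touching a padded-block border are
  flagged.
* Blocks are pure functions of their padded input and the merge is a
  deterministic reduction, so execution order (or any scheduler) cannot
  change the result. Subvolume skipping is result-preserving: detection
  skips blocks with no above-threshold signal; skipping blocks without a
  neuron mask (the production shortcut) is available as the
  `nonempty_blocks` utility but is not applied to detection by default,
  because a marker channel can contain sites of neurons other than the one
  masked.

## Evaluation

Greedy one-to-one matching: candidate (pred, gt) pairs with IoU ≥ `min_iou`
(default 0.1 — permissive, since ground-truth curation in this field treats
any plausibly coincident cluster as the same object) sorted by descending
overlap, ties by lower pred then gt id. Precision = TP/(TP+FP), recall =
TP/(TP+FN), with empty denominators scoring 1.0. Instance-level matching is
the primary metric; a voxel-level Dice coefficient is auxiliary. An optional
evaluation region restricts both labelings first (scoring only where ground
truth exists).

## Phantom generator

The generator emulates the statistical structure the pipeline assumes, with
every parameter in `PhantomSpec`:

| parameter | default | meaning |
|---|---|---|
| volume_shape | 256³ | synthetic volume, voxels |
| n_neurons | 3 | one bounded-curvature random-walk tube per neuron, each confined to its own slab so neurons never touch |
| tube_radius_voxels | 4 | tube radius |
| tube_step_count / length | 300 / 4 | walk length (~1200-voxel arc) |
| gap_count_per_neuron / gap_length_voxels | 2 / 12 | labeling gaps; carving a sphere of radius sqrt((g/2)² + r²) leaves an inter-fragment gap of ~g, bounded above by sqrt(g² + 4r²) ≈ 14.4 ≤ 15, hence bridgeable at the default 20 |
| n_presyn_per_neuron | 40 | ellipsoids of 450–3000 voxels on tube-surface varicosities ("boutons") added to the neuron mask so ≥ 50 % site-mask overlap holds by construction |
| n_postsyn_apposed | 15 | smaller ellipsoids (250–1000 voxels) sharing a controlled 1–30 voxel overlap with their presynaptic partner on neuron 1 |
| n_noise_puncta | 0 | sub-gate puncta (20–350 voxels) in the presynaptic channel |
| background_sigma | 0 | additive Gaussian noise; the default study conditions are noise-free |
| intensities | 200 neuron / 255 sites | 8-bit channels; site intensity 255 maps to probability 1.0 under the default provider range |

Site ellipsoids are kept within ±10 % anisotropy so the distance-transform
ridge stays shorter than the 3-voxel seed suppression radius — one site, one
watershed seed. Placement uses voxel-accurate clearance (the ellipsoid grown
by 2 voxels must be free of foreign labels), which guarantees distinct
instances are never 26-connected; postsynaptic partners are the only allowed
overlap. The postsynaptic size cap of 1000 voxels makes a single overlap
voxel meet the 0.1 % contact rule inclusively. Apposition can instead be
"touching" (no overlap) to exercise the contact-dilation switch. Ground
truth (label volumes, assignment and connection tables) is recorded during
placement; `validate_dataset` re-measures every invariant from the emitted
volumes and fails loudly naming offending objects.

What the phantom does *not* model: optics (PSF, anisotropic blur),
expansion distortion, antibody chemistry, intensity variation within a
label, off-target neuron labeling, and real neuron morphology. Passing
tests therefore demonstrate correctness of the *computational* rules
(thresholds, gates, colocalization arithmetic, merge logic) under the
stated geometric conditions — not classifier performance on real
fluorescence data, which depends on the trained model plugged into the
provider interface.

## Numerical and design choices

* Deterministic label order everywhere: components are relabeled 1..K by the
  raster position of each component's first voxel, so repeated runs are
  byte-identical and blockwise merges reproduce global ids.
* Bridging tie-breaks: the arg-min voxel pair is the first minimum in raster
  order on each side; line rasterization is integer n-dimensional line
  drawing (26-connected).
* `subtract_crosstalk` clamps at zero and saturates back to the input dtype.
* Degenerate inputs: empty masks yield empty labelings; constant volumes are
  errors for Otsu/Li but legal for manual thresholds; an empty config file
  yields all defaults; unknown config keys are rejected by name, numeric
  strings are coerced with a warning.
* Problem sizes in the test suite and acceptance script (256³ phantoms,
  96³ randomized equivalence volumes, 100 × 32³ oracle masks) were chosen as
  the smallest sizes that exercise multi-block grids, halo interactions and
  the full default parameter set.

## Known limitations

* The gap-bridging pair search is quadratic in the number of components per
  round; it is intended for post-threshold neuron masks (tens of
  components), not for unfiltered speckle.
* Blockwise detection equals the global run only when sites fit within the
  halo; the package warns rather than splits silently, but extremely
  elongated instances near block faces can still be clipped.
* The evaluation matching rule (greedy by overlap) is one defensible choice;
  published pipelines rarely state theirs, so absolute precision/recall
  values are comparable only under the same rule.
* `anisotropic_distances` affects gap measurement and the distance transform
  switchably, but all defaults are isotropic voxel units, matching how gap
  lengths and size gates are stated in voxels.
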