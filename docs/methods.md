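# Methods

## Attack model

The cohort `H` is a set of patients; the attacker's background knowledge is
an *ordered* list of patient-labelled slides, one per patient.  An attack
maps every probe slide to exactly one patient (prosecutor model — the
attacker knows the target is represented in the background data).  A patient
is *f-vulnerable* if at least one of their probes is mapped back to them;
`R_s` is the fraction of vulnerable patients.  Properties relied on
throughout: `0 ≤ R_s ≤ 1`; `R_s·|H|` is an integer; a perfect assignment
gives `R_s = 1`; patients with no probes can never be vulnerable.

Patients whose probe set is empty (distance-threshold designs with large
`l`) **stay in the denominator**.  This follows the metric's literal
definition; the alternative reading (drop them) is available as
`exclude_probeless=True` on `compute_rs`, `evaluate_attack` and
`ExperimentConfig` for sensitivity analysis, but is never the default.

The nearest-neighbour attack takes the argmax of the similarity between the
probe's feature vector and each background vector.  Tie-breaking is by the
smallest background index, where the index order is the manifest insertion
order; similarity ties are detected by exact float equality (no epsilon
band, which would be measure-dependent).  This makes the whole attack
deterministic given inputs, which the reproducibility guarantees rest on.
Exact linkage of bit-identical releases uses SHA-256 digests of the raw
pixel buffer; a digest shared by two patients is treated as corrupt input,
not a tie.

Extension points deliberately left as interfaces: randomized attacks (the
assignment type only requires a mapping, so a stochastic strategy can be
evaluated by computing `R_s` per draw) and probe-revelation probabilities.
Prior-weighted `R_s` *is* implemented (`compute_weighted_rs`).

## Features and similarity

All extractors consume square inputs (default 224 px).  Whole slides are
downscaled with area (box) interpolation — the resampling kernel is a free
choice; box filtering is the standard area-preserving one — and pixel values
live in [0, 1] (8-bit inputs divided by 255).  Crops take the interior
window instead, since cropping removes the tissue's outline from view.

The default extractor `grid-stats-512` partitions the frame into an 8×8
grid and records, per cell, per-channel mean and standard deviation plus a
2-bin gradient-magnitude histogram (split fixed at 0.05 on the [0,1] scale),
L2-normalised: 8·8·(3+3+2) = 512 dimensions.  It is deterministic, needs no
downloaded weights, and is locally Lipschitz in the pixels (regression
bound: an L∞ perturbation of 0.01 moves self-cosine by < 0.05).  CNN
backbones plug into the same registry by declaring their name, output
dimension and input side; the registry enforces the declared contract at
call time.  The library's conclusions about *relative* risk orderings do not
hinge on the extractor family; the default trades raw matching power for
dependency-free determinism.

Cosine similarity is the primary measure (bounded in [−1,1],
scale-invariant); the Euclidean variant `1/(1+‖v−w‖²)` (bounded in (0,1]) is
included for comparison.

## Experiment designs

* **Pair designs** (`E1`, `E2a`): every patient must have exactly two
  slides; a fair coin decides which goes to `B`.
* **Distance thresholding** (`E2b`): slide distance is the absolute
  difference of cumulative section positions (per-cut spacings summed);
  probes are slides *strictly* farther than `l` mm from the per-patient
  random pivot.  Empty probe sets are expected and retained.
* **Sweeps**: `sweep_patients` draws a uniform `n`-patient subset, one
  random slide each to `B`, rest to `P`; `sweep_probes` restricts to
  patients with at least `p+1` slides and samples exactly `p` probes.
* **Crop designs**: windows of side 224 px (the extractor input, so no
  resampling happens after cropping) are cut from registered frames; the
  background window is centred on the tissue centroid (intensity-weighted,
  tissue darker than glass), the probe window displaced by the configured
  shift in one uniformly random *continuous* direction per pair per repeat.
  Continuous directions are the natural choice and produce the analytic
  overlap extremes at axis-aligned (maximum) and diagonal (minimum)
  directions: overlap fraction `(1−|dx|/W)(1−|dy|/W)`, clipped at 0.  The
  window centre is clamped so that both windows fit the frame; geometry that
  cannot fit raises.  Crop shifts are not supported for the non-consecutive
  design (`cE2b`), whose far-apart sections are not meaningfully registered.

One master seed drives everything: each repeat gets a spawned child seed,
and split construction, shift directions and bootstrap resampling consume
named streams from it, so a results CSV regenerates bit-identically from
its logged configuration.

## Synthetic cohorts

The phantom generator emulates the *relationships* between slides, not
histology:

* **Base texture** — a Gaussian random field (correlation length 24 px at
  the default 512-px frame) thresholded softly into tissue blobs on a light
  glass background, colourised between hematoxylin-like and eosin-like
  stains.  Each patient additionally draws morphology offsets (tissue
  fraction, stain balance, staining intensity), giving patients individual
  signatures in feature space, as distinct tissue blocks have.
* **Rescan** (`H-1`) — per-channel gain and gamma jitter (amplitude 0.04),
  sub-pixel resampling (≤ 0.75 px) and Gaussian sensor noise (sd 0.01);
  geometry untouched.
* **Section** (`H-2`) — elastic deformation by a smoothed random
  displacement field with amplitude 1.5 px/mm of cutting distance, plus
  content turnover: a smoothly-masked fraction `min(0.05·d, 1)` of the frame
  is replaced by fresh texture, modelling structures appearing and vanishing
  through the block.  Families are evolved cut by cut, so divergence between
  two sections grows with their separation.  Distance 0 with zero noise is
  the exact identity.

Amplitudes have no real-data anchor (the restricted collections' internal
similarity scale is unknowable from published numbers); they were fixed once
to reproduce the qualitative orderings that characterise slide linkage —
rescans nearly always linkable, consecutive sections linkable, risk decaying
over ~20 mm of block depth — and are not fitted to any quantitative target.
Consequently the trend tests demonstrate that the *framework* recovers the
expected orderings on data with this structure; they say nothing about the
absolute `R_s` of any real collection, and absolute synthetic values (e.g.
how fast risk decays with crop shift) should not be read across to clinical
WSIs, whose texture correlation structure is far richer.

Default problem sizes in the test suite mirror the canonical cohort shapes:
28 rescan pairs (40 repeats), 28 consecutive pairs for crop experiments
(20 repeats), and an 80-patient × 7-section block cohort at 3–5 mm spacing
(20 repeats per condition) for distance thresholds and sweeps.  Features are
memoised per slide across repeats for non-crop designs; crop designs
re-extract because the windows move each repeat.

## Reporting

Samples of `R_s` across repeats are summarised by median, type-7
(linear-interpolation) quartiles and the true min–max range without outlier
trimming, plus a percentile-bootstrap 95 % confidence interval of the
median (1000 resamples by default, deterministic per seed).  The bootstrap
targets the **median**, matching the distribution-free summary; the count
and the choice of median over mean are implementation choices.  Results
CSVs carry one row per repeat with full provenance columns and a
comment-prefixed summary block; floats are printed at 12 significant
digits so read-back is lossless at that precision.

## Known limitations

* The phantom is statistically minimal: no staining-protocol hierarchy, no
  multiple primary samples or time points, no scanner artefacts beyond
  colour jitter and noise.
* No image registration is implemented; crop designs assume pre-aligned
  pairs (synthetic pairs are generated aligned).
* The default extractor is far weaker than a trained CNN; absolute `R_s`
  values on real data would differ by extractor.
* Gigapixel pyramid formats are out of scope; inputs are pre-rendered
  8-bit PNG/TIFF thumbnails referenced from a CSV manifest.
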