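# Methods

This note records the scientific and numerical choices behind `rgbchem`:
what is computed, which knobs matter, what the synthetic data does and does
not emulate, and where the genuinely open design decisions were resolved.

## Descriptors

For an `N`-atom molecule with Cartesian coordinates in Å:

- **Distance matrix.** `R_ij` is the Euclidean distance; `R_ii = 0`. The
  component squares are summed left-to-right and squared by multiplication,
  so every entry equals a scalar evaluation of the formula bit-for-bit —
  the test suite relies on exact equality against per-entry loops.
- **Coulomb matrix.** `Z_i Z_j / R_ij` off-diagonal. The *full* variant
  carries `0.5 Z_i^2.4` on the diagonal; because those diagonal values are
  numerically much larger than the off-diagonal entries (36.9 for carbon vs
  typically < 10) they can dominate min–max scaling, which is why the
  *reduced* variant (zero diagonal) exists as an alternative green channel.
  Coincident distinct atoms raise a degenerate-geometry error.
- **Bond order.** The raw, uncorrected ReaxFF pairwise primitive:
  `BO′ = BO^σ + BO^π + BO^ππ` with each term `exp[p_odd (r/r₀)^p_even]`.
  No cutoff, taper, or overcoordination correction is applied, and no
  distance cutoff is imposed. A reference radius `r₀ ≤ 0` (the `−1`
  sentinel) disables its term exactly; a pair absent from the table yields
  `BO′ = 0` with a warning rather than an error, so one exotic pair cannot
  abort a dataset run.
- **Diagonal channels.** First ionization energy (eV) and atomic number,
  zero off-diagonal.

**Pair parameters.** The shipped table
(`data/pair_params_synthetic.txt`) is a *synthetic stand-in*: hand-set
values of realistic ReaxFF magnitude for all H/C/N/O/F pairs, in the same
roles as a force-field library file. Bond-order channels are therefore
structurally faithful (near 1 for bonded pairs, decaying steeply with
distance, σ/π/ππ composition for multiple bonds) but not numerically
traceable to any published force field. Following the observation that
fluorine in QM9-composition molecules essentially only bonds to carbon, the
O–F, F–N and F–H pairs are forced to the sentinel regardless of file
content; F–F is additionally suppressed by default (`suppress_ff=True`).

All descriptor matrices are exactly symmetric and exactly permutation
equivariant — `D(π·mol) = P_π D(mol) P_π^T` with bit-identical entries —
which is the algebraic fact the augmentation strategy rests on.

## Image encoding

Order of operations: **normalize, then fill margins**. Each property is
mapped onto `[0, 255]` first, and margin filling (including the
channel-average fill) operates on normalized values. The alternative
(normalize after filling) would make the average fill depend on the margin
size; the chosen order keeps the molecular block independent of `S`.

- **Normalization scope.** Default is per-image, per-property min–max
  (observed min → 0, max → 255; constant matrices → 0). This is
  self-contained but deliberately discards absolute scale, making images of
  different molecules incomparable in magnitude. A fixed-range scheme
  (`normalization="fixed"` with explicit `(lo, hi)` per property, clipped)
  preserves cross-molecule scale and is what the training-facing runs in
  this package use. Both schemes are tested.
- **Combined channels** (e.g. distance + ionization in red): the
  off-diagonal and diagonal properties are normalized *independently* and
  written into their disjoint cells. Joint normalization is available
  (`combined_joint_norm=True`) but not default: a numerically dominant
  diagonal would crush the off-diagonal contrast.
- **Canvas policies.** `black` fill (margin exactly 0), `average` fill
  (margin = per-channel mean of the molecular block), or bilinear `resize`.
  Offsets are top-left (`fixed`) or uniform over the `(S−N+1)²` grid
  (`random`); positioning is meaningless under resize and rejected there.
  The bilinear resampler uses half-pixel-centred source coordinates with
  edge clamping, implemented in-repo so outputs are bit-reproducible across
  runs (it agrees with `skimage.transform.resize(order=1, mode="edge")` to
  1e-12, but cross-library bit-exactness is not promised).
- **Quantization.** The pipeline is float internally; emission rounds
  half-up to uint8 (PNG is lossless, so read-back is exact). Only square
  canvases are supported; the study range is S = 32–48.

## Shuffling and augmentation

Permutations act on *positions within a class*: `groups` permutes occupants
within each element's position set (the element at every index is
unchanged), `partial` within the heavy-atom {C,N,O,F} and hydrogen position
sets, `full` over all positions, `none` is the identity. Coordinates travel
with their atoms; labels are never modified.

Per molecule, `k` permutations are drawn *without replacement* while the
strategy admits at least `k` distinct orderings (exhaustive enumeration up
to 20 000 orderings, rejection sampling above); molecules with fewer
distinct orderings fall back to duplicates with a warning. Held-out
validation/test molecules are encoded deterministically (shuffle `none`,
one image each) by default, so evaluation never depends on a permutation
draw.

## The compact CNN regressors

`S1CNN` = one `3×3` conv stage (conv → LeakyReLU → 2×2 maxpool), `S2CNN` =
two such stages, each followed by three dense layers (defaults 96 → 48 → 1).
Default widths give 201 633 parameters for S1CNN and 104 497 for S2CNN at
S = 32 — the fidelity claim is the ≈0.2 M / ≈0.1 M budget and the
one-vs-two-stage structure, not the specific widths, which published
descriptions leave open. LeakyReLU (slope 0.01) rather than plain ReLU is a
deliberate choice: with 8–48-unit layers, whole-layer ReLU death at
unlucky initializations is common and stalls MAE training.

Training: Adam (β₁ plays the role of "momentum", β₂ = 0.999), MAE loss by
default (MSE selectable), mini-batches (study range 16–128), early stopping
with `min_delta = 0` — an epoch improves only if validation loss strictly
decreases — and best-validation weight restoration. Targets are
standardized to zero mean/unit variance for the optimizer and
un-standardized inside `predict`, so all reported MAEs are in eV; without
this, sign-gradient MAE training crawls toward eV-scale targets from a
near-zero initialization. Everything is seeded and single-threaded, so
runs are exactly reproducible.

External backbones (ResNet, VGG, ...) can be registered as opaque plug-in
factories whose classification head is replaced by a scalar output; none
are bundled or required.

## Synthetic molecules: what a green test establishes

The generator emulates the *shape* of QM9-like input: 1–9 heavy atoms from
{C,N,O,F} (default weights 0.70/0.10/0.15/0.05), tree-connected with
tabulated single-bond lengths jittered by σ = 0.03 Å, hydrogens completing
simple valences (C4 N3 O2 F1), any geometry with an interatomic distance
≤ 0.5 Å rejected. It does **not** emulate rings, multiple-bond geometry,
conformational realism, or quantum-mechanical labels.

The label is `intercept + slope · Σ_ij R_ij + ε`, ε ~ N(0, 0.05 eV), with
defaults (2.0 eV, 0.005 eV/Å) chosen so labels span roughly 2–10 eV like
HOMO–LUMO gaps. The summed-distance summary was chosen because it is (a)
invariant under every shuffle strategy, so augmented copies carry
consistent labels, and (b) proportional to the mean red-channel intensity
under black-margin, fixed-range encoding, so the learning-sanity tests have
a signal that is genuinely recoverable from the images. A passing learning
test therefore establishes that the encode→train→evaluate chain can recover
a structural signal — not that the method reaches any published accuracy on
real quantum-chemistry data, which would require the real dataset and
cluster-scale training.

## Numerical and degenerate-input conventions

- Exact symmetry everywhere: squared coordinate differences are computed so
  `(x_i−x_j)²` and `(x_j−x_i)²` are bit-identical.
- `normalize_matrix` divides before scaling by 255, so the observed maximum
  maps to exactly 255.0.
- A constant matrix normalizes to all-zeros (black plane), including the
  single-atom distance matrix.
- `N = S` makes every canvas mode the identity; `N > S` is an error except
  under resize.
- Fixed normalization with `hi ≤ lo`, unknown elements, malformed parameter
  files, and declared-vs-actual atom-count mismatches all fail fast with
  named errors; only missing bond-order pairs degrade (to 0, with warning).

## Known limitations

- Bond-order magnitudes are stand-in-parameterized (see above); analyses
  that depend on quantitative ReaxFF fidelity are out of scope.
- Published benchmark accuracies on the real 133 885-molecule dataset
  (hundreds of meV MAE with 10⁵–10⁶ training images) are not reproducible
  at desk scale and are not claimed; the package's stochastic acceptance
  check asserts direction-of-effect only (augmentation helps, the model
  beats a constant predictor).
- Non-square canvases, SMILES/SDF input, geometry optimization, periodic
  systems, and the full Monte-Carlo hyperparameter search with its
  statistical post-processing are out of scope.
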