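# rgbchem

Encode 3D molecular structures as three-channel images and train compact
convolutional neural networks to regress scalar molecular properties
(typically the HOMO–LUMO gap, in eV) from them.

## The idea

A molecule with `N` atoms yields symmetric `N × N` descriptor matrices that
need no quantum-chemical calculation beyond an available geometry:

- **interatomic distance** `R_ij = √((x_i−x_j)² + (y_i−y_j)² + (z_i−z_j)²)` (Å),
- **Coulomb matrix** `M_ij = Z_i Z_j / R_ij` for `i ≠ j`, with either
  `0.5 Z_i^2.4` on the diagonal ("full") or zeros ("reduced"),
- **uncorrected ReaxFF bond order**
  `BO′_ij = Σ_t exp[p_bo,odd (r_ij / r₀^t)^{p_bo,even}]` over the σ/π/ππ
  terms, parameterized per element pair,

plus two per-atom (diagonal) properties: first ionization energy and atomic
number. Each property is normalized onto `[0, 255]` and the matrices are
stacked into the red/green/blue planes of one of six fixed layouts (types
A–F; e.g. type A = distance + ionization | reduced Coulomb | bond order).
The `N × N` block is unified to a fixed `S × S` canvas (bilinear resize,
black fill, or channel-average fill, with a fixed or random offset), giving
an image a CNN can consume.

The encoding is permutation *equivariant*, not invariant: reordering the
atoms permutes image rows and columns. Rather than a flaw, this is used as
augmentation — shuffling the atom order ("groups" within each element,
"partial" within heavy-atoms/hydrogens, or "full") turns one molecule into
`k` distinct, equally valid training images, multiplying the training set
while every copy keeps the molecule's label.

Two compact regression heads are provided: **S1CNN** (one conv stage + three
dense layers, ≈0.2 M parameters at S=32) and **S2CNN** (two conv stages +
three dense layers, ≈0.1 M parameters), trained with Adam and early stopping
(Δ = 0, configurable patience), reporting MAE in eV. They are implemented on
plain numpy, so no deep-learning framework is required.

Because downloading QM9 is not required anywhere, a synthetic-molecule
generator provides QM9-shaped corpora (≤9 heavy atoms from C/N/O/F plus
hydrogens, plausible geometry, eV-scale labels affine in a structural
summary) for tests, examples and desk-scale experiments.

## Worked example

```bash
python examples/01_encode_molecule.py
```

prints, for methanol, the three descriptor matrices and the encoded image —
e.g. the bond-order matrix row for the carbon atom

```
[0.    1.164 0.925 0.925 0.925 0.013]
```

(≈1.2 to the bonded oxygen, ≈0.93 to its three hydrogens, ≈0 to the hydroxyl
hydrogen), and the red-channel diagonal `[211, 255, 255, 255, 255, 255]` —
the normalized ionization energies of C, O and the four hydrogens.

`examples/02_shuffle_augmentation.py` demonstrates the four shuffle
strategies and the n × k data-point accounting; `examples/03_train_s2cnn.py`
runs the full pipeline on 120 synthetic molecules (96 train × 4 images = 384
points) and finishes with a held-out MAE around 0.12 eV in under a minute:

```
 "architecture": "s2cnn",
 "n_params": 104497,
 "n_train_images": 384,
 "test_mae_ev": 0.118...
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it synthesizes a
300-molecule corpus, encodes type-A images with groups-shuffle augmentation
(4 images per training molecule), trains the default S2CNN, prints the run
report (counts, parameter count, train/val/test MAE in eV) and writes the
results JSON to `--out`. All randomness derives from `--seed`.

## Layout

```
src/rgbchem/
  xyz_io.py          xyz parsing (plain + QM9 dialect), PNG + manifest I/O
  chem_tables.py     element constants, bond-order pair parameters
  descriptors.py     distance / Coulomb / bond-order / diagonal matrices
  image_encoder.py   normalization, A–F channel layouts, canvas policies
  augmentation.py    shuffle strategies, k-images-per-molecule expansion
  nn.py, training.py numpy CNN layers, S1CNN/S2CNN, Adam + early stopping
  synthetic_mols.py  QM9-like synthetic corpus generator
  pipeline.py        one-config end-to-end runs and run summaries
```

See `docs/methods.md` for modelling assumptions, defaults and limitations.
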