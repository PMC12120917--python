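"""Desk-scale end-to-end run: synthesize, encode, train S2CNN, evaluate.

Builds a 120-molecule synthetic corpus (labels affine in a distance
summary, QM9-gap-like eV scale), encodes type-A images with 4
groups-shuffled images per training molecule, trains the ~0.1M-parameter
two-conv-stage CNN with Adam + early stopping, and reports MAE in eV on
held-out molecules.  Runs in well under a minute on one CPU.
"""

import json

from rgbchem import RunConfig, run
from rgbchem.augmentation import ShuffleSpec
from rgbchem.image_encoder import EncodingConfig
from rgbchem.synthetic_mols import SynthesisConfig
from rgbchem.training import ModelSpec, TrainConfig

cfg = RunConfig(
    synthesis=SynthesisConfig(n_molecules=120),
    encoding=EncodingConfig(
        gen_type="A", canvas_size=32, margin_mode="black",
        normalization="fixed",
        fixed_ranges={
            "distance": (0.0, 10.0), "coulomb_reduced": (0.0, 40.0),
            "bond_order": (0.0, 3.0), "ionization_diag": (0.0, 20.0),
        },
    ),
    shuffle=ShuffleSpec(kind="groups"),
    images_per_molecule=4,
    model=ModelSpec(architecture="s2cnn", input_size=32),
    train_cfg=TrainConfig(lr=3e-3, batch_size=64, patience=8, max_epochs=15),
    seed=7,
    out_dir="runs/example03",
)
report = run(cfg)
print(json.dumps(report, indent=1))
print(
    f"\n{report['n_train_molecules']} training molecules x "
    f"{report['images_per_molecule']} images = {report['n_train_images']} points; "
    f"held-out test MAE {report['test_mae_ev']:.3f} eV on labels spanning a few eV."
)
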