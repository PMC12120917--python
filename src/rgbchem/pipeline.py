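"""One reproducible run: corpus -> subset -> split -> images -> CNN -> MAE.

A :class:`RunConfig` captures every knob (database denominator N for the
1/N "QM9_N" subset, split fractions, encoding, shuffle strategy, images
per molecule k, model and optimizer settings) plus all seeds, and
``run()`` materializes a deterministic directory:

    out_dir/
      corpus/            synthetic xyz + labels.csv (when synthesized)
      splits.json        molecule ids per split
      train/ val/ test/  images/ + manifest.csv each
      history.json       per-epoch train/val MAE
      report.json        metrics + data-point accounting

Held-out validation/test molecules are encoded deterministically (shuffle
"none", one image each) by default so evaluation never depends on a
permutation draw; the training set gets the configured shuffle and k
images per molecule, so training points = training molecules x k.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augmentation import ShuffleSpec, generate_dataset, plan_augmentation, subset_database
from .chem_tables import load_element_table, load_pair_params
from .image_encoder import EncodingConfig
from .synthetic_mols import SynthesisConfig, generate_molecules
from .training import ModelSpec, TrainConfig, build_model, evaluate_mae, load_dataset, train
from .xyz_io import Molecule, read_labels_csv, read_xyz_file

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    corpus_path: str | None = None  # directory of .xyz + labels.csv; None -> synthesize
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    denominator: int = 1  # the N of a QM9_N-style 1/N subset
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    shuffle: ShuffleSpec = field(default_factory=ShuffleSpec)
    images_per_molecule: int = 1
    model: ModelSpec = field(default_factory=ModelSpec)
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    deterministic_eval: bool = True
    seed: int = 0
    out_dir: str = "runs/run0"

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        if self.images_per_molecule < 1:
            raise ValueError("images_per_molecule must be >= 1")
        if self.model.input_size != self.encoding.canvas_size:
            raise ValueError(
                f"model input_size {self.model.input_size} != canvas_size "
                f"{self.encoding.canvas_size}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Build a RunConfig from a YAML key tree mirroring the dataclasses."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("synthesis", SynthesisConfig),
            ("encoding", EncodingConfig),
            ("shuffle", ShuffleSpec),
            ("model", ModelSpec),
            ("train_cfg", TrainConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                for tup_key in ("heavy_atom_range", "split_fractions", "conv_channels", "fc_widths"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = klass(**sub)
        if "split_fractions" in kwargs:
            kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
        return cls(**kwargs)


def _load_corpus(path: str | Path) -> list[Molecule]:
    path = Path(path)
    labels = read_labels_csv(path / "labels.csv") if (path / "labels.csv").exists() else {}
    mols = []
    for xyz in sorted(path.glob("*.xyz")):
        mol = read_xyz_file(xyz)
        if mol.id in labels:
            mol = mol.with_label(labels[mol.id])
        mols.append(mol)
    if not mols:
        raise FileNotFoundError(f"no .xyz files under {path}")
    return mols


def split_molecules(
    mols: list[Molecule],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[list[Molecule], list[Molecule], list[Molecule]]:
    """Seeded random train/val/test partition by molecule (never by image)."""
    order = rng.permutation(len(mols))
    n_train = int(round(fractions[0] * len(mols)))
    n_val = int(round(fractions[1] * len(mols)))
    pick = lambda idx: [mols[i] for i in idx]
    return (
        pick(order[:n_train]),
        pick(order[n_train : n_train + n_val]),
        pick(order[n_train + n_val :]),
    )


def run(cfg: RunConfig) -> dict:
    """Execute one full pipeline run; returns (and writes) the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    elements = load_element_table()
    params = load_pair_params()

    stage = "corpus"
    try:
        if cfg.corpus_path is None:
            mols = generate_molecules(cfg.synthesis, rng)
        else:
            mols = _load_corpus(cfg.corpus_path)

        stage = "subset"
        mols = subset_database(mols, cfg.denominator, rng)

        stage = "split"
        train_mols, val_mols, test_mols = split_molecules(mols, cfg.split_fractions, rng)
        (out / "splits.json").write_text(
            json.dumps({
                "train": [m.id for m in train_mols],
                "val": [m.id for m in val_mols],
                "test": [m.id for m in test_mols],
            }, indent=1)
        )
        if not train_mols or not val_mols:
            raise ValueError("split produced an empty train or validation set")

        stage = "encode"
        plan = plan_augmentation(len(train_mols), cfg.images_per_molecule, cfg.shuffle.kind)
        train_manifest = generate_dataset(
            train_mols, cfg.encoding, cfg.shuffle, cfg.images_per_molecule,
            rng, out / "train", elements, params,
        )
        eval_shuffle = ShuffleSpec(kind="none") if cfg.deterministic_eval else cfg.shuffle
        eval_k = 1 if cfg.deterministic_eval else cfg.images_per_molecule
        val_manifest = generate_dataset(
            val_mols, cfg.encoding, eval_shuffle, eval_k, rng, out / "val", elements, params
        )
        test_manifest = (
            generate_dataset(
                test_mols, cfg.encoding, eval_shuffle, eval_k, rng, out / "test",
                elements, params,
            )
            if test_mols
            else None
        )
        assert len(train_manifest) == plan.total_points, "image-count accounting broke"

        stage = "train"
        model = build_model(cfg.model)
        history = train(model, train_manifest, val_manifest, cfg.train_cfg)
        (out / "history.json").write_text(json.dumps(history, indent=1))

        stage = "evaluate"
        report = {
            "config_fingerprint": cfg.encoding.fingerprint(),
            "seed": cfg.seed,
            "n_molecules": len(mols),
            "n_train_molecules": len(train_mols),
            "images_per_molecule": cfg.images_per_molecule,
            "n_train_images": len(train_manifest),
            "shuffle": cfg.shuffle.kind,
            "gen_type": cfg.encoding.gen_type,
            "architecture": cfg.model.architecture,
            "n_params": model.n_params,
            "epochs_run": history["epochs_run"],
            "best_epoch": history["best_epoch"],
            "train_mae_ev": evaluate_mae(model, train_manifest),
            "val_mae_ev": history["best_val_mae"],
            "test_mae_ev": evaluate_mae(model, test_manifest) if test_manifest else None,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("run complete: %s", report)
    return report


def summarize(run_dirs: list[str | Path], out_csv: str | Path | None = None) -> pd.DataFrame:
    """Collect report.json files into one comparison table sorted by MAE."""
    rows = []
    for d in run_dirs:
        report = Path(d) / "report.json"
        if not report.exists():
            warnings.warn(f"no report.json under {d}; skipping", stacklevel=2)
            continue
        rows.append({"run_dir": str(d), **json.loads(report.read_text())})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("val_mae_ev", kind="stable").reset_index(drop=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
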