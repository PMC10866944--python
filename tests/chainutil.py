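"""Helper to drive the full CLI pipeline at miniature scale from tests."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from click.testing import CliRunner

from gliomaseg.cli import main

#: phantom small enough that the whole chain runs in seconds
MINI_SPEC = {
    "image_shape": [48, 48, 16],
    "brain_axes": [20.0, 20.0, 6.0],
    "wt_radius": 5.0,
    "tc_radius": 3.2,
    "core_radius": 1.8,
    "noise_std": 0.05,
}

MINI_CONFIG = {
    "seed": 0,
    "data": {"n_cases": 4, "image_shape": [48, 48, 16], "jitter": 1.0},
    "preprocess": {"crop_size": [32, 32], "min_brain_fraction": 0.01},
    "model": {
        "base_filters": 4,
        "input_size": [32, 32],
        "transformer": {"num_blocks": 1, "num_heads": 2, "embed_dim": 16, "mlp_dim": 32, "patch_size": 1},
    },
    "train": {"epochs": 2, "folds": 2, "val_interval": 1, "batch_size": 16},
}


def write_mini_inputs(root: Path, seed: int = 0) -> tuple[Path, Path]:
    cfg = dict(MINI_CONFIG)
    cfg["seed"] = seed
    cfg_path = root / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    spec_path = root / "spec.json"
    spec_path.write_text(json.dumps(MINI_SPEC))
    return cfg_path, spec_path


def run_chain(root: Path, seed: int = 0) -> Path:
    """simulate -> preprocess -> train -> predict -> ensemble -> evaluate -> explain.

    Returns the path of the evaluation CSV.
    """
    root.mkdir(parents=True, exist_ok=True)
    cfg_path, spec_path = write_mini_inputs(root, seed)
    runner = CliRunner()

    def run(*args):
        res = runner.invoke(main, list(args), catch_exceptions=False)
        assert res.exit_code == 0, res.output
        return res

    data_dir = root / "cases"
    run("simulate", "--config", cfg_path, "--out-dir", data_dir, "--spec", spec_path)
    run("preprocess", "--config", cfg_path, "--data-dir", data_dir, "--out-dir", root / "prep")
    run("train", "--config", cfg_path, "--data-dir", data_dir, "--out-dir", root / "model")
    case = sorted(p for p in data_dir.iterdir() if p.is_dir())[0]
    preds = []
    for fold in (0, 1):
        out = root / f"pred_fold{fold}.nii.gz"
        run("predict", "--config", cfg_path, "--checkpoint", root / "model" / f"fold{fold}.npz",
            "--case", case, "--out", out)
        preds.append(out)
    fused = root / f"{case.name}_fused.nii.gz"
    run("ensemble", "--config", cfg_path, "--inputs", preds[0], "--inputs", preds[1], "--out", fused)
    eval_csv = root / "eval.csv"
    run("evaluate", "--config", cfg_path, "--pred", fused, "--truth-dir", data_dir, "--out", eval_csv)
    run("explain", "--config", cfg_path, "--checkpoint", root / "model" / "fold0.npz",
        "--case", case, "--layer", "OUT", "--target", "ET",
        "--out", root / "heatmap.nii.gz", "--ablation-csv", root / "ablation.csv")
    return eval_csv
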