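"""The packaged synthetic semi-supervision benchmark.

A fixed study design used by the test suite and the reproduction script:
200 training patches of histology-like blobs (2 classes), 20% labeled,
a held-out test set, and three training arms compared over several seeds:

* ``full``       — hierarchical + coarse--fine consistency with the MSC
                   fine head (the complete dual-consistency method);
* ``hc_only``    — uncertainty-rectified hierarchical consistency alone
                   (the pyramid-consistency arm, no MSC / no fine head);
* ``supervised`` — deeply supervised training on the labeled pool only.

Patches are 32x32 and batches hold 2 labeled + 8 unlabeled images (the
4:1 unlabeled:labeled ratio), sized so the whole comparison runs in
minutes on one CPU; see docs/methods.md for the design rationale.
"""

from __future__ import annotations

import numpy as np

from .losses import ScheduleConfig
from .network import NetworkConfig
from .synthetic import SyntheticPatchSpec, generate_patches, make_ssl_split
from .trainer import AblationFlags, TrainConfig, evaluate, fit

__all__ = ["ARMS", "benchmark_spec", "run_arm", "run_benchmark"]

ARMS = {
    "full": AblationFlags(use_hc=True, use_cfgc=True, use_msc=True),
    "hc_only": AblationFlags(use_hc=True, use_cfgc=False, use_msc=False),
    "supervised": AblationFlags(use_hc=False, use_cfgc=False, use_msc=False),
}

PATCH_SIZE = 32
N_TRAIN = 200
N_TEST = 40
LABELED_FRACTION = 0.2
BATCH_SIZE = 10
ITERATIONS = 300
BASE_WIDTH = 16


def benchmark_spec(seed: int) -> SyntheticPatchSpec:
    return SyntheticPatchSpec(height=PATCH_SIZE, width=PATCH_SIZE,
                              n_classes=2, blob_count_range=(1, 3),
                              blob_radius_range=(4, 8), seed=seed)


def _data(seed: int):
    spec = benchmark_spec(seed)
    train = generate_patches(spec, N_TRAIN, seed=seed)
    test = generate_patches(spec, N_TEST, seed=seed + 10_000)
    ds = make_ssl_split(train, LABELED_FRACTION, seed=seed)
    return ds, test


def run_arm(arm: str, seed: int, iterations: int = ITERATIONS) -> dict:
    """Train one arm for one seed; returns held-out macro metrics."""
    ds, test = _data(seed)
    flags = ARMS[arm]
    bpb = BATCH_SIZE - BATCH_SIZE // 5         # unlabeled per batch
    n_batches = int(np.ceil(ds.n_u / bpb))
    epochs = max(1, int(round(iterations / n_batches)))
    cfg = TrainConfig(
        epochs=epochs, batch_size=BATCH_SIZE, unlabeled_per_labeled=4,
        learning_rate=0.01, seed=seed,
        schedule=ScheduleConfig(k=0.1, beta=0.5),
        ablation=flags,
        network=NetworkConfig(n_classes=2, base_width=BASE_WIDTH,
                              head_levels=flags.head_levels,
                              use_msc=flags.use_msc))
    model, _ = fit(ds, cfg)
    return evaluate(model, test, n_classes=2)


def run_benchmark(seeds=(0, 1, 2, 3, 4), arms=("full", "hc_only", "supervised"),
                  iterations: int = ITERATIONS, verbose: bool = False) -> dict:
    """Mean held-out metrics per arm over the given seeds.

    Returns {arm: {"per_seed": [...], "mean_dsc": float, "mean_iou": float}}.
    """
    out = {}
    for arm in arms:
        per_seed = []
        for seed in seeds:
            scores = run_arm(arm, seed, iterations=iterations)
            per_seed.append(scores)
            if verbose:
                print(f"{arm} seed={seed}: dsc={scores['dsc']:.4f}")
        out[arm] = {
            "per_seed": per_seed,
            "mean_dsc": float(np.mean([s["dsc"] for s in per_seed])),
            "mean_iou": float(np.mean([s["iou"] for s in per_seed])),
        }
    return out
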