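"""Semi-supervised training loop.

Each optimization step draws a two-stream mini-batch — a labeled part and
an unlabeled part at a fixed ratio (default 4 unlabeled : 1 labeled) —
computes the deeply supervised loss on the labeled part and the two
consistency terms on the unlabeled part, and takes one SGD step with
momentum and weight decay.  The unsupervised weight follows the Gaussian
warm-up schedule over optimizer iterations (T = epochs x batches/epoch).

Ablation flags switch the arms of the method:

* ``use_hc=False, use_cfgc=False, use_msc=False`` — plain deeply
  supervised training on the labeled pool only (the supervised control);
* ``use_hc=True`` alone — uncertainty-rectified hierarchical consistency
  without the multi-scale fine head (the pyramid-consistency arm);
* all flags on — the full dual-consistency method.

Since the backbone has no batch statistics, running the labeled and
unlabeled parts as two forward passes is mathematically identical to one
concatenated batch.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import losses as L
from . import metrics as M
from .losses import LossBundle, ScheduleConfig
from .network import NetworkConfig, SegNet
from .synthetic import PatchDataset

__all__ = ["TrainConfig", "AblationFlags", "make_batches", "train_step",
           "fit", "evaluate"]


@dataclass
class AblationFlags:
    use_hc: bool = True
    use_cfgc: bool = True
    use_msc: bool = True
    head_levels: int = 4


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 20
    unlabeled_per_labeled: int = 4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    learning_rate: float = 0.01
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0
    ablation: AblationFlags = field(default_factory=AblationFlags)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    consistency_on_labeled: bool = False   # extend consistency to labeled part
    augment_flips: bool = False

    def __post_init__(self):
        if self.batch_size % (1 + self.unlabeled_per_labeled):
            raise ValueError(
                "batch_size must be divisible by 1 + unlabeled_per_labeled")
        if min(self.learning_rate, self.momentum, self.weight_decay) < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def labeled_per_batch(self) -> int:
        return self.batch_size // (1 + self.unlabeled_per_labeled)

    @property
    def unlabeled_per_batch(self) -> int:
        return self.batch_size - self.labeled_per_batch

    @property
    def semi_supervised(self) -> bool:
        return self.ablation.use_hc or self.ablation.use_cfgc

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = ScheduleConfig(**d["schedule"])
        if "ablation" in d and isinstance(d["ablation"], dict):
            d["ablation"] = AblationFlags(**d["ablation"])
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig(**d["network"])
        return cls(**d)


def _cycled_order(n: int, need: int, rng) -> np.ndarray:
    """A shuffled index stream of length >= need, reshuffling per cycle."""
    reps = []
    got = 0
    while got < need:
        reps.append(rng.permutation(n))
        got += n
    return np.concatenate(reps)[:need]


def make_batches(ds: PatchDataset, cfg: TrainConfig, epoch: int):
    """Yield (labeled_part, unlabeled_part) batches for one epoch.

    ``labeled_part`` is a list of (image, mask) pairs, ``unlabeled_part`` a
    list of images (empty for the supervised control).  Both pools are
    reshuffled each epoch from the run seed; the smaller pool cycles so
    that every batch is full.
    """
    if ds.n_l == 0:
        raise ValueError("labeled pool is empty")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.seed, 1000 + epoch)))
    n_lab = cfg.labeled_per_batch

    def maybe_flip(lab, unl):
        if not cfg.augment_flips:
            return lab, unl
        lab = [(im[:, ::-1].copy(), mk[:, ::-1].copy())
               if rng.random() < 0.5 else (im, mk) for im, mk in lab]
        unl = [im[:, ::-1].copy() if rng.random() < 0.5 else im
               for im in unl]
        return lab, unl

    if not cfg.semi_supervised or ds.n_u == 0:
        order = rng.permutation(ds.n_l)
        for b in range(int(np.ceil(ds.n_l / n_lab))):
            idx = order[b * n_lab:(b + 1) * n_lab]
            if len(idx) < n_lab:
                extra = _cycled_order(ds.n_l, n_lab - len(idx), rng)
                idx = np.concatenate([idx, extra])
            yield maybe_flip([ds.labeled_items[i] for i in idx], [])
        return
    n_unl = cfg.unlabeled_per_batch
    n_batches = int(np.ceil(ds.n_u / n_unl))
    lab_order = _cycled_order(ds.n_l, n_batches * n_lab, rng)
    unl_order = _cycled_order(ds.n_u, n_batches * n_unl, rng)
    for b in range(n_batches):
        lab = [ds.labeled_items[i]
               for i in lab_order[b * n_lab:(b + 1) * n_lab]]
        unl = [ds.unlabeled_items[i]
               for i in unl_order[b * n_unl:(b + 1) * n_unl]]
        yield maybe_flip(lab, unl)


def _to_nchw(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return arr.transpose(0, 3, 1, 2)


def train_step(batch, model: SegNet, optimizer, t: int, cfg: TrainConfig
               ) -> LossBundle:
    """One optimization step; returns the loss bundle for logging."""
    labeled, unlabeled = batch
    flags = cfg.ablation
    sched = cfg.schedule
    optimizer.zero_grad()

    images = _to_nchw([im for im, _ in labeled])
    masks = np.stack([mk for _, mk in labeled])
    preds, _ = model.forward(images, train_mode=True)
    alpha = list(sched.alpha) if sched.alpha is not None \
        else [1.0] * len(preds.maps)
    l_sup_t = L.supervised_loss(preds, masks, alpha=alpha)

    # With only one consistency arm enabled, that arm takes the full
    # unsupervised weight (beta collapses to 1 for HC-only, 0 for CFGC-only).
    beta = sched.beta
    if not flags.use_cfgc:
        beta = 1.0
    elif not flags.use_hc:
        beta = 0.0
    eff_sched = ScheduleConfig(k=sched.k, total_iters=sched.total_iters,
                               beta=beta, alpha=sched.alpha)

    l_hc = l_urc = l_cr = 0.0
    unsup_t = None
    if cfg.semi_supervised and (unlabeled or cfg.consistency_on_labeled):
        pool = list(unlabeled)
        if cfg.consistency_on_labeled:
            pool = [im for im, _ in labeled] + pool
        u_preds, _ = model.forward(_to_nchw(pool), train_mode=True)
        heads = u_preds.heads()
        if flags.use_hc and len(heads) >= 2:
            p_avg = L.average_prediction(heads)
            umap = L.uncertainty_map(heads, p_avg)
            l_urc_t = L.rectified_consistency(heads, p_avg, umap)
            l_hc = L.hierarchical_consistency(heads, p_avg).item()
            l_urc = l_urc_t.item()
            unsup_t = l_urc_t * beta
        if flags.use_cfgc and u_preds.p0 is not None:
            l_cr_t = L.cfgc_loss(u_preds.p0, u_preds.maps[1])
            l_cr = l_cr_t.item()
            term = l_cr_t * (1.0 - beta)
            unsup_t = term if unsup_t is None else unsup_t + term

    bundle = L.total_loss(l_sup_t.item(), l_urc, l_cr, t, eff_sched, hc=l_hc)
    total_t = l_sup_t if unsup_t is None else l_sup_t + unsup_t * bundle.lam
    if not np.isfinite(total_t.item()):
        raise FloatingPointError(
            f"non-finite loss at iteration {t}: sup={bundle.l_sup} "
            f"urc={bundle.l_urc} cr={bundle.l_cr}")
    total_t.backward()
    optimizer.step()
    return bundle


def evaluate(model: SegNet, items, n_classes: int) -> dict:
    """Mean macro metrics of the model over (image, mask) pairs."""
    sums = {m: 0.0 for m in ("iou", "dsc", "accuracy", "precision", "recall")}
    for img, mask in items:
        pred = model.predict(np.asarray(img, np.float32).transpose(2, 0, 1)[None])
        rep = M.macro_report(pred, mask, n_classes)
        for m in sums:
            sums[m] += rep[m]
    n = max(len(items), 1)
    return {m: v / n for m, v in sums.items()}


def fit(ds: PatchDataset, cfg: TrainConfig, eval_items=None,
        out_dir=None, resume_from=None, verbose: bool = False
        ) -> tuple[SegNet, list[dict]]:
    """Train a network on a labeled/unlabeled patch dataset.

    Returns the trained model and a history list with one row per
    iteration (loss terms, lambda) plus per-epoch evaluation rows when
    ``eval_items`` is given.  With ``out_dir`` set, history is written as
    CSV and a checkpoint is saved after every epoch; ``resume_from`` loads
    such a checkpoint and continues from its epoch counter.
    """
    from .nn import SGD

    net_cfg = cfg.network
    if cfg.ablation.head_levels != net_cfg.head_levels or \
            cfg.ablation.use_msc != net_cfg.use_msc:
        net_cfg = NetworkConfig(**{**asdict(net_cfg),
                                   "head_levels": cfg.ablation.head_levels,
                                   "use_msc": cfg.ablation.use_msc})
    start_epoch = 0
    if resume_from is not None:
        model = SegNet.load(resume_from)
        start_epoch = int(Path(resume_from).stem.split("_ep")[-1])
    else:
        model = SegNet(net_cfg, seed=cfg.seed)
    opt = SGD(model.params, lr=cfg.learning_rate, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)

    probe = list(make_batches(ds, cfg, epoch=0))
    bpe = len(probe)
    total_iters = cfg.epochs * bpe
    sched = ScheduleConfig(k=cfg.schedule.k, total_iters=total_iters,
                           beta=cfg.schedule.beta, alpha=cfg.schedule.alpha)
    run_cfg = TrainConfig(**{**asdict(cfg), "schedule": asdict(sched),
                             "ablation": asdict(cfg.ablation),
                             "network": asdict(net_cfg)})
    run_cfg = TrainConfig.from_dict(run_cfg.to_dict())

    history: list[dict] = []
    t = start_epoch * bpe
    for epoch in range(start_epoch, cfg.epochs):
        for batch in make_batches(ds, run_cfg, epoch):
            bundle = train_step(batch, model, opt, t, run_cfg)
            history.append({"iter": t, "epoch": epoch, **asdict(bundle)})
            t += 1
        if eval_items:
            scores = evaluate(model, eval_items, net_cfg.n_classes)
            history.append({"iter": t - 1, "epoch": epoch,
                            **{f"val_{m}": v for m, v in scores.items()}})
            if verbose:
                print(f"epoch {epoch}: val_dsc={scores['dsc']:.4f}")
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            model.save(out / f"checkpoint_seed{cfg.seed}_ep{epoch + 1}.npz")
            _write_history(out / "history.csv", history)
            (out / "config.json").write_text(json.dumps(
                {**run_cfg.to_dict(),
                 "n_parameters": model.n_parameters()}, indent=2))
    return model, history


def _write_history(path, history):
    cols = ["iter", "epoch", "l_sup", "l_hc", "l_urc", "l_cr", "l_unsup",
            "l_total", "lam", "val_iou", "val_dsc", "val_accuracy",
            "val_precision", "val_recall"]
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=cols)
        wr.writeheader()
        for row in history:
            wr.writerow({k: row.get(k, "") for k in cols})
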