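"""Diagnostic performance metrics and the cross-validation harness.

Detection performance uses the standard confusion-matrix quantities
with AD as the positive class:

    Se = TP/(TP+FN)   Sp = TN/(TN+FP)   pr = TP/(TP+FP)
    Acc = (TP+TN)/(TP+TN+FP+FN)

plus the detection-rate pair ADDR (correctly detected AD / total AD)
and NADDR (correctly detected non-AD / total non-AD). ADDR coincides
with Se and NADDR with Sp by definition; the identity is asserted on
every report as a consistency check. Metrics with a zero denominator
are reported as ``None`` (undefined), never as 0.

Cross-validation is stratified and seeded; augmentation happens inside
each fold's training only — test folds are never augmented (that
contract lives in the pipeline's fit/predict split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .fma import ClassifierConfig, ap_segment, fit_staging, stage_classify
from .imgio import GrayImage
from .pipeline import DetectionPipeline, PipelineConfig

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "detection_rates",
    "kfold_cv",
    "staging_cv",
    "CVReport",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Se/Sp/pr/Acc + ADDR/NADDR on the [0, 1] scale (None = undefined)."""

    se: float | None
    sp: float | None
    pr: float | None
    acc: float | None
    addr: float | None
    naddr: float | None

    def as_percent(self) -> dict[str, float | None]:
        """Percentages rounded to 2 decimals, table style."""
        return {
            k: (None if v is None else round(100.0 * v, 2))
            for k, v in vars(self).items()
        }


def confusion(truth, pred, positive: str = "AD") -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``positive`` as the positive class."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    t_pos = truth == positive
    p_pos = pred == positive
    return ConfusionCounts(
        TP=int(np.sum(t_pos & p_pos)),
        TN=int(np.sum(~t_pos & ~p_pos)),
        FP=int(np.sum(~t_pos & p_pos)),
        FN=int(np.sum(t_pos & ~p_pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Se/Sp/pr/Acc from counts; undefined metrics come back as None."""
    se = _ratio(cc.TP, cc.TP + cc.FN)
    sp = _ratio(cc.TN, cc.TN + cc.FP)
    return MetricsReport(
        se=se,
        sp=sp,
        pr=_ratio(cc.TP, cc.TP + cc.FP),
        acc=_ratio(cc.TP + cc.TN, cc.total),
        addr=se,
        naddr=sp,
    )


def detection_rates(truth, pred, positive: str = "AD"):
    """(ADDR, NADDR): per-class correct-detection rates.

    ADDR == Se and NADDR == Sp by definition; the cross-check against
    :func:`metrics` runs on every call.
    """
    cc = confusion(truth, pred, positive=positive)
    addr = _ratio(cc.TP, cc.TP + cc.FN)
    naddr = _ratio(cc.TN, cc.TN + cc.FP)
    rep = metrics(cc)
    assert addr == rep.se and naddr == rep.sp, "ADDR/Se identity violated"
    return addr, naddr


@dataclass(frozen=True)
class CVReport:
    """Per-fold reports plus the across-fold mean of defined metrics."""

    folds: tuple[MetricsReport, ...]
    mean: MetricsReport
    fold_sizes: tuple[int, ...]


def _mean_report(folds: list[MetricsReport]) -> MetricsReport:
    def avg(name):
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        return None if not vals else float(np.mean(vals))

    return MetricsReport(**{k: avg(k) for k in
                            ("se", "sp", "pr", "acc", "addr", "naddr")})


def kfold_cv(
    images: list[GrayImage],
    labels,
    cfg: PipelineConfig,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV of the AD/NAD detection pipeline.

    The deterministic imaging front end (resize + Gabor fusion) is
    computed once and shared across folds; training (with augmentation)
    and testing (without) run per fold with fold-derived seeds.
    """
    labels = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError("k exceeds the smallest class size")

    front = DetectionPipeline(cfg)
    pre = front.preprocess_many(images)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)

    folds, sizes = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_cfg = PipelineConfig(
            working_size=cfg.working_size, gabor=cfg.gabor,
            classifier=cfg.classifier, seed=int(fold_seeds[fold]),
        )
        pipe = DetectionPipeline(fold_cfg)
        pipe.fit([pre[i] for i in tr], labels[tr], preprocessed=True)
        pred = pipe.predict([pre[i] for i in te], preprocessed=True)
        folds.append(metrics(confusion(labels[te], pred)))
        sizes.append(len(te))
    return CVReport(folds=tuple(folds), mean=_mean_report(folds),
                    fold_sizes=tuple(sizes))


def staging_cv(
    images: list[GrayImage],
    stage_labels,
    cfg: ClassifierConfig,
    k: int = 5,
    seed: int = 0,
    working_size: int | None = None,
) -> tuple[list[float], float]:
    """Stratified k-fold CV of mild/advanced staging on detected-AD images.

    Images are resized to the classifier's input size, AP masks come
    from the morphological-gradient segmenter (auto threshold), and each
    fold trains a fresh staging stack. Returns per-fold accuracies and
    their mean.
    """
    from skimage.transform import resize as _sk_resize

    stage_labels = np.asarray(stage_labels, dtype=object)
    size = working_size or cfg.recnn.input_size
    resized = []
    for im in images:
        px = im.pixels
        if px.shape != (size, size):
            px = np.clip(_sk_resize(px, (size, size), order=1,
                                    anti_aliasing=True, preserve_range=True),
                         0.0, 1.0)
        resized.append(GrayImage(px, spacing_mm=im.spacing_mm))
    masks = [ap_segment(im) for im in resized]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)

    accs = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(stage_labels)),
                                              stage_labels)):
        mild = [i for i in tr if stage_labels[i] == "mild"]
        adv = [i for i in tr if stage_labels[i] == "advanced"]
        model = fit_staging(
            [resized[i] for i in mild], [resized[i] for i in adv],
            [masks[i] for i in mild], [masks[i] for i in adv],
            cfg=cfg, seed=int(fold_seeds[fold]),
        )
        pred = [stage_classify(model, resized[i], masks[i]) for i in te]
        accs.append(float(np.mean([p == stage_labels[i]
                                   for p, i in zip(pred, te)])))
    return accs, float(np.mean(accs))
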