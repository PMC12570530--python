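"""End-to-end detection pipeline: preprocess -> Gabor -> features -> FCM.

Two layers of orchestration live here:

:class:`FeatureClassifier`
    The learner shared by detection and staging: optional shift
    augmentation, CNN feature extraction trained through a temporary
    softmax head, per-feature z-scoring on training statistics, an FCM
    fit on the standardized features and a majority-vote cluster ->
    class map. Augmentation is applied during ``fit`` only, never in
    ``predict``.

:class:`DetectionPipeline`
    Adds the imaging front end (resize to the working resolution and
    Gabor-bank max-fusion) and classifies images as AD vs NAD.

Feature z-scoring is a deliberate design choice: the FCM head uses
Euclidean distances, and raw global-average-pooled channel responses
differ in scale by orders of magnitude across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import fcm as _fcm
from .augment import augment_set
from .fgt import GaborBank, GaborParams, apply_fgt, build_bank
from .imgio import GrayImage
from .recnn import (
    RECNNConfig,
    TrainedExtractor,
    build_recnn,
    forward_features_batch,
    train_extractor,
)

__all__ = [
    "ClassifierConfig",
    "FeatureClassifier",
    "PipelineConfig",
    "DetectionPipeline",
    "desk_scale_config",
    "config_from_yaml",
    "save_pipeline",
    "load_pipeline",
]


@dataclass(frozen=True)
class ClassifierConfig:
    recnn: RECNNConfig = field(default_factory=RECNNConfig)
    epochs: int = 5
    lr: float = 3e-3
    batch_size: int = 16
    # More clusters than classes: AD is morphologically heterogeneous
    # (mild vs advanced), so clusters sub-divide it and the majority-vote
    # map absorbs the extras into the two class labels.
    fcm_k: int = 4
    m_exp: float = 2.0
    fcm_max_iter: int = 100
    fcm_tol: float = 1e-5
    augment_offset_px: int | None = None  # None disables augmentation


class FeatureClassifier:
    """CNN feature extractor + z-scoring + FCM soft-cluster classifier."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        self.extractor: TrainedExtractor | None = None
        self.cluster: _fcm.ClusterModel | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.cluster is not None

    def _standardize(self, F: np.ndarray) -> np.ndarray:
        return (F - self._mu) / self._sd

    def fit(self, imgs: list[GrayImage], labels) -> "FeatureClassifier":
        labels = np.asarray(labels, dtype=object)
        if len(imgs) != len(labels):
            raise ValueError("one label per image required")
        if self.cfg.augment_offset_px is not None:
            imgs = augment_set(list(imgs), self.cfg.augment_offset_px)
            labels = np.repeat(labels, 5)
        cfg_r = replace(self.cfg.recnn, seed=self.seed)
        model = build_recnn(cfg_r)
        model = train_extractor(
            model, imgs, labels,
            epochs=self.cfg.epochs, lr=self.cfg.lr,
            seed=self.seed, batch_size=self.cfg.batch_size,
        )
        F = forward_features_batch(model, imgs)
        self._mu = F.mean(axis=0)
        sd = F.std(axis=0)
        sd[sd < 1e-12] = 1.0
        self._sd = sd
        Z = (F - self._mu) / self._sd
        cluster, M = _fcm.fcm_fit(
            Z, k=self.cfg.fcm_k, m_exp=self.cfg.m_exp,
            max_iter=self.cfg.fcm_max_iter, tol=self.cfg.fcm_tol,
            seed=self.seed + 1,
        )
        cluster.cluster_to_class = _fcm.map_clusters_to_classes(M, labels)
        self.extractor = model
        self.cluster = cluster
        return self

    def memberships(self, imgs: list[GrayImage]) -> np.ndarray:
        if not self.fitted:
            raise ValueError("classifier is not fitted")
        F = forward_features_batch(self.extractor, imgs)
        return _fcm.membership_rows(self.cluster, self._standardize(F))

    def predict(self, imgs: list[GrayImage]) -> list[str]:
        M = self.memberships(imgs)
        c2c = self.cluster.cluster_to_class
        return [c2c[int(j)] for j in M.argmax(axis=1)]

    def predict_one(self, img: GrayImage) -> tuple[np.ndarray, str]:
        M = self.memberships([img])
        j = int(M[0].argmax())
        return M[0], self.cluster.cluster_to_class[j]


@dataclass(frozen=True)
class PipelineConfig:
    """Working resolution, Gabor bank and classifier settings."""

    working_size: int = 256
    gabor: GaborParams = field(default_factory=GaborParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier.recnn.input_size != self.working_size:
            raise ValueError("classifier.recnn.input_size must equal working_size")

    @property
    def default_offset_px(self) -> int:
        # 8 px at the 256 reference resolution, scaled proportionally
        return max(1, round(8 * self.working_size / 256))


def desk_scale_config(seed: int = 0, working_size: int = 32,
                      epochs: int = 5) -> PipelineConfig:
    """Desk-scale configuration: 32-px working resolution, a 48-kernel
    Gabor bank (15-degree orientation step over all four frequency
    factors) and filter counts scaled by 1/64 (8 / 16 / 8)."""
    recnn = RECNNConfig(scale=1 / 64, input_size=working_size, seed=seed)
    clf = ClassifierConfig(
        recnn=recnn, epochs=epochs,
        augment_offset_px=max(1, round(8 * working_size / 256)),
    )
    gabor = GaborParams(theta_step=15.0, support_radius=5)
    return PipelineConfig(working_size=working_size, gabor=gabor,
                          classifier=clf, seed=seed)


def config_from_yaml(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized top-level keys: ``working_size``, ``seed``, and nested
    ``gabor``, ``recnn``, ``classifier`` sections whose entries map
    directly onto the corresponding config dataclasses. Omitted keys
    keep their defaults; ``recnn.input_size`` defaults to the working
    size.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    working_size = int(data.get("working_size", 256))
    gabor_kw = dict(data.get("gabor", {}))
    if "freqs" in gabor_kw:
        gabor_kw["freqs"] = tuple(float(f) for f in gabor_kw["freqs"])
    recnn_kw = dict(data.get("recnn", {}))
    recnn_kw.setdefault("input_size", working_size)
    clf_kw = dict(data.get("classifier", {}))
    return PipelineConfig(
        working_size=working_size,
        gabor=GaborParams(**gabor_kw),
        classifier=ClassifierConfig(recnn=RECNNConfig(**recnn_kw), **clf_kw),
        seed=int(data.get("seed", 0)),
    )


class DetectionPipeline:
    """Resize -> Gabor max-fusion -> FeatureClassifier, AD vs NAD."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.bank: GaborBank = build_bank(cfg.gabor)
        clf_cfg = cfg.classifier
        if clf_cfg.augment_offset_px is None:
            clf_cfg = replace(clf_cfg, augment_offset_px=cfg.default_offset_px)
        self.classifier = FeatureClassifier(clf_cfg, seed=cfg.seed)

    # -- preprocessing ----------------------------------------------------
    def preprocess(self, img: GrayImage) -> GrayImage:
        from skimage.transform import resize as _sk_resize

        px = img.pixels
        size = self.cfg.working_size
        if px.shape != (size, size):
            px = np.clip(
                _sk_resize(px, (size, size), order=1, anti_aliasing=True,
                           preserve_range=True),
                0.0, 1.0,
            )
            img = GrayImage(px, spacing_mm=img.spacing_mm)
        return apply_fgt(img, self.bank)

    def preprocess_many(self, imgs: list[GrayImage]) -> list[GrayImage]:
        return [self.preprocess(im) for im in imgs]

    # -- learning ---------------------------------------------------------
    def fit(self, imgs: list[GrayImage], labels,
            preprocessed: bool = False) -> "DetectionPipeline":
        if not preprocessed:
            imgs = self.preprocess_many(imgs)
        self.classifier.fit(imgs, labels)
        return self

    def predict(self, imgs: list[GrayImage],
                preprocessed: bool = False) -> list[str]:
        if not preprocessed:
            imgs = self.preprocess_many(imgs)
        return self.classifier.predict(imgs)


# ------------------------------------------------------------ persistence


def _classifier_payload(clf: FeatureClassifier) -> dict:
    import json

    if not clf.fitted:
        raise ValueError("cannot persist an unfitted classifier")
    payload = {f"w_{k}": v for k, v in clf.extractor.weights.items()}
    payload["mu"] = clf._mu
    payload["sd"] = clf._sd
    payload["centers"] = clf.cluster.centers
    cfg = clf.cfg
    meta = {
        "classifier": {
            "epochs": cfg.epochs, "lr": cfg.lr, "batch_size": cfg.batch_size,
            "fcm_k": cfg.fcm_k, "m_exp": cfg.m_exp,
            "fcm_max_iter": cfg.fcm_max_iter, "fcm_tol": cfg.fcm_tol,
            "augment_offset_px": cfg.augment_offset_px,
        },
        "recnn": vars(cfg.recnn),
        "seed": clf.seed,
        "cluster_to_class": {str(k): v for k, v in
                             clf.cluster.cluster_to_class.items()},
    }
    payload["__meta__"] = np.array(json.dumps(meta))
    return payload


def _classifier_from_payload(data) -> FeatureClassifier:
    import json

    from . import fcm as fcm_mod

    meta = json.loads(str(data["__meta__"][()]))
    recnn_kw = meta["recnn"]
    for key in ("conv1_filters", "conv1_kernel", "conv2_filters",
                "conv2_kernel", "conv3_filters", "conv3_kernel",
                "pool_kernel", "input_size", "seed"):
        recnn_kw[key] = int(recnn_kw[key])
    clf_kw = meta["classifier"]
    if clf_kw["augment_offset_px"] is not None:
        clf_kw["augment_offset_px"] = int(clf_kw["augment_offset_px"])
    cfg = ClassifierConfig(recnn=RECNNConfig(**recnn_kw),
                           epochs=int(clf_kw["epochs"]), lr=clf_kw["lr"],
                           batch_size=int(clf_kw["batch_size"]),
                           fcm_k=int(clf_kw["fcm_k"]), m_exp=clf_kw["m_exp"],
                           fcm_max_iter=int(clf_kw["fcm_max_iter"]),
                           fcm_tol=clf_kw["fcm_tol"],
                           augment_offset_px=clf_kw["augment_offset_px"])
    clf = FeatureClassifier(cfg, seed=int(meta["seed"]))
    weights = {k[2:]: data[k] for k in data.files if k.startswith("w_")}
    clf.extractor = TrainedExtractor(cfg=cfg.recnn, weights=weights)
    clf._mu = data["mu"]
    clf._sd = data["sd"]
    clf.cluster = fcm_mod.ClusterModel(
        centers=data["centers"], m_exp=cfg.m_exp,
        max_iter=cfg.fcm_max_iter, tol=cfg.fcm_tol,
        cluster_to_class={int(k): v for k, v in
                          meta["cluster_to_class"].items()},
    )
    return clf


def save_pipeline(pipe: DetectionPipeline, path) -> None:
    """Persist a fitted detection pipeline to a single .npz checkpoint."""
    import json

    payload = _classifier_payload(pipe.classifier)
    gcfg = vars(pipe.cfg.gabor)
    payload["__pipeline__"] = np.array(json.dumps(
        {"working_size": pipe.cfg.working_size, "seed": pipe.cfg.seed,
         "gabor": gcfg}, default=float))
    np.savez(path, **payload)


def load_pipeline(path) -> DetectionPipeline:
    import json

    with np.load(path, allow_pickle=False) as data:
        info = json.loads(str(data["__pipeline__"][()]))
        clf = _classifier_from_payload(data)
    gkw = info["gabor"]
    gkw["freqs"] = tuple(float(f) for f in gkw["freqs"])
    gkw["support_radius"] = int(gkw["support_radius"])
    cfg = PipelineConfig(working_size=int(info["working_size"]),
                         gabor=GaborParams(**gkw), classifier=clf.cfg,
                         seed=int(info["seed"]))
    pipe = DetectionPipeline(cfg)
    pipe.classifier = clf
    return pipe
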