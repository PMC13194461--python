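"""scikit-learn style estimators wrapping the segmentation pipelines.

``PointCloudSegmenter`` is a fit/predict classifier over labeled scenes
(semantic segmentation); ``PlantClusterer`` is a clusterer assigning plant
instance ids to the points of one scene.  Both expose ``get_params`` /
``set_params`` and fitted attributes with trailing underscores, so they
compose with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cloud import LabeledPointCloud
from .instances import DBSCANParams, segment_instances
from .network import ModelConfig
from .train import TrainConfig, evaluate, train


def _as_cloud(x) -> LabeledPointCloud:
    if isinstance(x, LabeledPointCloud):
        return x
    return LabeledPointCloud.from_array(np.asarray(x))


class PointCloudSegmenter(BaseEstimator):
    """Semantic segmentation of seedling scenes (tray / stem / leaf).

    Parameters mirror the architecture toggles (multi-scale residual
    blocks, channel attention, global context, improved feature
    propagation) and the training protocol.  ``fit`` consumes a list of
    labeled scenes; ``predict`` returns one label vector per scene.

    Examples
    --------
    >>> seg = PointCloudSegmenter(epochs=5, batch_size=4)
    >>> seg.fit(train_scenes, val_scenes=val_scenes)   # doctest: +SKIP
    >>> labels = seg.predict(test_scenes)              # doctest: +SKIP
    """

    def __init__(
        self,
        use_ms: bool = True,
        use_se: bool = True,
        use_gc: bool = True,
        use_improved_fp: bool = True,
        compact: bool = True,
        epochs: int = 30,
        batch_size: int = 16,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        lr_step: int = 10,
        lr_factor: float = 0.5,
        n_points: int = 2049,
        seed: int = 0,
    ):
        self.use_ms = use_ms
        self.use_se = use_se
        self.use_gc = use_gc
        self.use_improved_fp = use_improved_fp
        self.compact = compact
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.lr_step = lr_step
        self.lr_factor = lr_factor
        self.n_points = n_points
        self.seed = seed

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        base = ModelConfig.compact if self.compact else ModelConfig
        return base(
            use_ms=self.use_ms,
            use_se=self.use_se,
            use_gc=self.use_gc,
            use_improved_fp=self.use_improved_fp,
            seed=self.seed,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            weight_decay=self.weight_decay,
            lr_step=self.lr_step,
            lr_factor=self.lr_factor,
            n_points=self.n_points,
            seed=self.seed,
        )

    def fit(self, X, y=None, val_scenes=None):
        """Train on labeled scenes (labels live inside the clouds).

        Without explicit ``val_scenes`` the last max(1, 10 %) of ``X`` is
        held out for validation-based model selection.
        """
        scenes = [_as_cloud(x) for x in X]
        if len(scenes) < 2 and val_scenes is None:
            raise ValueError("need at least 2 scenes (train + validation)")
        if val_scenes is None:
            n_val = max(1, len(scenes) // 10)
            train_scenes, val = scenes[:-n_val], scenes[-n_val:]
        else:
            train_scenes, val = scenes, [_as_cloud(x) for x in val_scenes]
        self.model_, self.history_ = train(
            self._model_config(), self._train_config(), train_scenes, val
        )
        self.classes_ = np.arange(self.model_.config.n_classes)
        self.n_parameters_ = self.model_.n_parameters
        return self

    def predict(self, X):
        """Per-point labels for each scene (full resolution)."""
        self._check_fitted()
        out = []
        for x in X:
            cloud = _as_cloud(x)
            out.append(
                self.model_.predict_scene(cloud.coords, cloud.normals,
                                          cloud.colors)
            )
        return out

    def score(self, X, y=None) -> float:
        """Micro-averaged overall point accuracy on resampled scenes."""
        self._check_fitted()
        report = self.evaluate(X)
        return report.overall_accuracy

    def evaluate(self, X):
        """Full metrics report (micro-averaged over the split)."""
        self._check_fitted()
        return evaluate(self.model_, [_as_cloud(x) for x in X],
                        n_points=self.n_points, batch_size=self.batch_size,
                        seed=self.seed)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")


class PlantClusterer(BaseEstimator, ClusterMixin):
    """Instance segmentation by per-class DBSCAN and stem-leaf assembly."""

    def __init__(
        self,
        alpha_stem: float = 0.8,
        alpha_leaf: float = 1.2,
        min_samples: int = 5,
        attach_radius: float = 2.0,
        attach_noise: bool = False,
    ):
        self.alpha_stem = alpha_stem
        self.alpha_leaf = alpha_leaf
        self.min_samples = min_samples
        self.attach_radius = attach_radius
        self.attach_noise = attach_noise

    def _params(self) -> DBSCANParams:
        return DBSCANParams(
            alpha_stem=self.alpha_stem,
            alpha_leaf=self.alpha_leaf,
            min_samples=self.min_samples,
            attach_radius=self.attach_radius,
            attach_noise=self.attach_noise,
        )

    def fit(self, X, y=None):
        """Cluster one scene; ``X`` is a cloud or an (N, 11) array.

        ``y`` optionally overrides the semantic labels (e.g. network
        predictions).
        """
        cloud = _as_cloud(X)
        instances, labels, orphans = segment_instances(
            cloud, self._params(), sem_labels=y
        )
        self.instances_ = instances
        self.labels_ = labels
        self.orphans_ = orphans
        self.n_instances_ = len(instances)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
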