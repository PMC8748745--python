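"""High-level model/results interface over the two-stage pipeline.

``VolumeSegmenter`` bundles training data and configuration the way a
statistical modelling package bundles endog/exog and options: construct it
from (intensity, label) volume pairs, call :meth:`fit`, and receive a
:class:`SegmenterResults` carrying the trained parameters, the training
log, and the downstream operations (semantic prediction, instance
segmentation, evaluation, summary table).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import metrics as M
from .network import (NetworkConfig, SegNet3D, TrainConfig, TrainingLog,
                      predict_semantic_volume, semantic_argmax,
                      train_semantic_model)
from .touch_cluster import InstanceSegmentation, segment_instances
from .volume_io import IntensityVolume, LabelVolume

__all__ = ["VolumeSegmenter", "SegmenterResults"]


class VolumeSegmenter:
    """Two-stage cell segmenter: semantic network + touching-area clustering.

    Parameters
    ----------
    dataset
        Training pairs of intensity and instance-label volumes.
    train_config, network_config
        Optimization and architecture settings (sensible defaults).
    """

    def __init__(
        self,
        dataset: Sequence[tuple[IntensityVolume, LabelVolume]],
        train_config: TrainConfig | None = None,
        network_config: NetworkConfig | None = None,
    ):
        self.dataset = list(dataset)
        self.train_config = train_config or TrainConfig()
        self.network_config = network_config or NetworkConfig()

    def fit(self, init: SegNet3D | None = None) -> "SegmenterResults":
        """Train the semantic network; ``init`` warm-starts (fine-tuning)."""
        net, log = train_semantic_model(
            self.dataset, self.train_config, self.network_config, init=init
        )
        return SegmenterResults(model=self, net=net, log=log)


@dataclasses.dataclass
class SegmenterResults:
    """Fitted pipeline: trained network plus the stage-2 clustering."""

    model: VolumeSegmenter
    net: SegNet3D
    log: TrainingLog

    def predict(self, image: IntensityVolume | np.ndarray):
        """Per-voxel class probabilities for a new volume."""
        return predict_semantic_volume(image, self.net)

    def segment(
        self, image: IntensityVolume | np.ndarray, min_area: int = 30
    ) -> InstanceSegmentation:
        """Full two-stage instance segmentation of a new volume.

        ``min_area`` is the single user-facing hyperparameter; changing it
        re-runs only the clustering stage logic, never the network.
        """
        probs = self.predict(image)
        masks = semantic_argmax(probs)
        return segment_instances(masks, min_area=min_area)

    def evaluate(self, pred: LabelVolume, gt: LabelVolume) -> M.EvaluationReport:
        return M.evaluate(pred, gt)

    def summary(self) -> str:
        """Plain-text fit summary: architecture, loss trajectory."""
        totals = self.log.totals()
        lines = [
            "Two-stage 3D cell segmentation — fit summary",
            "=" * 46,
            f"network parameters : {self.net.n_parameters:,}",
            f"encoder levels     : {self.net.cfg.n_levels} "
            f"(base {self.net.cfg.base_channels} channels)",
            f"training steps     : {len(totals)}",
        ]
        if len(totals):
            k = min(20, max(1, len(totals) // 5))
            lines += [
                f"loss (first {k} steps) : {totals[:k].mean():.4f}",
                f"loss (last {k} steps)  : {totals[-k:].mean():.4f}",
                f"final loss         : {totals[-1]:.4f}",
            ]
        lines.append(f"alpha = {self.model.train_config.alpha}, "
                     f"w_min = {self.model.train_config.w_min}")
        return "\n".join(lines)
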