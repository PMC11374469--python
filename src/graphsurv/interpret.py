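"""Interpretability: survival activation maps, attention heatmaps, Dice.

SAM adapts the GradCAM recipe to the graph setting: differentiate the
pre-sigmoid logit of the earliest (highest-risk) survival bin with respect
to the node-feature map A (N x D) produced by the last GraphMixer layer,
average the gradient over nodes to get one importance weight per channel,

    alpha_j = (1/N) sum_i d logit / d A_ij,

and score each node by the magnitude of the channel-weighted activation,
|sum_j alpha_j A_ij|. Magnitude rather than a ReLU is used because both
positive and negative evidence of early-bin risk are of interest. For the
fusion model the gradient is still taken at the node level (upstream of the
genomic attention), so SAM stays per-patch.

TAH re-exposes the gated pooling weights (node-pooled models only); CoAttn
re-exposes the M genomic attention rows of the fusion model. Maps are
compared against boolean annotation masks by the Dice coefficient after
per-slide min-max rescaling and thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GraphsurvError
from .graphs import ImagingGraph
from .model import SurvivalModel

__all__ = ["SaliencyMap", "AnnotationMask", "sam", "tah", "coattn",
           "dice", "dice_curve", "render_heatmap"]


@dataclass
class SaliencyMap:
    """Per-node scalar importance aligned to patch coordinates."""

    per_node_score: np.ndarray
    coords: np.ndarray
    method: str
    signature_index: int | None = None

    def __post_init__(self):
        self.per_node_score = np.asarray(self.per_node_score, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if not np.isfinite(self.per_node_score).all():
            raise ConfigurationError("saliency scores must be finite")
        if len(self.per_node_score) != len(self.coords):
            raise ConfigurationError("score / coords length mismatch")

    @property
    def rescaled(self) -> np.ndarray:
        """Min-max rescaling to [0, 1] (constant maps map to zeros)."""
        s = self.per_node_score
        span = s.max() - s.min()
        if span == 0:
            return np.zeros_like(s)
        return (s - s.min()) / span


@dataclass
class AnnotationMask:
    per_node_label: np.ndarray
    label_name: str = ""

    def __post_init__(self):
        self.per_node_label = np.asarray(self.per_node_label, dtype=bool)


def sam(model: SurvivalModel, graph: ImagingGraph, signatures=None,
        target_bin: int = 0) -> SaliencyMap:
    """Survival activation map for ``target_bin`` (default: earliest bin)."""
    if not 0 <= target_bin < model.config.n_bins:
        raise ConfigurationError(
            f"target_bin {target_bin} outside [0, {model.config.n_bins})")
    was_training = model.training
    model.eval()  # dropout off: the map must be deterministic
    try:
        logits, internals = model.forward(graph, signatures)
    finally:
        model.train(was_training)
    feature_map = internals["last_mixer"]
    logits[target_bin:target_bin + 1].sum().backward()
    grads = feature_map.grad
    if grads is None:
        grads = np.zeros_like(feature_map.data)
    alpha = grads.mean(axis=0)                      # (D,) channel weights
    scores = np.abs(feature_map.data @ alpha)       # (N,) magnitude
    return SaliencyMap(scores, graph.coords, "SAM")


def sam_channel_weights(model: SurvivalModel, graph: ImagingGraph,
                        signatures=None, target_bin: int = 0) -> np.ndarray:
    """The channel importance weights alpha_j alone (for validation)."""
    was_training = model.training
    model.eval()
    try:
        logits, internals = model.forward(graph, signatures)
    finally:
        model.train(was_training)
    feature_map = internals["last_mixer"]
    logits[target_bin:target_bin + 1].sum().backward()
    grads = feature_map.grad
    if grads is None:
        grads = np.zeros_like(feature_map.data)
    return grads.mean(axis=0)


def tah(model: SurvivalModel, graph: ImagingGraph, signatures=None
        ) -> SaliencyMap:
    """Attention-pooling-weight heatmap (node-pooled, i.e. imaging models)."""
    if model.config.is_fusion:
        raise GraphsurvError(
            "TAH is undefined for fusion models: pooling runs over signature "
            "tokens, not nodes")
    logits, internals = model.forward(graph, signatures)
    weights = internals["pool_weights"].data.copy()
    return SaliencyMap(weights, graph.coords, "TAH")


def coattn(model: SurvivalModel, graph: ImagingGraph, signatures
           ) -> list[SaliencyMap]:
    """Per-signature co-attention maps (fusion models only)."""
    if not model.config.is_fusion:
        raise GraphsurvError("CoAttn requires a fusion model")
    logits, internals = model.forward(graph, signatures)
    attn = internals["gam_attn"].data
    return [SaliencyMap(attn[m].copy(), graph.coords, "CoAttn",
                        signature_index=m)
            for m in range(attn.shape[0])]


def dice(saliency: SaliencyMap, mask: AnnotationMask, threshold: float
         ) -> float:
    """Dice overlap of the thresholded (rescaled) map with the mask."""
    labels = mask.per_node_label
    if len(labels) != len(saliency.per_node_score):
        raise ConfigurationError("map and mask lengths differ")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError("threshold must lie in [0, 1]")
    pred = saliency.rescaled >= threshold
    p, g = pred.sum(), labels.sum()
    if p == 0 and g == 0:
        return 1.0
    inter = np.logical_and(pred, labels).sum()
    return float(2.0 * inter / (p + g))


def dice_curve(saliency: SaliencyMap, mask: AnnotationMask, thresholds
               ) -> list[tuple[float, float]]:
    return [(float(t), dice(saliency, mask, float(t))) for t in thresholds]


def render_heatmap(saliency: SaliencyMap, graph: ImagingGraph, output_path,
                   colormap: str = "jet") -> None:
    """PNG heatmap (one cell per patch) + CSV of raw scores alongside."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = saliency.coords
    h = coords[:, 0].max() + 1
    w = coords[:, 1].max() + 1
    img = np.full((h, w), np.nan)
    img[coords[:, 0], coords[:, 1]] = saliency.rescaled
    fig, ax = plt.subplots(figsize=(max(2, w / 4), max(2, h / 4)))
    im = ax.imshow(img, cmap=colormap, vmin=0.0, vmax=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    title = saliency.method
    if saliency.signature_index is not None:
        title += f" sig#{saliency.signature_index + 1}"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.savefig(output_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    csv_path = str(output_path).rsplit(".", 1)[0] + ".csv"
    pd.DataFrame({"row": coords[:, 0], "col": coords[:, 1],
                  "score": saliency.per_node_score}).to_csv(csv_path,
                                                            index=False)
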