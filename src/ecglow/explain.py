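"""Model introspection: Grad-CAM saliency over beat positions, threshold
histograms and 2-D embedding of the learned beat representations.

Grad-CAM on a 1-D conv network: channel weights are the position-averaged
gradients of the (pre-softmax) class score with respect to the last conv
layer's feature maps, alpha_k = mean_i d y_c / d A_k[i]; the map is
ReLU(sum_k alpha_k A_k), normalised to max 1 per beat.  Because every conv
layer preserves the 53-sample length, the map indexes beat positions directly
with no upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SALIENCY_THRESHOLD = 0.9


@dataclass
class SaliencyMap:
    values: np.ndarray   # (53,), in [0, 1]
    target_class: int


@dataclass
class SaliencyHistogram:
    counts: np.ndarray   # per-position counts of maps exceeding the threshold
    n_maps: int
    threshold: float


@dataclass
class Embedding2D:
    xy: np.ndarray        # (n, 2)
    labels: np.ndarray    # (n,)
    glucose: np.ndarray   # (n,)


def grad_cam(detector, beats: np.ndarray, activity: np.ndarray,
             target_class: int = 1, batch_size: int = 512) -> list[SaliencyMap]:
    """Grad-CAM saliency per beat for the requested class.

    Only the per-beat CNN exposes last-conv feature maps; the sequence model's
    LSTM head is not supported.
    """
    if getattr(detector, "architecture", None) != "cnn":
        raise TypeError("Grad-CAM is only defined for the per-beat CNN detector")
    beats = np.asarray(beats, dtype=np.float32)
    activity = np.asarray(activity, dtype=np.float32)
    maps: list[SaliencyMap] = []
    for i in range(0, len(beats), batch_size):
        A, dA = detector.feature_maps_and_grads(beats[i:i + batch_size],
                                                activity[i:i + batch_size], target_class)
        alpha = dA.mean(axis=1)                      # (B, K): position-averaged gradients
        cam = np.einsum("bk,blk->bl", alpha, A)      # weighted sum of feature maps
        cam = np.maximum(cam, 0.0)
        peak = cam.max(axis=1, keepdims=True)
        nonzero = peak[:, 0] > 0
        cam[nonzero] = cam[nonzero] / peak[nonzero]
        maps.extend(SaliencyMap(values=cam[b].astype(float), target_class=target_class)
                    for b in range(cam.shape[0]))
    return maps


def saliency_histogram(maps: list[SaliencyMap],
                       threshold: float = SALIENCY_THRESHOLD) -> SaliencyHistogram:
    """Per-position count of maps whose normalised value strictly exceeds the threshold."""
    if not maps:
        raise ValueError("need at least one saliency map")
    stack = np.stack([m.values for m in maps])
    return SaliencyHistogram(counts=(stack > threshold).sum(axis=0),
                             n_maps=len(maps), threshold=threshold)


def embed_tsne(detector, beats: np.ndarray, activity: np.ndarray,
               labels: np.ndarray, glucose: np.ndarray, seed: int = 0,
               perplexity: float = 30.0, use_conv_activations: bool = False) -> Embedding2D:
    """t-SNE of the learned embedding on a class-balanced beat subset.

    Normals are downsampled (seeded, without replacement) to match the lows;
    the embedded space is the 30-unit dense activation (pre-dropout), or the
    flattened last-conv maps when ``use_conv_activations`` is set.
    """
    from sklearn.manifold import TSNE

    labels = np.asarray(labels).astype(int)
    low_idx = np.flatnonzero(labels == 1)
    norm_idx = np.flatnonzero(labels == 0)
    if low_idx.size == 0 or norm_idx.size == 0:
        raise ValueError("both classes must be present for embedding")
    rng = np.random.default_rng(seed)
    if norm_idx.size > low_idx.size:
        norm_idx = rng.choice(norm_idx, size=low_idx.size, replace=False)
    keep = np.sort(np.concatenate([low_idx, norm_idx]))

    beats = np.asarray(beats, dtype=np.float32)[keep]
    act = np.asarray(activity, dtype=np.float32)[keep]
    if use_conv_activations:
        detector.forward(beats, act, training=False)
        feats = detector._last_A.transpose(1, 0, 2).reshape(len(beats), -1)
    else:
        feats = detector.embed(beats, act)
    perp = min(perplexity, max(2.0, (len(keep) - 1) / 3.0))
    xy = TSNE(n_components=2, perplexity=perp, max_iter=1000, init="pca",
              random_state=seed).fit_transform(np.asarray(feats, dtype=np.float64))
    return Embedding2D(xy=xy, labels=labels[keep], glucose=np.asarray(glucose)[keep])
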