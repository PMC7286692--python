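"""Representational similarity analysis with permutation nulls.

Feature matrices (image x unit activations, one per named layer; raw pixel
intensities always count as a layer) are z-scored per unit, compared with
Spearman rank correlations between image pairs (Pearson and negative squared
Euclidean distance are alternatives), summarized within and between
categories, and visualized with classical (Torgerson) multidimensional
scaling on squared Euclidean distances.

Two permutation nulls are provided:

* *label shuffle* — face labels stay fixed while non-face image labels are
  randomized before recomputing face-vs-category mean similarities
  (default 2500 permutations, 2.5/97.5% bounds);
* *weight shuffle* — each layer's weights of a pluggable feed-forward
  extractor are permuted in place, simulating an untrained network while
  preserving the weight distribution (default 500 permutations).

The pretrained network of interest is a plug-in behind the extractor
interface; everything here runs on the pixel layer, random-projection
layers, or tiny seeded toy networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

CATEGORIES = ("faces", "bodies", "animals", "houses", "objects", "tools")


class UnsupportedSchemeError(TypeError):
    """Raised when a permutation scheme does not apply to the extractor."""


class FeatureExtractionError(RuntimeError):
    """Extractor failure, annotated with the offending layer."""


@dataclass
class FeatureMatrix:
    """Image x unit activations for one named layer, with category labels."""

    data: np.ndarray
    labels: np.ndarray
    layer: str

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 2:
            raise ValueError("feature matrix must be 2-D (images x units)")
        if self.labels.size != self.data.shape[0]:
            raise ValueError("one label per image required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class SimilarityMatrix:
    """Pairwise image similarities under a named metric."""

    values: np.ndarray
    labels: np.ndarray
    metric: str
    layer: str


@dataclass
class PermutationNull:
    """Null-distribution summaries per face-vs-category comparison."""

    scheme: str
    n_permutations: int
    observed: dict
    null_mean: dict
    lower: dict                      # 2.5% percentile
    upper: dict                      # 97.5% percentile
    null_samples: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"comparison": k, "observed": self.observed[k],
                 "null_mean": self.null_mean[k], "lower_2p5": self.lower[k],
                 "upper_97p5": self.upper[k]} for k in sorted(self.observed)]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------

class ToyReluNet:
    """A tiny seeded feed-forward network with mutable per-layer weights.

    Serves as the stand-in network behind the extractor interface: layers
    are dense matrices followed by a rectifier, named relu1..reluN.  Weights
    are exposed for the weight-shuffle null."""

    def __init__(self, layer_sizes, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.weights = [rng.standard_normal((din, dout)) / np.sqrt(din)
                        for din, dout in zip(layer_sizes[:-1], layer_sizes[1:])]
        self.layer_names = [f"relu{i + 1}" for i in range(len(self.weights))]

    def activations(self, images: np.ndarray) -> dict:
        x = np.asarray(images, float).reshape(len(images), -1)
        out = {}
        for name, w in zip(self.layer_names, self.weights):
            try:
                x = np.maximum(x @ w, 0.0)
            except Exception as exc:   # surface layer context
                raise FeatureExtractionError(
                    f"extractor failed at layer {name!r}: {exc}") from exc
            out[name] = x.copy()
        return out

    def with_shuffled_weights(self, rng) -> "ToyReluNet":
        """A copy with each layer's weights permuted in place (the weight
        multiset of every layer is preserved exactly)."""
        clone = ToyReluNet.__new__(ToyReluNet)
        clone.layer_names = list(self.layer_names)
        clone.weights = [rng.permutation(w.ravel()).reshape(w.shape)
                         for w in self.weights]
        return clone


def extract_features(images, labels, extractor=None):
    """One FeatureMatrix per layer; vectorized pixel intensities are always
    included as the first ("pixel") layer."""
    images = np.asarray(images, float)
    labels = np.asarray(labels)
    out = [FeatureMatrix(images.reshape(len(images), -1), labels, "pixel")]
    if extractor is not None:
        for name, acts in extractor.activations(images).items():
            out.append(FeatureMatrix(acts, labels, name))
    return out


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def zscore_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-unit mean 0 / SD 1 across images; zero-variance units dropped."""
    sd = fm.data.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zscore_features: dropped %d zero-variance units in %s",
                    dropped, fm.layer)
    z = (fm.data[:, keep] - fm.data[:, keep].mean(axis=0)) / sd[keep]
    return FeatureMatrix(z, fm.labels, fm.layer)


def pair_similarity(fm: FeatureMatrix, metric: str = "spearman") -> SimilarityMatrix:
    """All-pairs image similarity: Spearman (rank transform then Pearson),
    Pearson, or negative squared Euclidean distance."""
    X = fm.data
    if metric == "spearman":
        ranks = stats.rankdata(X, axis=1)
        vals = np.corrcoef(ranks)
    elif metric == "pearson":
        vals = np.corrcoef(X)
    elif metric == "neg_sq_euclidean":
        vals = -cdist(X, X, "sqeuclidean")
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    return SimilarityMatrix(np.asarray(vals, float), fm.labels, metric, fm.layer)


def within_between_summary(sim: SimilarityMatrix, labels=None) -> pd.DataFrame:
    """Mean similarity per category pair; the diagonal holds within-category
    means (self-pairs excluded)."""
    labels = sim.labels if labels is None else np.asarray(labels)
    cats = sorted(set(labels))
    out = pd.DataFrame(index=cats, columns=cats, dtype=float)
    for i, c1 in enumerate(cats):
        a = np.nonzero(labels == c1)[0]
        for c2 in cats[i:]:
            b = np.nonzero(labels == c2)[0]
            block = sim.values[np.ix_(a, b)]
            if c1 == c2:
                iu = np.triu_indices(len(a), k=1)
                val = float(block[iu].mean())
            else:
                val = float(block.mean())
            out.loc[c1, c2] = out.loc[c2, c1] = val
    return out


def mds_embedding(fm: FeatureMatrix, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS on squared Euclidean distances between the
    activation patterns.  Orientation and reflection are unconstrained."""
    D2 = cdist(fm.data, fm.data, "sqeuclidean")
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

def _face_category_means(sim_values, labels, face_label):
    """Observed mean face-vs-category similarity, plus the per-image mean
    similarity to faces used to evaluate label permutations."""
    face_idx = np.nonzero(labels == face_label)[0]
    other_idx = np.nonzero(labels != face_label)[0]
    if face_idx.size == 0:
        raise ValueError(f"no images labelled {face_label!r}")
    s_bar = sim_values[np.ix_(face_idx, other_idx)].mean(axis=0)
    return face_idx, other_idx, s_bar


def label_permutation_test(fm, n_permutations: int = 2500, seed: int = 0,
                           metric: str = "spearman",
                           face_label: str = "faces") -> PermutationNull:
    """Null distribution of face-vs-category mean similarities obtained by
    shuffling the labels of the *non-face* images (face labels stay fixed).

    Because every non-face image pairs with every face image, the observed
    and permuted statistics reduce to means over the per-image mean
    similarity to faces, which is what is computed."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(fm, FeatureMatrix):
        sim = pair_similarity(zscore_features(fm), metric)
    else:
        sim = fm
    labels = sim.labels
    face_idx, other_idx, s_bar = _face_category_means(sim.values, labels,
                                                      face_label)
    other_labels = labels[other_idx]
    cats = sorted(set(other_labels))
    rng = np.random.default_rng(seed)
    # permuted group assignment: each row is one shuffle of the non-face labels
    perm = np.argsort(rng.random((n_permutations, other_idx.size)), axis=1)
    observed, null_mean, lower, upper, samples = {}, {}, {}, {}, {}
    pos = 0
    for c in cats:
        n_c = int((other_labels == c).sum())
        key = f"{face_label}_vs_{c}"
        observed[key] = float(s_bar[other_labels == c].mean())
        draw = s_bar[perm[:, pos:pos + n_c]].mean(axis=1)
        null_mean[key] = float(draw.mean())
        lower[key] = float(np.percentile(draw, 2.5))
        upper[key] = float(np.percentile(draw, 97.5))
        samples[key] = draw
        pos += n_c
    return PermutationNull("label_shuffle", n_permutations, observed,
                           null_mean, lower, upper, samples)


def weight_shuffle_test(extractor, images, labels, n_permutations: int = 500,
                        seed: int = 0, metric: str = "spearman",
                        face_label: str = "faces") -> dict:
    """Per-layer null distributions from distribution-preserving weight
    shuffles of the extractor (simulated untrained network).

    Returns layer name -> :class:`PermutationNull`.  The pixel layer has no
    weights and is not eligible; extractors without accessible weights raise
    :class:`UnsupportedSchemeError`."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if extractor is None or not hasattr(extractor, "with_shuffled_weights"):
        raise UnsupportedSchemeError(
            "weight shuffling requires an extractor with mutable weights")
    labels = np.asarray(labels)
    cats = sorted(set(labels[labels != face_label]))
    observed = {}
    for fmat in extract_features(images, labels, extractor)[1:]:
        sim = pair_similarity(zscore_features(fmat), metric)
        _, other_idx, s_bar = _face_category_means(sim.values, labels, face_label)
        observed[fmat.layer] = {
            f"{face_label}_vs_{c}": float(s_bar[labels[other_idx] == c].mean())
            for c in cats}
    rng = np.random.default_rng(seed)
    draws = {layer: {k: [] for k in obs} for layer, obs in observed.items()}
    for _ in range(n_permutations):
        shuffled = extractor.with_shuffled_weights(rng)
        for fmat in extract_features(images, labels, shuffled)[1:]:
            sim = pair_similarity(zscore_features(fmat), metric)
            _, other_idx, s_bar = _face_category_means(sim.values, labels,
                                                       face_label)
            for c in cats:
                draws[fmat.layer][f"{face_label}_vs_{c}"].append(
                    float(s_bar[labels[other_idx] == c].mean()))
    out = {}
    for layer, obs in observed.items():
        arr = {k: np.asarray(v) for k, v in draws[layer].items()}
        out[layer] = PermutationNull(
            "weight_shuffle", n_permutations, obs,
            {k: float(v.mean()) for k, v in arr.items()},
            {k: float(np.percentile(v, 2.5)) for k, v in arr.items()},
            {k: float(np.percentile(v, 97.5)) for k, v in arr.items()},
            arr)
    return out


# ---------------------------------------------------------------------------
# synthetic category features
# ---------------------------------------------------------------------------

def make_category_features(n_per_category: int = 40, n_features: int = 64,
                           face_body_shared: float = 0.0,
                           category_scale: float = 1.5,
                           noise_scale: float = 1.0, seed: int = 0,
                           categories=CATEGORIES) -> FeatureMatrix:
    """Synthetic image features for six categories.

    Each category has a Gaussian mean pattern of scale ``category_scale``;
    faces and bodies additionally share a latent component of weight
    ``face_body_shared`` (the knob that makes their representations merge).
    With ``category_scale = 0`` and ``face_body_shared = 0`` the features
    are exchangeable across images."""
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_features)
    rows, labels = [], []
    for cat in categories:
        mu = category_scale * rng.standard_normal(n_features)
        if cat in ("faces", "bodies"):
            mu = mu + face_body_shared * shared
        rows.append(mu + noise_scale
                    * rng.standard_normal((n_per_category, n_features)))
        labels.extend([cat] * n_per_category)
    return FeatureMatrix(np.vstack(rows), np.asarray(labels), "synthetic")
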