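"""Pixel-level interpretable diagnostic classifier.

Spectra of tissue pixels are standardized per channel (training statistics),
projected onto a small PCA basis (default 8 components), expanded into a
multi-scale contextual feature stack (raw components, Gaussian-blurred
versions at sigma = 1 and 2, and gradient-magnitude maps of each blurred
image), and classified with a multinomial logistic regression into normal
(N), follicular (F) and papillary (P) tissue, producing per-pixel probability
maps P(N), P(F), P(P).  Atypical (anaplastic-like) specimens never contribute
training pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .voxelio import BinaryMask, VoxelStack

CLASS_LABELS = {"normal": "N", "follicular": "F", "papillary": "P"}
LABELS = ("N", "F", "P")


@dataclass
class ChannelStandardizer:
    """Per-channel (mean, sd) transform estimated on training tissue pixels."""

    mean: np.ndarray
    sd: np.ndarray
    eps: float = 1e-8

    @classmethod
    def fit(cls, pixels: np.ndarray, eps: float = 1e-8) -> "ChannelStandardizer":
        mean = pixels.mean(axis=0)
        sd = pixels.std(axis=0)
        if np.any(sd < eps):
            warnings.warn("zero-variance channel(s); epsilon guard applied")
        return cls(mean=mean, sd=sd, eps=eps)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / np.maximum(self.sd, self.eps)


@dataclass
class SpectralBasis:
    """Orthonormal PCA loadings (n_components × C) with variance ratios."""

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class ContextConfig:
    blur_scales: tuple[float, ...] = (1.0, 2.0)
    include_raw: bool = True
    include_gradient: bool = True

    def __post_init__(self):
        if any(s <= 0 for s in self.blur_scales):
            raise ValueError("blur scales must be positive")

    def n_features(self, n_components: int) -> int:
        per = (1 if self.include_raw else 0) + len(self.blur_scales) * (
            2 if self.include_gradient else 1
        )
        return n_components * per


@dataclass
class ClassProbabilityMaps:
    """Per-pixel P(N), P(F), P(P); NaN outside the tissue mask."""

    P_N: np.ndarray
    P_F: np.ndarray
    P_P: np.ndarray
    tissue_mask: BinaryMask

    def stacked(self) -> np.ndarray:
        """H×W×3 array in (N, F, P) order."""
        return np.stack([self.P_N, self.P_F, self.P_P], axis=-1)

    def argmax_labels(self) -> np.ndarray:
        """H×W array of 0/1/2 = N/F/P on tissue, -1 elsewhere."""
        lab = np.full(self.P_N.shape, -1, dtype=int)
        tis = self.tissue_mask.data.astype(bool)
        lab[tis] = np.argmax(self.stacked()[tis], axis=-1)
        return lab


@dataclass
class TrainingPixels:
    """Sampled labeled spectra with their source locations."""

    spectra: np.ndarray          # (n, C)
    labels: np.ndarray           # (n,) in {'N','F','P'}
    specimen_index: np.ndarray   # (n,) index into the training specimen list
    rows: np.ndarray
    cols: np.ndarray


def sample_training_pixels(
    specimens, per_class_cap: int = 20000, seed: int = 0
) -> TrainingPixels:
    """Sample labeled pixel spectra from training specimens.

    Normal pixels come from non-tumor tissue of every non-atypical specimen;
    follicular/papillary pixels only from tumor ∩ tissue of specimens of that
    class.  At most ``per_class_cap`` pixels per class per slide; atypical
    specimens contribute nothing.
    """
    spectra, labels, sidx, rr, cc = [], [], [], [], []
    for i, spec in enumerate(specimens):
        if spec.true_class == "atypical":
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        tissue = spec.tissue_mask.data.astype(bool)
        tumor = spec.tumor_mask.data.astype(bool)
        pools = {"N": tissue & ~tumor}
        if spec.true_class in ("follicular", "papillary"):
            pools[CLASS_LABELS[spec.true_class]] = tumor & tissue
        for lab, pool in pools.items():
            coords = np.argwhere(pool)
            if len(coords) == 0:
                continue
            if len(coords) > per_class_cap:
                coords = coords[
                    rng.choice(len(coords), size=per_class_cap, replace=False)
                ]
            spectra.append(spec.voxels.data[coords[:, 0], coords[:, 1]])
            labels.append(np.full(len(coords), lab))
            sidx.append(np.full(len(coords), i))
            rr.append(coords[:, 0])
            cc.append(coords[:, 1])
    if not spectra:
        raise ValueError("no training pixels available")
    out = TrainingPixels(
        spectra=np.concatenate(spectra),
        labels=np.concatenate(labels),
        specimen_index=np.concatenate(sidx),
        rows=np.concatenate(rr),
        cols=np.concatenate(cc),
    )
    present = set(np.unique(out.labels))
    wanted = {CLASS_LABELS[s.true_class] for s in specimens
              if s.true_class != "atypical"}
    missing = wanted - present
    if missing:
        raise ValueError(f"no pixels available for class(es) {sorted(missing)}")
    return out


def fit_standardizer_and_pca(
    pixels: np.ndarray, n_components: int = 8
) -> tuple[ChannelStandardizer, SpectralBasis]:
    """Fit the per-channel standardizer and the PCA spectral basis.

    Components are ordered by decreasing explained variance; each loading
    row's sign is fixed so its largest-magnitude entry is positive, making
    stored bases comparable across runs.
    """
    pixels = np.asarray(pixels, dtype=float)
    n, c = pixels.shape
    k = min(n_components, c, n)
    std = ChannelStandardizer.fit(pixels)
    z = std.transform(pixels)
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    pca.fit(z)
    loadings = pca.components_.copy()
    for row in loadings:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    basis = SpectralBasis(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    return std, basis


def project_to_pc_maps(
    stack: VoxelStack, standardizer: ChannelStandardizer, basis: SpectralBasis
) -> np.ndarray:
    """Standardize each pixel spectrum and project onto the PCA basis (H×W×K)."""
    if stack.n_channels != standardizer.mean.shape[0]:
        raise ValueError(
            f"stack has {stack.n_channels} channels, standardizer expects "
            f"{standardizer.mean.shape[0]}"
        )
    z = standardizer.transform(stack.data)
    return z @ basis.loadings.T


def _central_gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude via central differences with reflect padding."""
    p = np.pad(img, 1, mode="reflect")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return np.sqrt(gx**2 + gy**2)


def build_context_features(
    pc_maps: np.ndarray, config: ContextConfig | None = None
) -> np.ndarray:
    """Expand PC maps into the multi-scale contextual feature stack.

    With defaults (raw + blur at sigma 1, 2 + gradient magnitude of each
    blurred map) each component yields 5 features: K components → 5K features.
    Blur uses reflect boundaries truncated at 4 sigma.
    """
    config = config or ContextConfig()
    feats = []
    k = pc_maps.shape[2]
    for i in range(k):
        m = pc_maps[:, :, i]
        if config.include_raw:
            feats.append(m)
        for s in config.blur_scales:
            b = gaussian_filter(m, s, mode="reflect", truncate=4.0)
            feats.append(b)
            if config.include_gradient:
                feats.append(_central_gradient_magnitude(b))
    return np.stack(feats, axis=-1)


def fit_pixel_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> LogisticRegression:
    """Fit the three-class softmax-linear pixel classifier (L2, C=1.0)."""
    if len(np.unique(labels)) < 2:
        raise ValueError("pixel classifier needs at least two classes")
    clf = LogisticRegression(
        C=C, max_iter=max_iter, solver="lbfgs", random_state=seed
    )
    clf.fit(features, labels)
    return clf


def predict_probability_maps(
    stack: VoxelStack,
    tissue_mask: BinaryMask,
    standardizer: ChannelStandardizer,
    basis: SpectralBasis,
    classifier: LogisticRegression,
    context: ContextConfig | None = None,
) -> ClassProbabilityMaps:
    """Full chain: project → context features → per-pixel class probabilities.

    Pixels outside the tissue mask are flagged invalid (NaN).
    """
    if not hasattr(classifier, "coef_"):
        raise ValueError("classifier is not fitted")
    pc = project_to_pc_maps(stack, standardizer, basis)
    feats = build_context_features(pc, context)
    h, w, f = feats.shape
    proba = classifier.predict_proba(feats.reshape(-1, f)).reshape(h, w, -1)
    order = list(classifier.classes_)
    maps = {}
    for lab in LABELS:
        m = (
            proba[:, :, order.index(lab)]
            if lab in order
            else np.zeros((h, w))
        )
        m = m.copy()
        m[~tissue_mask.data.astype(bool)] = np.nan
        maps[lab] = m
    return ClassProbabilityMaps(
        P_N=maps["N"], P_F=maps["F"], P_P=maps["P"], tissue_mask=tissue_mask
    )


class PixelGate(BaseEstimator):
    """Sklearn-style estimator for the pixel-level diagnostic gate.

    ``fit`` consumes a list of training specimens (objects with ``voxels``,
    ``tissue_mask``, ``tumor_mask`` and ``true_class`` attributes) and learns
    the standardizer, PCA basis and multinomial logistic pixel classifier;
    ``predict_proba_maps`` returns per-pixel probability maps for one
    specimen.

    Parameters
    ----------
    n_components : PCA components retained (8; clipped to the channel count).
    per_class_cap : max sampled pixels per class per slide.
    blur_scales : Gaussian sigmas of the contextual blur stack.
    C : inverse L2 regularization strength of the logistic model.
    random_state : seed for pixel sampling and the solver.
    """

    def __init__(
        self,
        n_components: int = 8,
        per_class_cap: int = 20000,
        blur_scales: tuple[float, ...] = (1.0, 2.0),
        include_raw: bool = True,
        include_gradient: bool = True,
        C: float = 1.0,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.per_class_cap = per_class_cap
        self.blur_scales = blur_scales
        self.include_raw = include_raw
        self.include_gradient = include_gradient
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def _context(self) -> ContextConfig:
        return ContextConfig(
            blur_scales=tuple(self.blur_scales),
            include_raw=self.include_raw,
            include_gradient=self.include_gradient,
        )

    def fit(self, specimens, y=None):
        pixels = sample_training_pixels(
            specimens, per_class_cap=self.per_class_cap, seed=self.random_state
        )
        self.standardizer_, self.basis_ = fit_standardizer_and_pca(
            pixels.spectra, n_components=self.n_components
        )
        ctx = self._context()
        feats = []
        for i in np.unique(pixels.specimen_index):
            spec = specimens[int(i)]
            pc = project_to_pc_maps(spec.voxels, self.standardizer_, self.basis_)
            fs = build_context_features(pc, ctx)
            sel = pixels.specimen_index == i
            feats.append(fs[pixels.rows[sel], pixels.cols[sel]])
        X = np.concatenate(feats)
        order = np.argsort(pixels.specimen_index, kind="stable")
        self.classifier_ = fit_pixel_classifier(
            X,
            pixels.labels[order],
            C=self.C,
            max_iter=self.max_iter,
            seed=self.random_state,
        )
        self.classes_ = self.classifier_.classes_.copy()
        return self

    def save(self, path) -> None:
        """Persist the fitted bundle (standardizer, loadings, classifier
        coefficients, config, version) as a single npz archive."""
        from pathlib import Path

        from . import __version__

        if not hasattr(self, "classifier_"):
            raise ValueError("PixelGate is not fitted")
        np.savez(
            Path(path).with_suffix(".npz"),
            version=np.array(__version__),
            mean=self.standardizer_.mean,
            sd=self.standardizer_.sd,
            loadings=self.basis_.loadings,
            evr=self.basis_.explained_variance_ratio,
            coef=self.classifier_.coef_,
            intercept=self.classifier_.intercept_,
            classes=self.classifier_.classes_,
            params=np.array(
                [self.n_components, self.per_class_cap, self.C,
                 self.max_iter, self.random_state]
            ),
            blur_scales=np.array(self.blur_scales, dtype=float),
            flags=np.array([self.include_raw, self.include_gradient]),
        )

    @classmethod
    def load(cls, path) -> "PixelGate":
        from pathlib import Path

        data = np.load(Path(path).with_suffix(".npz"), allow_pickle=False)
        p = data["params"]
        gate = cls(
            n_components=int(p[0]),
            per_class_cap=int(p[1]),
            blur_scales=tuple(data["blur_scales"]),
            include_raw=bool(data["flags"][0]),
            include_gradient=bool(data["flags"][1]),
            C=float(p[2]),
            max_iter=int(p[3]),
            random_state=int(p[4]),
        )
        gate.standardizer_ = ChannelStandardizer(mean=data["mean"], sd=data["sd"])
        gate.basis_ = SpectralBasis(
            loadings=data["loadings"], explained_variance_ratio=data["evr"]
        )
        clf = LogisticRegression(C=float(p[2]), max_iter=int(p[3]), solver="lbfgs")
        clf.coef_ = data["coef"]
        clf.intercept_ = data["intercept"]
        clf.classes_ = data["classes"]
        gate.classifier_ = clf
        gate.classes_ = clf.classes_.copy()
        return gate

    def predict_proba_maps(self, specimen) -> ClassProbabilityMaps:
        if not hasattr(self, "classifier_"):
            raise ValueError("PixelGate is not fitted")
        return predict_probability_maps(
            specimen.voxels,
            specimen.tissue_mask,
            self.standardizer_,
            self.basis_,
            self.classifier_,
            self._context(),
        )
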