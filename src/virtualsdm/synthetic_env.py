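"""Seeded synthetic environmental raster stacks.

Real climate predictor sets are spatially smooth and strongly collinear:
temperature, altitude and evapo-transpiration layers over a continent can
share most of their variance, which is exactly what makes collinearity
screening (VIF) a meaningful preprocessing step.  This module emulates that
situation with Gaussian random fields: independent white-noise fields are
smoothed at a chosen length-scale, optionally tilted by a linear spatial
gradient, standardised, and finally mixed through the Cholesky factor of a
target inter-layer correlation matrix, so the empirical correlations of the
resulting layers approximate the target.

The default correlation template (:func:`default_correlation`) builds 27
layers — 15 moderately correlated "base" variables plus 12 near-duplicates —
so that iterative VIF elimination at the conventional threshold of 10 removes
roughly a dozen layers, mirroring a typical 27 → 15 predictor reduction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .errors import DegenerateLayerError, ParameterError
from .raster import EnvStack, GridSpec, Raster, bilinear_resample  # noqa: F401

__all__ = [
    "default_correlation",
    "generate_env_stack",
    "pca_scores",
    "bilinear_resample",
]


def default_correlation(
    n_layers: int = 27,
    n_redundant: int = 12,
    base_r: float = 0.3,
    redundant_r: float = 0.97,
) -> np.ndarray:
    """Correlation template with a block of near-duplicate layers.

    The first ``n_layers - n_redundant`` layers are "base" variables with
    uniform pairwise correlation ``base_r``.  Each of the remaining
    ``n_redundant`` layers is a noisy copy of one base layer with correlation
    ``redundant_r`` to it.  The matrix is built from that explicit factor
    model, so it is positive semi-definite by construction.
    """
    n_base = n_layers - n_redundant
    if n_base < 1 or n_redundant < 0:
        raise ParameterError("need at least one base layer")
    if n_redundant > n_base:
        raise ParameterError("at most one redundant copy per base layer")
    base = np.full((n_base, n_base), base_r)
    np.fill_diagonal(base, 1.0)
    corr = np.eye(n_layers)
    corr[:n_base, :n_base] = base
    a = redundant_r
    for i in range(n_redundant):
        d = n_base + i  # duplicate of base layer i
        corr[d, :n_base] = a * base[i]
        corr[:n_base, d] = corr[d, :n_base]
        for j in range(i):
            e = n_base + j
            corr[d, e] = corr[e, d] = a * a * base[i, j]
        corr[d, n_base + i:] = 0.0
        corr[d, d] = 1.0
        corr[d, i] = corr[i, d] = a
    return corr


def _mixing_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix A with A Aᵀ = corr (Cholesky, eigen fallback for PSD edge)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ParameterError("target_correlation must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ParameterError("target_correlation must be symmetric")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        raise ParameterError("target_correlation must be positive semi-definite")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v * np.sqrt(np.clip(w, 0.0, None))


def generate_env_stack(
    spec: GridSpec,
    n_layers: int,
    target_correlation: np.ndarray | None = None,
    smoothness: float = 5.0,
    seed: int = 0,
    gradient_weight: float = 0.3,
    layer_prefix: str = "env",
) -> EnvStack:
    """Generate a stack of smooth, collinear synthetic environmental layers.

    Parameters
    ----------
    spec
        Grid geometry of every layer.
    n_layers
        Number of layers to generate.
    target_correlation
        Symmetric PSD matrix of size ``n_layers``; the empirical inter-layer
        Pearson correlations approximate it.  Identity when omitted.
    smoothness
        Gaussian smoothing length-scale in cells; controls spatial
        autocorrelation.
    seed
        Seed for the random field generator; identical calls are
        bit-reproducible.
    gradient_weight
        Relative weight of a linear spatial gradient (random orientation per
        field) added before standardisation; gives layers the large-scale
        trend typical of climatic surfaces.  Gradients are independent across
        fields, so cross-layer correlations stay on target.
    """
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    if target_correlation is None:
        target_correlation = np.eye(n_layers)
    target_correlation = np.asarray(target_correlation, dtype=float)
    if target_correlation.shape != (n_layers, n_layers):
        raise ParameterError("target_correlation size must match n_layers")
    mix = _mixing_factor(target_correlation)

    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(
        np.arange(spec.n_rows, dtype=float),
        np.arange(spec.n_cols, dtype=float),
        indexing="ij",
    )
    fields = np.empty((n_layers, spec.n_rows, spec.n_cols))
    for i in range(n_layers):
        noise = rng.standard_normal(spec.shape)
        field = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
        if gradient_weight > 0:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            grad = np.cos(theta) * cols + np.sin(theta) * rows
            grad_sd = grad.std()
            if grad_sd > 0:
                field = field / max(field.std(), 1e-12)
                field = field + gradient_weight * (grad - grad.mean()) / grad_sd
        field = field - field.mean()
        field = field / max(field.std(), 1e-12)
        fields[i] = field

    mixed = np.tensordot(mix, fields, axes=(1, 0))
    # cosmetic per-layer affine so layers live on climate-like scales;
    # correlations and all standardised downstream steps are unaffected
    scales = rng.uniform(0.5, 20.0, size=n_layers)
    offsets = rng.uniform(-10.0, 100.0, size=n_layers)
    width = len(str(n_layers))
    layers = [
        (
            f"{layer_prefix}_{i + 1:0{width}d}",
            Raster(spec, mixed[i] * scales[i] + offsets[i]),
        )
        for i in range(n_layers)
    ]
    return EnvStack(layers)


def pca_scores(
    stack: EnvStack, n_components: int = 2
) -> tuple[list[Raster], np.ndarray]:
    """Per-cell principal-component scores of a (standardised) stack.

    Layers are z-standardised over jointly valid cells before the
    decomposition.  Each returned score raster is itself standardised to mean
    0 and unit variance, so downstream niche breadths are expressed in
    axis-standard-deviation units.  The sign of each component is fixed by
    orienting its largest-magnitude loading positive, which makes niches
    reproducible under layer reordering.

    Returns the score rasters and the explained-variance fractions.
    """
    if len(stack) < 2:
        raise ParameterError("PCA needs at least two layers")
    if n_components < 1 or n_components > len(stack):
        raise ParameterError("n_components must be in [1, n_layers]")
    mask = stack.joint_valid_mask
    X = stack.table(mask)
    sd = X.std(axis=0)
    for j, name in enumerate(stack.names):
        if sd[j] <= 0:
            raise DegenerateLayerError(f"layer {name!r} is constant")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] = -scores[:, k]
    scores = scores - scores.mean(axis=0)
    score_sd = scores.std(axis=0)
    score_sd[score_sd <= 0] = 1.0
    scores = scores / score_sd

    rasters = []
    for k in range(n_components):
        values = np.full(stack.spec.shape, np.nan)
        values[mask] = scores[:, k]
        rasters.append(Raster(stack.spec, values))
    return rasters, pca.explained_variance_ratio_
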