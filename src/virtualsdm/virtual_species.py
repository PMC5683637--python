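"""Virtual species: Gaussian niches on principal-component axes.

A virtual species is defined by a bivariate Gaussian response centred at the
origin of the first two (standardised) PCA axes of the environmental stack.
Niche breadth — the standard deviation of the response on each axis — encodes
ecological specialisation: 0.8 for a generalist down to 0.2 for a strict
specialist.  Per-cell suitability is the *product* of the two axis responses
(one strongly unfavourable variable suppresses suitability regardless of the
other), rescaled so its maximum is exactly 1, and the "true" range is the set
of cells at or above a fixed suitability threshold (0.2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import GridError, ParameterError
from .raster import EnvStack, Raster, read_ascii_grid, write_ascii_grid
from .synthetic_env import pca_scores

__all__ = [
    "SPECIALISATION_SIGMA",
    "NicheParams",
    "VirtualSpecies",
    "gaussian_response",
    "build_suitability",
    "threshold_range",
    "make_species",
    "save_species",
    "load_species",
]

#: Niche breadth (axis standard deviations) per specialisation level.
SPECIALISATION_SIGMA = {
    "generalist": 0.8,
    "restricted_generalist": 0.6,
    "relaxed_specialist": 0.4,
    "specialist": 0.2,
}


@dataclass(frozen=True)
class NicheParams:
    """Gaussian niche parameters on the first two PCA axes."""

    sigma1: float
    sigma2: float
    mu1: float = 0.0
    mu2: float = 0.0
    threshold: float = 0.2
    specialisation_label: str | None = None

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ParameterError("niche breadths must be positive")
        if not 0 < self.threshold < 1:
            raise ParameterError("threshold must be in (0, 1)")
        if (
            self.specialisation_label is not None
            and self.specialisation_label not in SPECIALISATION_SIGMA
        ):
            raise ParameterError(
                f"unknown specialisation label {self.specialisation_label!r}"
            )


@dataclass
class VirtualSpecies:
    """A simulated species with known suitability surface and true range."""

    params: NicheParams
    suitability: Raster
    true_range: Raster
    resolution_tag: str = "high"
    pc_axes: list[Raster] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.suitability.spec != self.true_range.spec:
            raise GridError("suitability and true range must share one grid")

    @property
    def label(self) -> str | None:
        return self.params.specialisation_label

    @property
    def spec(self):
        return self.suitability.spec

    def presence_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) presence cells of the true range."""
        return np.argwhere(self.true_range.values == 1.0)

    def absence_cells(self) -> np.ndarray:
        return np.argwhere(self.true_range.values == 0.0)


def gaussian_response(x, mu: float = 0.0, sigma: float = 1.0):
    """Gaussian suitability factor exp(−(x−mu)² / (2 sigma²)) in (0, 1]."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def build_suitability(pc1: Raster, pc2: Raster, params: NicheParams) -> Raster:
    """Multiplicative suitability of the two axis responses, rescaled to max 1.

    The rescaling guarantees the fixed 0.2 threshold is comparable across
    specialisation levels (without it a narrow niche could have an empty
    super-threshold set).
    """
    if pc1.spec != pc2.spec:
        raise GridError("PC score rasters must share one grid")
    product = gaussian_response(pc1.values, params.mu1, params.sigma1) * \
        gaussian_response(pc2.values, params.mu2, params.sigma2)
    peak = np.nanmax(product)
    if not np.isfinite(peak) or peak <= 0:
        raise ParameterError("suitability surface has no positive values")
    return Raster(pc1.spec, product / peak)


def threshold_range(suitability: Raster, threshold: float = 0.2) -> Raster:
    """Binary true range: presence (1.0) iff suitability ≥ threshold.

    The boundary is inclusive; nodata propagates.
    """
    values = np.where(suitability.values >= threshold, 1.0, 0.0)
    values[~suitability.valid_mask] = np.nan
    return Raster(suitability.spec, values)


def make_species(
    stack: EnvStack,
    specialisation_label: str,
    threshold: float = 0.2,
    resolution_tag: str = "high",
) -> VirtualSpecies:
    """Build a virtual species of the given specialisation level on a stack.

    Composes the PCA of the stack (first two standardised axes), the isotropic
    Gaussian niche with breadth looked up from :data:`SPECIALISATION_SIGMA`,
    the multiplicative suitability and the thresholded true range.
    Deterministic given the stack and label.
    """
    if specialisation_label not in SPECIALISATION_SIGMA:
        raise ParameterError(
            f"unknown specialisation label {specialisation_label!r}; "
            f"expected one of {sorted(SPECIALISATION_SIGMA)}"
        )
    sigma = SPECIALISATION_SIGMA[specialisation_label]
    params = NicheParams(
        sigma1=sigma,
        sigma2=sigma,
        threshold=threshold,
        specialisation_label=specialisation_label,
    )
    (pc1, pc2), _ = pca_scores(stack, n_components=2)
    suitability = build_suitability(pc1, pc2, params)
    true_range = threshold_range(suitability, threshold)
    return VirtualSpecies(
        params=params,
        suitability=suitability,
        true_range=true_range,
        resolution_tag=resolution_tag,
        pc_axes=[pc1, pc2],
    )


# ---------------------------------------------------------------------------
# Disk round-trip (suitability + true range as .asc, metadata as YAML)
# ---------------------------------------------------------------------------

def save_species(species: VirtualSpecies, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(species.suitability, out / "suitability.asc")
    write_ascii_grid(species.true_range, out / "true_range.asc")
    meta = {
        "specialisation_label": species.params.specialisation_label,
        "sigma1": species.params.sigma1,
        "sigma2": species.params.sigma2,
        "mu1": species.params.mu1,
        "mu2": species.params.mu2,
        "threshold": species.params.threshold,
        "resolution_tag": species.resolution_tag,
    }
    (out / "species.yaml").write_text(yaml.safe_dump(meta))


def load_species(in_dir: str | Path) -> VirtualSpecies:
    path = Path(in_dir)
    meta = yaml.safe_load((path / "species.yaml").read_text())
    params = NicheParams(
        sigma1=meta["sigma1"],
        sigma2=meta["sigma2"],
        mu1=meta.get("mu1", 0.0),
        mu2=meta.get("mu2", 0.0),
        threshold=meta["threshold"],
        specialisation_label=meta.get("specialisation_label"),
    )
    return VirtualSpecies(
        params=params,
        suitability=read_ascii_grid(path / "suitability.asc"),
        true_range=read_ascii_grid(path / "true_range.asc"),
        resolution_tag=meta.get("resolution_tag", "high"),
    )
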