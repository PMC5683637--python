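"""Probabilistic occurrence sampling and positional-error injection.

Presences are drawn by rejection sampling from the presence region of the
true range: a candidate cell is drawn uniformly and accepted with probability
equal to its suitability, so a pixel with suitability 0.8 has an 80% chance
of yielding a record per offer and high-suitability pixels are sampled
proportionally more often.  Absences are drawn from the absence region and
accepted with probability 1 − suitability.  Accepted records are placed
uniformly within their cell.

Positional error is injected at four levels.  Level 0 leaves coordinates
untouched.  Level k ≥ 1 displaces each record in a uniformly random direction
by a distance drawn uniformly from the annulus (k·w, (k+1)·w], where w is the
cell width — i.e. just outside a buffer of k pixels around the true location.
Displaced points landing outside the study extent are re-drawn rather than
clipped, to avoid piling records on the map edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SamplingError
from .raster import GridSpec
from .virtual_species import VirtualSpecies

__all__ = [
    "Occurrence",
    "OccurrenceSet",
    "sample_presences",
    "sample_absences",
    "simulate_offers",
    "degrade_positions",
]


@dataclass(frozen=True)
class Occurrence:
    """One sampled record with provenance back to its originating cell."""

    x: float
    y: float
    observed_class: str  # "presence" | "absence"
    precision_level: int
    true_cell: tuple[int, int]


@dataclass
class OccurrenceSet:
    """An ordered, reproducible set of sampled records."""

    occurrences: list[Occurrence]
    species_id: str
    seed: int

    def __len__(self) -> int:
        return len(self.occurrences)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates."""
        return np.array([[o.x, o.y] for o in self.occurrences], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_id,
                "x": [o.x for o in self.occurrences],
                "y": [o.y for o in self.occurrences],
                "observed_class": [o.observed_class for o in self.occurrences],
                "precision_level": [o.precision_level for o in self.occurrences],
                "true_row": [o.true_cell[0] for o in self.occurrences],
                "true_col": [o.true_cell[1] for o in self.occurrences],
                "seed": self.seed,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        occs = [
            Occurrence(
                x=row.x,
                y=row.y,
                observed_class=row.observed_class,
                precision_level=int(row.precision_level),
                true_cell=(int(row.true_row), int(row.true_col)),
            )
            for row in df.itertuples()
        ]
        species_id = str(df["species_id"].iloc[0]) if len(df) else ""
        seed = int(df["seed"].iloc[0]) if len(df) else 0
        return cls(occs, species_id=species_id, seed=seed)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _region_cells(species: VirtualSpecies, region: str) -> np.ndarray:
    cells = (
        species.presence_cells() if region == "presence" else species.absence_cells()
    )
    if len(cells) == 0:
        raise SamplingError(f"species has no {region} cells")
    return cells


def _acceptance_prob(species: VirtualSpecies, rows, cols, region: str) -> np.ndarray:
    suit = species.suitability.values[rows, cols]
    return suit if region == "presence" else 1.0 - suit


def _uniform_in_cell(rng, spec: GridSpec, rows, cols) -> tuple[np.ndarray, np.ndarray]:
    u = rng.random(len(rows))
    v = rng.random(len(rows))
    x = spec.origin_x + (cols + u) * spec.cell_size
    y = spec.origin_y + (spec.n_rows - rows - 1 + v) * spec.cell_size
    return x, y


def _rejection_sample(
    species: VirtualSpecies,
    n: int,
    seed: int,
    region: str,
    max_offers: int | None = None,
) -> OccurrenceSet:
    if n < 1:
        raise ParameterError("n must be >= 1")
    cells = _region_cells(species, region)
    spec = species.spec
    rng = np.random.default_rng(seed)
    if max_offers is None:
        max_offers = max(100_000, 10_000 * n)
    observed_class = "presence" if region == "presence" else "absence"

    kept_rows: list[np.ndarray] = []
    kept_cols: list[np.ndarray] = []
    total_kept = 0
    offers = 0
    batch = max(4 * n, 256)
    while total_kept < n:
        if offers >= max_offers:
            raise SamplingError(
                f"acceptance stalled after {offers} offers "
                f"({total_kept}/{n} accepted)"
            )
        idx = rng.integers(0, len(cells), size=batch)
        r = rng.random(batch)
        rows, cols = cells[idx, 0], cells[idx, 1]
        accept = r <= _acceptance_prob(species, rows, cols, region)
        kept_rows.append(rows[accept])
        kept_cols.append(cols[accept])
        total_kept += int(accept.sum())
        offers += batch
    rows = np.concatenate(kept_rows)[:n]
    cols = np.concatenate(kept_cols)[:n]
    x, y = _uniform_in_cell(rng, spec, rows, cols)
    occs = [
        Occurrence(
            x=float(x[i]),
            y=float(y[i]),
            observed_class=observed_class,
            precision_level=0,
            true_cell=(int(rows[i]), int(cols[i])),
        )
        for i in range(n)
    ]
    species_id = species.label or "species"
    return OccurrenceSet(occs, species_id=species_id, seed=seed)


def sample_presences(
    species: VirtualSpecies, n: int, seed: int = 0, max_offers: int | None = None
) -> OccurrenceSet:
    """Draw exactly ``n`` presence records (suitability-weighted; seeded)."""
    return _rejection_sample(species, n, seed, "presence", max_offers)


def sample_absences(
    species: VirtualSpecies, n: int, seed: int = 0, max_offers: int | None = None
) -> OccurrenceSet:
    """Draw exactly ``n`` absence records from outside the true range."""
    return _rejection_sample(species, n, seed, "absence", max_offers)


def simulate_offers(
    species: VirtualSpecies,
    n_offers: int,
    seed: int = 0,
    cell: tuple[int, int] | None = None,
    region: str = "presence",
) -> np.ndarray:
    """Replay the sampler's acceptance rule and return per-offer outcomes.

    Diagnostic entry point for calibration checks: offers ``n_offers``
    candidate cells (a fixed ``cell``, or uniform draws from the region) and
    returns the boolean acceptance vector under the same rule
    :func:`sample_presences` / :func:`sample_absences` use.
    """
    cells = _region_cells(species, region)
    rng = np.random.default_rng(seed)
    if cell is not None:
        rows = np.full(n_offers, cell[0])
        cols = np.full(n_offers, cell[1])
    else:
        idx = rng.integers(0, len(cells), size=n_offers)
        rows, cols = cells[idx, 0], cells[idx, 1]
    r = rng.random(n_offers)
    return r <= _acceptance_prob(species, rows, cols, region)


# ---------------------------------------------------------------------------
# Positional degradation
# ---------------------------------------------------------------------------

def degrade_positions(
    occs: OccurrenceSet,
    level: int,
    spec: GridSpec,
    seed: int = 0,
    max_redraws: int = 1000,
) -> OccurrenceSet:
    """Displace records to emulate imprecise coordinates at a buffer level.

    Level 0 returns the records unchanged (coordinates bit-identical).  Level
    k ≥ 1 displaces each record by a uniform random direction and a distance
    uniform in (k·w, (k+1)·w] with w the cell width; points displaced outside
    the study extent are re-drawn.
    """
    if level not in (0, 1, 2, 3):
        raise ParameterError("precision level must be one of 0, 1, 2, 3")
    if level == 0:
        return OccurrenceSet(
            [replace(o, precision_level=0) for o in occs.occurrences],
            species_id=occs.species_id,
            seed=occs.seed,
        )
    rng = np.random.default_rng(seed)
    w = spec.cell_size
    pts = occs.points
    n = len(pts)
    new_x = np.empty(n)
    new_y = np.empty(n)
    pending = np.arange(n)
    for _ in range(max_redraws):
        theta = rng.uniform(0.0, 2.0 * np.pi, size=len(pending))
        # distance strictly greater than k·w, at most (k+1)·w
        dist = (level + 1.0 - rng.random(len(pending))) * w
        cx = pts[pending, 0] + dist * np.cos(theta)
        cy = pts[pending, 1] + dist * np.sin(theta)
        ok = spec.contains(cx, cy)
        new_x[pending[ok]] = cx[ok]
        new_y[pending[ok]] = cy[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        raise SamplingError("could not place displaced points inside the extent")
    occurrences = [
        replace(o, x=float(new_x[i]), y=float(new_y[i]), precision_level=level)
        for i, o in enumerate(occs.occurrences)
    ]
    return OccurrenceSet(occurrences, species_id=occs.species_id, seed=occs.seed)
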