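"""Model performance and spatial agreement metrics.

Performance: AUC (Mann–Whitney rank formulation, ties counted ½) and the True
Skill Statistic (sensitivity + specificity − 1) maximised over candidate
thresholds.  Agreement: Schoener's D on mass-normalised surfaces and the
Overall Concordance Correlation Coefficient, which for a pair of surfaces
reduces to Lin's concordance correlation (population-moment convention).
Performance metrics come in two modes: "standard" (held-out presence vs
background, as empirical studies compute internally) and "independent"
(presences and true absences freshly sampled from the known true range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import GridError, UndefinedMetricError
from .raster import Raster

__all__ = [
    "EvaluationRecord",
    "AgreementRecord",
    "auc",
    "tss",
    "schoeners_d",
    "occc",
    "evaluate_scores",
    "independent_evaluation",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """AUC/TSS evaluation of one model run."""

    auc: float
    tss: float
    sensitivity: float
    specificity: float
    tss_threshold: float
    mode: str  # "standard" | "independent"
    replicate: int | None = None
    fold: int | None = None


@dataclass(frozen=True)
class AgreementRecord:
    """Spatial agreement between two suitability surfaces."""

    schoeners_d: float
    occc: float
    pair: tuple[str, str] = ("", "")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError("need both classes to evaluate")


def auc(scores, labels) -> float:
    """Probability that a random presence outranks a random absence.

    Rank (Mann–Whitney) formulation; tied scores count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def tss(scores, labels) -> tuple[float, float, float, float]:
    """Maximised True Skill Statistic.

    Evaluates sensitivity + specificity − 1 at every candidate threshold (the
    observed scores plus 0 and 1, prediction positive iff score ≥ threshold)
    and returns ``(tss, threshold, sensitivity, specificity)`` at the
    maximum; ties broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels != 1])
    n1, n0 = len(pos_scores), len(neg_scores)
    cuts = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    # sensitivity: share of presences with score >= cut; specificity: share
    # of absences with score < cut
    sens = 1.0 - np.searchsorted(pos_scores, cuts, side="left") / n1
    spec = np.searchsorted(neg_scores, cuts, side="left") / n0
    stat = sens + spec - 1.0
    best = int(np.argmax(stat))  # first (= lowest cut) among ties
    return float(stat[best]), float(cuts[best]), float(sens[best]), float(spec[best])


def _paired_values(r1, r2) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(r1, Raster) or isinstance(r2, Raster):
        if r1.spec != r2.spec:
            raise GridError("agreement metrics need a shared grid")
        v1, v2 = r1.values, r2.values
    else:
        v1, v2 = np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)
        if v1.shape != v2.shape:
            raise GridError("agreement metrics need equal shapes")
    mask = np.isfinite(v1) & np.isfinite(v2)
    return v1[mask].ravel(), v2[mask].ravel()


def schoeners_d(r1, r2) -> float:
    """Schoener's D niche overlap: 1 − ½ Σ|p1 − p2| on normalised surfaces.

    Each surface is normalised to total mass 1 over the shared valid cells,
    so D is invariant to positive rescaling of either surface; 0 = disjoint,
    1 = identical distributions.
    """
    v1, v2 = _paired_values(r1, r2)
    if np.any(v1 < 0) or np.any(v2 < 0):
        raise UndefinedMetricError("Schoener's D requires non-negative surfaces")
    t1, t2 = v1.sum(), v2.sum()
    if t1 <= 0 or t2 <= 0:
        raise UndefinedMetricError("Schoener's D undefined for zero-mass surface")
    return float(1.0 - 0.5 * np.abs(v1 / t1 - v2 / t2).sum())


def occc(r1, r2) -> float:
    """Concordance between two surfaces (Lin's coefficient for a pair).

    2·s12 / (s1² + s2² + (m1 − m2)²) with population (n-denominator) moments
    over the shared valid cells; 1 means identical surfaces, 0 no concordance
    beyond chance, negative values systematic discordance.
    """
    v1, v2 = _paired_values(r1, r2)
    if len(v1) < 2:
        raise UndefinedMetricError("OCCC needs at least two paired cells")
    m1, m2 = v1.mean(), v2.mean()
    s1 = np.mean((v1 - m1) ** 2)
    s2 = np.mean((v2 - m2) ** 2)
    s12 = np.mean((v1 - m1) * (v2 - m2))
    denom = s1 + s2 + (m1 - m2) ** 2
    if denom <= 0:
        raise UndefinedMetricError("OCCC undefined: both surfaces are constant")
    return float(2.0 * s12 / denom)


def evaluate_scores(
    scores,
    labels,
    mode: str = "standard",
    replicate: int | None = None,
    fold: int | None = None,
) -> EvaluationRecord:
    """Bundle AUC and maximised TSS into one evaluation record."""
    t, cut, sens, spec = tss(scores, labels)
    return EvaluationRecord(
        auc=auc(scores, labels),
        tss=t,
        sensitivity=sens,
        specificity=spec,
        tss_threshold=cut,
        mode=mode,
        replicate=replicate,
        fold=fold,
    )


def independent_evaluation(
    model,
    species,
    stack,
    n_eval: int = 500,
    seed: int = 0,
    replicate: int | None = None,
    fold: int | None = None,
) -> EvaluationRecord:
    """Evaluate a fitted model on fresh presences and *true* absences.

    Samples ``n_eval`` presences and ``n_eval`` absences from the species'
    known range via the occurrence sampler, extracts predictor features from
    ``stack`` at those points, scores them with ``model`` and returns the
    AUC/TSS record with ``mode="independent"``.
    """
    # local import: sampler depends on virtual_species, not on metrics
    from .occurrence_sampler import sample_absences, sample_presences
    from .predictor_prep import extract_features

    pres = sample_presences(species, n_eval, seed=seed)
    absn = sample_absences(species, n_eval, seed=seed + 1)
    pts = np.vstack([pres.points, absn.points])
    labels = np.concatenate([np.ones(n_eval, dtype=int), np.zeros(n_eval, dtype=int)])
    feats = extract_features(stack, pts, labels=labels)
    scores = model.predict(feats[stack.names].to_numpy())
    return evaluate_scores(
        scores,
        feats["label"].to_numpy(),
        mode="independent",
        replicate=replicate,
        fold=fold,
    )
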