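"""Similarity ranking of chemical profiles against a disease profile, and
evaluation of the ranking against known positives.

Profiles are compared as sets of significant feature names with one of three
measures:

* ``overlap``:  |A ∩ B|
* ``jaccard``:  |A ∩ B| / |A ∪ B|
* ``cosine``:   |A ∩ B| / sqrt(|A|·|B|)  (dot product of binary vectors)

Chemicals are sorted by descending similarity; tied chemicals receive the
mean of the rank positions they span (average ranks), and the "top %"
percentile of a chemical is 100·rank/total — smaller is better. A random
chemical therefore lands at 50% in expectation, which is the null the
evaluation t-test compares against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .enrichment import MolecularProfile, MolecularProfiler
from .io import ChemicalGeneTable, GeneSet, GeneSetCollection, KnownPositiveList

__all__ = [
    "RankedChemical",
    "EvaluationReport",
    "MEASURES",
    "overlap_similarity",
    "jaccard_similarity",
    "cosine_similarity",
    "rank_chemicals",
    "evaluate_known",
    "evaluate_stratified",
    "ChemicalPrioritizer",
    "round_half_away",
]


def overlap_similarity(A: Iterable[str], B: Iterable[str]) -> int:
    """Size of the intersection of two feature-name sets."""
    return len(frozenset(A) & frozenset(B))


def jaccard_similarity(A: Iterable[str], B: Iterable[str]) -> float:
    """Intersection over union; 0 when both sets are empty."""
    A, B = frozenset(A), frozenset(B)
    union = len(A | B)
    return len(A & B) / union if union else 0.0


def cosine_similarity(A: Iterable[str], B: Iterable[str]) -> float:
    """Dot product of binary membership vectors: |A∩B| / sqrt(|A|·|B|);
    0 when either set is empty."""
    A, B = frozenset(A), frozenset(B)
    if not A or not B:
        return 0.0
    return len(A & B) / math.sqrt(len(A) * len(B))


MEASURES = {
    "overlap": overlap_similarity,
    "jaccard": jaccard_similarity,
    "cosine": cosine_similarity,
}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation rounding; banker's rounding
    would turn 0.8125 into 0.812 instead of the conventional 0.813)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RankedChemical:
    """One chemical's position in the ranked list.

    ``rank`` is the average rank (fractional under ties); ``percentile`` is
    100·rank/total, in (0, 100], smaller = better.
    """

    chemical: str
    similarity: float
    rank: float
    percentile: float


def rank_chemicals(
    disease_profile: MolecularProfile,
    profiles: Mapping[str, MolecularProfile],
    measure: str = "jaccard",
) -> list[RankedChemical]:
    """Rank every chemical by profile similarity to the disease profile.

    Similarity is computed on significant-feature name sets; chemicals with
    empty profiles score 0. Output is sorted by descending similarity with a
    deterministic secondary sort by chemical id; tied similarities share the
    average of the rank positions they span.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {sorted(MEASURES)}, got {measure!r}")
    if len(disease_profile) == 0:
        raise ValueError(
            "disease profile is empty; check build_profile diagnostics "
            "(universe overlap, alpha, n_resamples)"
        )
    if not profiles:
        raise ValueError("no chemical profiles to rank")

    sim_fn = MEASURES[measure]
    d_names = disease_profile.feature_names
    chems = sorted(profiles)
    sims = np.array([float(sim_fn(d_names, profiles[c].feature_names)) for c in chems])

    order = np.lexsort((chems, -sims))  # similarity desc, id asc
    avg_rank = stats.rankdata(-sims, method="average")
    n = len(chems)
    return [
        RankedChemical(
            chemical=chems[i],
            similarity=float(sims[i]),
            rank=float(avg_rank[i]),
            percentile=100.0 * float(avg_rank[i]) / n,
        )
        for i in order
    ]


@dataclass
class EvaluationReport:
    """Recall and rank statistics of known positives within a ranked list.

    ``p_value`` is a one-sample t-test of the found percentiles against the
    random expectation of 50% (two-sided by default); NaN when fewer than two
    knowns are found, 1.0 when the percentiles have zero variance and equal
    50. ``decile_counts`` histograms the found percentiles over
    (0,10], (10,20], ..., (90,100].
    """

    recall: float
    mean_percentile: float
    median_percentile: float
    p_value: float
    decile_counts: tuple[int, ...]
    n_found: int
    n_known: int

    def summary(self) -> str:
        lines = [
            "Recall\tMean Ranking (top %)\tMedian ranking (top %)\tP-value",
            "%.3f\t%s\t%s\t%s"
            % (
                round_half_away(self.recall, 3),
                f"{self.mean_percentile:.2f}%" if self.n_found else "NA",
                f"{self.median_percentile:.2f}%" if self.n_found else "NA",
                f"{self.p_value:.3g}" if not math.isnan(self.p_value) else "NA",
            ),
            "Decile counts (top 10% ... bottom 10%): "
            + " ".join(str(c) for c in self.decile_counts),
        ]
        return "\n".join(lines)


def _decile_counts(percentiles: Sequence[float]) -> tuple[int, ...]:
    # half-open upper-inclusive bins (0,10], ..., (90,100]
    counts = [0] * 10
    for p in percentiles:
        idx = min(9, max(0, math.ceil(p / 10.0) - 1))
        counts[idx] += 1
    return tuple(counts)


def _percentile_pvalue(percentiles: np.ndarray, alternative: str) -> float:
    if len(percentiles) < 2:
        return math.nan
    if np.all(percentiles == percentiles[0]):
        # zero-variance convention: no evidence against 50 when equal to it,
        # complete separation otherwise
        v = float(percentiles[0])
        if v == 50.0:
            return 1.0
        if alternative == "two-sided":
            return 0.0
        if alternative == "less":
            return 0.0 if v < 50.0 else 1.0
        return 0.0 if v > 50.0 else 1.0
    return float(
        stats.ttest_1samp(percentiles, 50.0, alternative=alternative).pvalue
    )


def evaluate_known(
    ranked: Sequence[RankedChemical],
    known: KnownPositiveList | Iterable[str],
    alternative: str = "two-sided",
) -> EvaluationReport:
    """Evaluate a ranked list against a list of known positives.

    Recall is the fraction of known ids present anywhere in the ranked list
    (coverage-limited); mean/median/p-value/deciles are computed over the
    found chemicals' percentiles. Raises if no known id is found.
    """
    if not ranked:
        raise ValueError("ranked list is empty")
    ids = known.ids() if isinstance(known, KnownPositiveList) else list(known)
    if not ids:
        raise ValueError("known-positive list is empty")
    by_chem = {r.chemical: r for r in ranked}
    found = [by_chem[c] for c in ids if c in by_chem]
    if not found:
        raise ValueError("no known positives present in the ranked list")
    pct = np.array([r.percentile for r in found])
    return EvaluationReport(
        recall=len(found) / len(ids),
        mean_percentile=float(pct.mean()),
        median_percentile=float(np.median(pct)),
        p_value=_percentile_pvalue(pct, alternative),
        decile_counts=_decile_counts(pct),
        n_found=len(found),
        n_known=len(ids),
    )


def evaluate_stratified(
    ranked: Sequence[RankedChemical],
    known: KnownPositiveList,
    alternative: str = "two-sided",
) -> dict[str, EvaluationReport]:
    """Per-category evaluation of a categorized known-positive list.

    Categories none of whose members appear in the ranked list get a report
    with recall 0 and NaN rank statistics.
    """
    cats = known.categories()
    if not any(c for c in cats):
        raise ValueError("known-positive list carries no category labels")
    out: dict[str, EvaluationReport] = {}
    ranked_ids = {r.chemical for r in ranked}
    for cat, ids in cats.items():
        if not cat:
            continue
        if not any(c in ranked_ids for c in ids):
            out[cat] = EvaluationReport(
                recall=0.0,
                mean_percentile=math.nan,
                median_percentile=math.nan,
                p_value=math.nan,
                decile_counts=(0,) * 10,
                n_found=0,
                n_known=len(ids),
            )
        else:
            out[cat] = evaluate_known(ranked, ids, alternative)
    return out


class ChemicalPrioritizer(BaseEstimator):
    """Prioritize chemicals by molecular-profile similarity to a disease.

    ``fit(collection, disease_genes)`` builds the disease molecular profile;
    ``predict(X)`` profiles the chemicals in ``X`` (a ChemicalGeneTable or a
    precomputed mapping of profiles) and returns the full ranked list;
    ``score(X, known)`` returns the negated mean percentile of the known
    positives (greater is better, per sklearn convention).

    Parameters
    ----------
    measure : "overlap" | "jaccard" | "cosine" similarity on feature sets.
    alpha, n_resamples, correction, random_state : forwarded to the
        underlying :class:`~metaborank.enrichment.MolecularProfiler`.
    """

    def __init__(
        self,
        measure: str = "jaccard",
        alpha: float = 0.05,
        n_resamples: int = 1000,
        correction: str = "none",
        random_state: int = 0,
    ):
        self.measure = measure
        self.alpha = alpha
        self.n_resamples = n_resamples
        self.correction = correction
        self.random_state = random_state

    def fit(
        self,
        X: GeneSetCollection,
        y: GeneSet | Iterable[str] | None = None,
        disease_name: str = "disease",
    ):
        """Fit on the feature collection ``X`` and disease gene set ``y``."""
        if y is None:
            raise ValueError("disease gene set (y) is required")
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {sorted(MEASURES)}")
        self.profiler_ = MolecularProfiler(
            alpha=self.alpha,
            n_resamples=self.n_resamples,
            correction=self.correction,
            random_state=self.random_state,
        ).fit(X)
        self.disease_profile_ = self.profiler_.profile(disease_name, y)
        return self

    def predict(
        self, X: ChemicalGeneTable | Mapping[str, MolecularProfile]
    ) -> list[RankedChemical]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "disease_profile_")
        if isinstance(X, ChemicalGeneTable):
            profiles = self.profiler_.transform(X)
        else:
            profiles = dict(X)
        self.profiles_ = profiles
        return rank_chemicals(self.disease_profile_, profiles, self.measure)

    def score(self, X, y: KnownPositiveList | Iterable[str]) -> float:
        """Negated mean percentile of known positives (higher is better)."""
        report = evaluate_known(self.predict(X), y)
        return -report.mean_percentile
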