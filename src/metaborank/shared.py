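"""Characterize a chemical–disease pair by the features their profiles share.

A feature (pathway or mouse mutational phenotype) present in both the
disease and the metabolite profile is scored in each profile by a
top-normalized rank score

    rank_score(position, size) = (size - position + 1) / size

so the top-ranked feature scores 1 and the bottom one 1/size, and the two
scores are combined with a harmonic mean

    ranking_combined = 2 * ranking_d * ranking_m / (ranking_d + ranking_m).

The harmonic mean is dominated by its smaller argument, so a shared feature
ranks highly only when it ranks highly in *both* profiles: a feature at
position 5/5 in both (score 0.6 each, combined 0.6) outranks one at 1/10 in
one profile and 10/10 in the other (scores 1.0 and 0.1, combined ≈ 0.18).

For phenotypes, human genes are first translated to mouse homologs and the
profiles are built over an MGD-style phenotype-annotation collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .enrichment import MolecularProfile, build_profile
from .io import GeneSet, GeneSetCollection, HomologMap, PhenotypeAnnotationTable

__all__ = [
    "SharedFeature",
    "SharedFeatureReport",
    "rank_score",
    "combined_ranking",
    "shared_pathways",
    "map_genes_to_phenotype_sets",
    "shared_phenotypes",
]

logger = logging.getLogger(__name__)


def rank_score(position: int, profile_size: int) -> float:
    """Top-normalized rank score in (0, 1]: position 1 of N scores 1.0,
    position N scores 1/N."""
    if not 1 <= position <= profile_size:
        raise ValueError(
            f"position {position} outside [1, {profile_size}]"
        )
    return (profile_size - position + 1) / profile_size


def combined_ranking(ranking_d: float, ranking_m: float) -> float:
    """Harmonic mean of the disease-side and metabolite-side rank scores."""
    if ranking_d <= 0 or ranking_m <= 0:
        raise ValueError("rank scores must be positive")
    return 2.0 * ranking_d * ranking_m / (ranking_d + ranking_m)


@dataclass(frozen=True)
class SharedFeature:
    """A feature enriched in both profiles, with its two rank scores and
    their harmonic combination."""

    feature: str
    ranking_d: float
    ranking_m: float
    ranking_combined: float


@dataclass
class SharedFeatureReport:
    """Shared features of a disease/metabolite profile pair, sorted by
    descending combined ranking, plus the shared fraction relative to the
    disease profile (|D ∩ M| / |D|, as a percentage)."""

    features: list[SharedFeature]
    n_disease: int
    n_metabolite: int
    n_shared: int
    shared_fraction: float  # percent, full precision

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": [f.feature for f in self.features],
                "ranking_d": [f.ranking_d for f in self.features],
                "ranking_m": [f.ranking_m for f in self.features],
                "ranking_combined": [f.ranking_combined for f in self.features],
            }
        )


def shared_pathways(
    profile_d: MolecularProfile, profile_m: MolecularProfile
) -> SharedFeatureReport:
    """Intersect two profiles and prioritize the shared features.

    Each shared feature gets rank scores from its 1-based position within
    each profile's ordering; output is sorted by descending
    ``ranking_combined`` with ties broken by feature name. An empty
    intersection yields an empty report (logged, not raised).
    """
    if len(profile_d) == 0 or len(profile_m) == 0:
        raise ValueError("both profiles must be non-empty")
    shared_names = profile_d.feature_names & profile_m.feature_names
    if not shared_names:
        logger.info(
            "no shared features between %s and %s",
            profile_d.entity,
            profile_m.entity,
        )
    features = []
    for name in shared_names:
        rd = rank_score(profile_d.position(name), len(profile_d))
        rm = rank_score(profile_m.position(name), len(profile_m))
        features.append(SharedFeature(name, rd, rm, combined_ranking(rd, rm)))
    features.sort(key=lambda f: (-f.ranking_combined, f.feature))
    return SharedFeatureReport(
        features=features,
        n_disease=len(profile_d),
        n_metabolite=len(profile_m),
        n_shared=len(features),
        shared_fraction=100.0 * len(features) / len(profile_d),
    )


def map_genes_to_phenotype_sets(
    genes: GeneSet,
    homologs: HomologMap,
    annotations: PhenotypeAnnotationTable,
) -> tuple[GeneSet, GeneSetCollection]:
    """Translate human genes to mouse homologs and pair them with the
    phenotype collection.

    Returns the mapped mouse-gene query set (deduplicated) and the phenotype
    annotations as a gene-set collection over mouse genes. Human genes with
    no homolog are dropped with a logged count; raises if none map.
    """
    if len(homologs) == 0:
        raise ValueError("homolog map is empty")
    mouse_genes, dropped = homologs.map_genes(genes.genes)
    if dropped:
        logger.info(
            "%s: %d/%d genes had no mouse homolog and were dropped",
            genes.name,
            len(dropped),
            len(genes),
        )
    if not mouse_genes:
        raise ValueError(
            f"no genes of {genes.name!r} map to any mouse homolog"
        )
    return GeneSet(genes.name, mouse_genes), annotations.to_collection()


def shared_phenotypes(
    disease_genes: GeneSet,
    metabolite_genes: GeneSet,
    homologs: HomologMap,
    annotations: PhenotypeAnnotationTable,
    alpha: float = 0.05,
    n_resamples: int = 1000,
    seed: int = 0,
) -> SharedFeatureReport:
    """Shared mouse mutational phenotypes of a disease/metabolite pair.

    Both gene sets are mapped to mouse homologs, phenotype profiles are built
    by resampling enrichment over the annotation collection, and the shared
    phenotypes are prioritized exactly as shared pathways; the shared
    fraction is relative to the disease phenotype profile.
    """
    d_mouse, collection = map_genes_to_phenotype_sets(
        disease_genes, homologs, annotations
    )
    m_mouse, _ = map_genes_to_phenotype_sets(metabolite_genes, homologs, annotations)
    profile_d = build_profile(
        disease_genes.name, d_mouse, collection, alpha, n_resamples, seed
    )
    profile_m = build_profile(
        metabolite_genes.name, m_mouse, collection, alpha, n_resamples, seed
    )
    return shared_pathways(profile_d, profile_m)
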