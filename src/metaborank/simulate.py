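"""Synthetic universes for end-to-end testing of the prioritization pipeline.

A universe bundles everything the pipeline reads — a pathway collection, a
chemical–gene table, a disease gene list, mouse phenotype annotations, a
human→mouse homolog map and a known-positive list — plus the ground truth
used to plant it. It emulates, at toy scale, the statistical structure the
method assumes: sparse chemical–gene bipartite links, overlapping random
pathways, and a minority of chemicals whose genes are drawn from the
disease-pathway gene pool.

Planted signal: ``n_disease_pathways`` pathways have half their members
replaced by disease genes (so the disease profile is genuinely enriched for
them), and each of the ``n_positive_chemicals`` positives draws a
``signal_strength`` fraction of its genes from the disease-pathway gene pool
(the rest uniformly). ``signal_strength = 0`` yields a null universe whose
"positives" are statistically indistinguishable from background. Mouse
phenotype annotations mirror the pathway construction over a mouse-gene
mirror of the universe (``GENE0001`` → ``Gene0001``) with an identity
homolog map.

All randomness flows from ``config.seed`` through named substreams
(pathways / disease / chemicals / phenotypes), so regenerating any one stage
does not perturb another's draws and the same config is byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .enrichment import _stable_hash
from .io import (
    ChemicalGeneTable,
    GeneSet,
    GeneSetCollection,
    HomologMap,
    KnownPositiveList,
    PhenotypeAnnotationTable,
    write_chemical_gene_table,
    write_gene_set_collection,
    write_homolog_map,
    write_known_positives,
    write_phenotype_annotations,
)

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticUniverse",
           "generate_universe", "write_universe"]

#: fixture vocabulary for planted-positive category labels
CATEGORY_CYCLE = (
    "SCFAs",
    "Bile acids",
    "Indoles",
    "Cresols",
    "Phenolic acids",
    "Polyamines",
)

#: fraction of a disease pathway's members replaced by disease genes
DISEASE_SEED_FRACTION = 0.5


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic universe; defaults give a desk-scale world
    with a clearly recoverable planted signal."""

    n_genes: int = 1000
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 50)
    n_chemicals: int = 500
    chemical_genes_range: tuple[int, int] = (5, 20)
    n_disease_genes: int = 50
    n_disease_pathways: int = 10
    n_positive_chemicals: int = 30
    signal_strength: float = 0.8
    n_phenotypes: int = 200
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "n_chemicals": self.n_chemicals,
            "n_disease_genes": self.n_disease_genes,
            "n_disease_pathways": self.n_disease_pathways,
            "n_positive_chemicals": self.n_positive_chemicals,
            "n_phenotypes": self.n_phenotypes,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        for name, (lo, hi) in (
            ("pathway_size_range", self.pathway_size_range),
            ("chemical_genes_range", self.chemical_genes_range),
        ):
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be an ordered positive range")
            if hi > self.n_genes:
                raise ValueError(f"{name} max {hi} exceeds n_genes {self.n_genes}")
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes exceeds n_genes")
        if self.n_disease_pathways > self.n_pathways:
            raise ValueError("n_disease_pathways exceeds n_pathways")
        if self.n_disease_pathways > self.n_phenotypes:
            raise ValueError("n_disease_pathways exceeds n_phenotypes")
        if self.n_positive_chemicals > self.n_chemicals:
            raise ValueError("n_positive_chemicals exceeds n_chemicals")
        # every disease pathway must be able to host its disease-gene seeds
        max_seed = math.ceil(DISEASE_SEED_FRACTION * self.pathway_size_range[1])
        if max_seed > self.n_disease_genes:
            raise ValueError(
                f"infeasible config: a disease pathway may need {max_seed} "
                f"seeded disease genes but only {self.n_disease_genes} exist"
            )


@dataclass
class GroundTruth:
    """What was planted: the positive chemicals and the disease-enriched
    pathway/phenotype names."""

    positive_chemicals: frozenset[str]
    disease_pathways: frozenset[str]
    disease_phenotypes: frozenset[str]


@dataclass
class SyntheticUniverse:
    config: SyntheticConfig
    pathways: GeneSetCollection
    chemical_genes: ChemicalGeneTable
    disease_genes: GeneSet
    phenotype_annotations: PhenotypeAnnotationTable
    homologs: HomologMap
    known_positives: KnownPositiveList
    truth: GroundTruth


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), _stable_hash(label)]))
    )


def _random_sets(
    rng: np.random.Generator,
    genes: np.ndarray,
    n_sets: int,
    size_range: tuple[int, int],
    prefix: str,
) -> dict[str, frozenset[str]]:
    width = len(str(n_sets))
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_sets)
    return {
        f"{prefix}{i + 1:0{width}d}": frozenset(
            rng.choice(genes, size=int(sizes[i]), replace=False)
        )
        for i in range(n_sets)
    }


def _plant_disease(
    rng: np.random.Generator,
    sets: dict[str, frozenset[str]],
    target_names: list[str],
    disease_genes: np.ndarray,
) -> None:
    """Replace ~half of each target set's members with disease genes."""
    for name in target_names:
        members = sorted(sets[name])
        n_seed = max(1, round(DISEASE_SEED_FRACTION * len(members)))
        if n_seed > len(disease_genes):
            raise ValueError(
                f"infeasible: pathway {name!r} needs {n_seed} disease-gene "
                f"seeds but only {len(disease_genes)} disease genes exist"
            )
        seeds = rng.choice(disease_genes, size=n_seed, replace=False)
        keep = rng.choice(members, size=len(members) - n_seed, replace=False)
        sets[name] = frozenset(keep) | frozenset(seeds)


def generate_universe(config: SyntheticConfig) -> SyntheticUniverse:
    """Generate a complete synthetic universe from a validated config."""
    config.validate()
    width = len(str(config.n_genes))
    human = np.array([f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)])
    mouse_of = {g: g.capitalize() for g in human}

    # --- disease genes (own substream so other stages are unaffected) -----
    rng_d = _rng(config.seed, "disease")
    disease = np.sort(rng_d.choice(human, size=config.n_disease_genes, replace=False))

    # --- pathways, with disease genes planted into a designated subset ----
    rng_p = _rng(config.seed, "pathways")
    path_sets = _random_sets(
        rng_p, human, config.n_pathways, config.pathway_size_range, "PW"
    )
    disease_pathways = sorted(
        rng_p.choice(sorted(path_sets), size=config.n_disease_pathways, replace=False)
    )
    _plant_disease(rng_p, path_sets, disease_pathways, disease)
    collection = GeneSetCollection(
        GeneSet(name, genes) for name, genes in path_sets.items()
    )
    disease_pool = np.array(
        sorted(set().union(*(path_sets[n] for n in disease_pathways)))
    )

    # --- chemicals: positives mix disease-pool genes with background ------
    rng_c = _rng(config.seed, "chemicals")
    cwidth = len(str(config.n_chemicals))
    chem_names = [f"CHEM{i + 1:0{cwidth}d}" for i in range(config.n_chemicals)]
    positives = set(
        rng_c.choice(chem_names, size=config.n_positive_chemicals, replace=False)
    )
    chemicals: dict[str, frozenset[str]] = {}
    scores: dict[tuple[str, str], float] = {}
    lo, hi = config.chemical_genes_range
    for chem in chem_names:
        size = int(rng_c.integers(lo, hi + 1))
        if chem in positives:
            n_sig = min(round(config.signal_strength * size), len(disease_pool))
            sig = rng_c.choice(disease_pool, size=n_sig, replace=False)
            rest_pool = np.setdiff1d(human, sig, assume_unique=False)
            rest = rng_c.choice(rest_pool, size=size - n_sig, replace=False)
            genes = frozenset(sig) | frozenset(rest)
        else:
            genes = frozenset(rng_c.choice(human, size=size, replace=False))
        chemicals[chem] = genes
        for g in sorted(genes):
            scores[(chem, g)] = float(rng_c.integers(150, 1000))
    table = ChemicalGeneTable(chemicals, scores)

    # --- phenotypes over the mouse-gene mirror -----------------------------
    rng_f = _rng(config.seed, "phenotypes")
    mouse = np.array([mouse_of[g] for g in human])
    mouse_disease = np.array(sorted(mouse_of[g] for g in disease))
    phen_sets = _random_sets(
        rng_f, mouse, config.n_phenotypes, config.pathway_size_range, "phenotype "
    )
    disease_phenotypes = sorted(
        rng_f.choice(sorted(phen_sets), size=config.n_disease_pathways, replace=False)
    )
    _plant_disease(rng_f, phen_sets, disease_phenotypes, mouse_disease)
    annotations = PhenotypeAnnotationTable(dict(phen_sets))

    homologs = HomologMap({g: frozenset({mouse_of[g]}) for g in human})

    known = KnownPositiveList(
        [
            (chem, CATEGORY_CYCLE[i % len(CATEGORY_CYCLE)])
            for i, chem in enumerate(sorted(positives))
        ]
    )
    truth = GroundTruth(
        positive_chemicals=frozenset(positives),
        disease_pathways=frozenset(disease_pathways),
        disease_phenotypes=frozenset(disease_phenotypes),
    )
    return SyntheticUniverse(
        config=config,
        pathways=collection,
        chemical_genes=table,
        disease_genes=GeneSet("disease", frozenset(disease)),
        phenotype_annotations=annotations,
        homologs=homologs,
        known_positives=known,
        truth=truth,
    )


def write_universe(universe: SyntheticUniverse, directory) -> dict:
    """Write all six input files plus ground truth and a manifest.

    Returns the manifest (also written as ``manifest.json``): config, seed
    and the list of emitted files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files = {
        "pathways": "pathways.gmt",
        "chemical_genes": "chemical_genes.tsv",
        "disease_genes": "disease_genes.txt",
        "phenotype_annotations": "phenotype_annotations.tsv",
        "homologs": "homolog_map.tsv",
        "known_positives": "known_positives.tsv",
        "ground_truth": "ground_truth.tsv",
    }
    write_gene_set_collection(universe.pathways, directory / files["pathways"])
    write_chemical_gene_table(
        universe.chemical_genes, directory / files["chemical_genes"]
    )
    with open(directory / files["disease_genes"], "w") as fh:
        for g in sorted(universe.disease_genes.genes):
            fh.write(g + "\n")
    write_phenotype_annotations(
        universe.phenotype_annotations, directory / files["phenotype_annotations"]
    )
    write_homolog_map(universe.homologs, directory / files["homologs"])
    write_known_positives(universe.known_positives, directory / files["known_positives"])
    with open(directory / files["ground_truth"], "w") as fh:
        fh.write("kind\tname\n")
        for chem in sorted(universe.truth.positive_chemicals):
            fh.write(f"positive_chemical\t{chem}\n")
        for pw in sorted(universe.truth.disease_pathways):
            fh.write(f"disease_pathway\t{pw}\n")
        for ph in sorted(universe.truth.disease_phenotypes):
            fh.write(f"disease_phenotype\t{ph}\n")

    manifest = {
        "config": asdict(universe.config),
        "seed": universe.config.seed,
        "files": sorted(files.values()),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
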