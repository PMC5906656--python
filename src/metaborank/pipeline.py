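"""End-to-end pipeline: profile the disease and every chemical, rank, evaluate
against known positives, and characterize top-ranked chemicals by shared
pathways and shared mouse phenotypes.

Every stage writes a TSV under the output directory, and the staged outputs
are exactly what the corresponding library calls return — the orchestration
layer adds no computation of its own.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import io as mio
from .enrichment import MolecularProfile
from .ranking import ChemicalPrioritizer, RankedChemical, evaluate_known, \
    evaluate_stratified, round_half_away
from .shared import shared_pathways, shared_phenotypes

__all__ = ["RunConfig", "run_pipeline", "write_ranked_list", "write_profile"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    gene_sets: str
    chemical_genes: str
    disease_genes: str
    known_positives: str | None = None
    phenotype_annotations: str | None = None
    homolog_map: str | None = None
    out_dir: str = "metaborank_out"
    measure: str = "jaccard"
    alpha: float = 0.05
    n_resamples: int = 1000
    seed: int = 0
    score_cutoff: float = 0.0
    correction: str = "none"
    top_k: int = 1  # top-ranked non-known chemicals to characterize

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.measure not in ("overlap", "jaccard", "cosine"):
            raise ValueError(f"unknown measure {self.measure!r}")
        required = {
            "gene_sets": self.gene_sets,
            "chemical_genes": self.chemical_genes,
            "disease_genes": self.disease_genes,
        }
        optional = {
            "known_positives": self.known_positives,
            "phenotype_annotations": self.phenotype_annotations,
            "homolog_map": self.homolog_map,
        }
        for name, path in required.items():
            if not path:
                raise ValueError(f"missing required input path: {name}")
            if not Path(path).is_file():
                raise FileNotFoundError(f"{name}: no such file {path!r}")
        for name, path in optional.items():
            if path and not Path(path).is_file():
                raise FileNotFoundError(f"{name}: no such file {path!r}")


def write_profile(profile: MolecularProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_ranked_list(ranked: list[RankedChemical], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "chemical": [r.chemical for r in ranked],
            "similarity": [r.similarity for r in ranked],
            "rank": [r.rank for r in ranked],
            "percentile": [r.percentile for r in ranked],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_ranked_list(path) -> list[RankedChemical]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        RankedChemical(r.chemical, float(r.similarity), float(r.rank), float(r.percentile))
        for r in df.itertuples()
    ]


def _report_row(label: str, rep) -> dict:
    return {
        "subset": label,
        "n_known": rep.n_known,
        "n_found": rep.n_found,
        "recall": round_half_away(rep.recall, 3),
        "mean_top_pct": rep.mean_percentile,
        "median_top_pct": rep.median_percentile,
        "p_value": rep.p_value,
        "deciles": ",".join(str(c) for c in rep.decile_counts),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a run report (stage timings, outputs, summary
    statistics). Raises with the failing stage named on any error."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": [], "seed": config.seed}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                report["stages"][name] = round(dt, 3)
                if exc is not None:
                    logger.error("stage %s: failed after %.1fs: %s", name, dt, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.1fs", name, dt)

        return _Timer()

    with stage("load"):
        collection = mio.read_gene_set_collection(config.gene_sets)
        table = mio.read_chemical_gene_table(
            config.chemical_genes, score_cutoff=config.score_cutoff
        )
        disease = mio.read_gene_list(config.disease_genes, name="disease")
        known = (
            mio.read_known_positives(config.known_positives)
            if config.known_positives
            else None
        )

    with stage("profile"):
        prioritizer = ChemicalPrioritizer(
            measure=config.measure,
            alpha=config.alpha,
            n_resamples=config.n_resamples,
            correction=config.correction,
            random_state=config.seed,
        ).fit(collection, disease)
        write_profile(prioritizer.disease_profile_, out / "disease_profile.tsv")
        report["outputs"].append("disease_profile.tsv")
        report["n_disease_features"] = len(prioritizer.disease_profile_)

    with stage("rank"):
        ranked = prioritizer.predict(table)
        write_ranked_list(ranked, out / "ranked_chemicals.tsv")
        report["outputs"].append("ranked_chemicals.tsv")
        report["n_chemicals"] = len(ranked)

    summary_blocks: list[str] = []
    if known is not None:
        with stage("evaluate"):
            import pandas as pd

            rep = evaluate_known(ranked, known)
            rows = [_report_row("all", rep)]
            if any(cat for _, cat in known.entries):
                for cat, crep in sorted(evaluate_stratified(ranked, known).items()):
                    rows.append(_report_row(cat, crep))
            pd.DataFrame(rows).to_csv(
                out / "evaluation.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            report["outputs"].append("evaluation.tsv")
            report["evaluation"] = rows[0]
            summary_blocks.append("== Known-positive evaluation ==\n" + rep.summary())

    known_ids = set(known.ids()) if known is not None else set()
    top_novel = [r.chemical for r in ranked if r.chemical not in known_ids][
        : config.top_k
    ]
    report["top_novel"] = top_novel

    with stage("shared-pathways"):
        for chem in top_novel:
            pair = shared_pathways(
                prioritizer.disease_profile_, prioritizer.profiles_[chem]
            )
            pair.to_frame().to_csv(
                out / f"shared_pathways_{chem}.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            report["outputs"].append(f"shared_pathways_{chem}.tsv")
            summary_blocks.append(
                f"== Shared pathways: disease vs {chem} ==\n"
                f"{pair.n_shared} of {pair.n_disease} disease pathways shared "
                f"({round_half_away(pair.shared_fraction, 1)}%)"
            )

    if config.phenotype_annotations and config.homolog_map:
        with stage("shared-phenotypes"):
            annotations = mio.read_phenotype_annotations(config.phenotype_annotations)
            homologs = mio.read_homolog_map(config.homolog_map)
            for chem in top_novel:
                pair = shared_phenotypes(
                    disease,
                    mio.GeneSet(chem, table[chem]),
                    homologs,
                    annotations,
                    alpha=config.alpha,
                    n_resamples=config.n_resamples,
                    seed=config.seed,
                )
                pair.to_frame().to_csv(
                    out / f"shared_phenotypes_{chem}.tsv", sep="\t", index=False,
                    float_format=FLOAT_FORMAT,
                )
                report["outputs"].append(f"shared_phenotypes_{chem}.tsv")
                summary_blocks.append(
                    f"== Shared phenotypes: disease vs {chem} ==\n"
                    f"{pair.n_shared} of {pair.n_disease} disease phenotypes "
                    f"shared ({round_half_away(pair.shared_fraction, 0):.0f}%)"
                )

    with open(out / "summary.txt", "w") as fh:
        fh.write("\n\n".join(summary_blocks) + "\n")
    report["outputs"].append("summary.txt")
    return report
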