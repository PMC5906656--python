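"""Readers, writers and domain containers for the pipeline's file formats.

Human gene symbols are case-insensitive and normalized to uppercase (HGNC
convention); mouse symbols are conventionally mixed-case and matched exactly
(MGI convention), so phenotype-annotation and homolog-target symbols are left
untouched.

Formats:

* gene-set collections (pathways, phenotype sets): GMT — one set per line,
  ``name<TAB>description<TAB>gene1<TAB>gene2...``
* chemical–gene associations: TSV with header ``chemical_id, gene[, score]``
  (STITCH-style, score in [0, 1000])
* known positives: TSV with header ``chemical_id[, category]``
* phenotype annotations: two-column TSV ``gene, phenotype``
* homolog map: two-column TSV ``human_gene, mouse_gene``
* plain gene lists: one symbol per line
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ChemicalGeneTable",
    "PhenotypeAnnotationTable",
    "HomologMap",
    "KnownPositiveList",
    "ParseError",
    "ValidationError",
    "read_gene_list",
    "read_gene_set_collection",
    "write_gene_set_collection",
    "read_chemical_gene_table",
    "write_chemical_gene_table",
    "read_known_positives",
    "write_known_positives",
    "read_phenotype_annotations",
    "write_phenotype_annotations",
    "read_homolog_map",
    "write_homolog_map",
]

#: significant digits used when printing floating-point values to TSV
FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _check_symbol(sym: str, lineno: int | None = None, path=None) -> str:
    if not sym or any(c.isspace() for c in sym):
        where = f" (line {lineno} of {path})" if lineno is not None else ""
        raise ParseError(f"invalid gene symbol {sym!r}{where}")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    Symbols must be non-empty, whitespace-free strings; the set itself must
    be non-empty.
    """

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))
        for g in self.genes:
            _check_symbol(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


class GeneSetCollection:
    """A collection of uniquely named gene sets over a shared gene universe.

    The universe is the union of all member sets.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self.sets:
                raise ValidationError(f"duplicate set name {gs.name!r}")
            self.sets[gs.name] = gs
        universe: set[str] = set()
        for gs in self.sets.values():
            universe |= gs.genes
        self.universe: frozenset[str] = frozenset(universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {n: s.genes for n, s in self.sets.items()} == {
            n: s.genes for n, s in other.sets.items()
        }

    def __repr__(self) -> str:
        return (
            f"GeneSetCollection({len(self.sets)} sets, "
            f"universe of {len(self.universe)} genes)"
        )


@dataclass
class ChemicalGeneTable:
    """Bipartite chemical → gene-set mapping with optional association scores.

    ``scores`` maps (chemical, gene) to a STITCH-style confidence in
    [0, 1000]; it may be empty when the source carried no scores.
    """

    chemicals: dict[str, frozenset[str]]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for chem, genes in self.chemicals.items():
            if not genes:
                raise ValidationError(f"chemical {chem!r} has no genes")
            self.chemicals[chem] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.chemicals)

    def __iter__(self):
        return iter(self.chemicals.items())

    def __getitem__(self, chemical: str) -> frozenset[str]:
        return self.chemicals[chemical]

    def __contains__(self, chemical: str) -> bool:
        return chemical in self.chemicals

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChemicalGeneTable):
            return NotImplemented
        return self.chemicals == other.chemicals and self.scores == other.scores


@dataclass
class PhenotypeAnnotationTable:
    """Mapping phenotype name → set of annotated mouse gene symbols."""

    annotations: dict[str, frozenset[str]]

    def __post_init__(self):
        for phen, genes in self.annotations.items():
            if not genes:
                raise ValidationError(f"phenotype {phen!r} has no genes")
            self.annotations[phen] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.annotations)

    def to_collection(self) -> GeneSetCollection:
        """View the annotations as a gene-set collection over mouse genes."""
        return GeneSetCollection(
            GeneSet(name, genes) for name, genes in self.annotations.items()
        )


@dataclass
class HomologMap:
    """One-to-many mapping human gene symbol → mouse gene symbols."""

    pairs: dict[str, frozenset[str]]

    def __post_init__(self):
        for human, mice in self.pairs.items():
            if not mice:
                raise ValidationError(f"homolog entry {human!r} has no targets")
            self.pairs[human] = frozenset(mice)

    def __len__(self) -> int:
        return len(self.pairs)

    def map_genes(self, genes: Iterable[str]) -> tuple[frozenset[str], list[str]]:
        """Map human symbols to the union of their mouse homologs.

        Returns the mouse gene set and the list of human genes with no
        homolog entry (dropped).
        """
        mapped: set[str] = set()
        dropped: list[str] = []
        for g in genes:
            targets = self.pairs.get(g)
            if targets:
                mapped |= targets
            else:
                dropped.append(g)
        return frozenset(mapped), sorted(dropped)


@dataclass
class KnownPositiveList:
    """Known disease-associated chemicals, optionally labelled by category."""

    entries: list[tuple[str, str]]  # (chemical id, category; "" if absent)

    def __post_init__(self):
        ids = [c for c, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({c for c in ids if ids.count(c) > 1})
            raise ValidationError(f"duplicate known-positive ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [c for c, _ in self.entries]

    def categories(self) -> dict[str, list[str]]:
        """Category → chemical ids, preserving file order; uncategorized rows
        fall under the empty-string key."""
        out: dict[str, list[str]] = {}
        for chem, cat in self.entries:
            out.setdefault(cat, []).append(chem)
        return out


# ---------------------------------------------------------------------------
# readers


def read_gene_list(path, name: str = "query") -> GeneSet:
    """Read a plain-text gene list (one human symbol per line) as a GeneSet.

    Symbols are uppercased and deduplicated; blank lines and ``#`` comments
    are ignored.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            genes.add(_check_symbol(sym, lineno, path).upper())
    if not genes:
        raise ValidationError(f"no genes found in {path}")
    return GeneSet(name, frozenset(genes))


def read_gene_set_collection(path, uppercase: bool = True) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line needs at least three tab-separated fields (name, description,
    one or more genes). Genes are deduplicated within a line and, when
    ``uppercase`` (human symbols), normalized to uppercase.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno} of {path}: expected >=3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            genes = {
                _check_symbol(g, lineno, path).upper() if uppercase else g
                for g in fields[2:]
                if g
            }
            if not genes:
                raise ParseError(f"line {lineno} of {path}: set {name!r} has no genes")
            sets.append(GeneSet(name, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gene_set_collection(collection: GeneSetCollection, path) -> None:
    """Write a collection to GMT (description field left blank)."""
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, ""] + sorted(gs.genes)) + "\n")


def read_chemical_gene_table(path, score_cutoff: float = 0.0) -> ChemicalGeneTable:
    """Read a STITCH-style chemical–gene TSV.

    Mandatory header columns ``chemical_id`` and ``gene``; optional ``score``.
    Pairs with score below ``score_cutoff`` are dropped before grouping
    (default 0: keep everything). Gene symbols are uppercased.
    """
    chemicals: dict[str, set[str]] = {}
    scores: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for required in ("chemical_id", "gene"):
            if required not in cols:
                raise ValidationError(
                    f"{path}: missing mandatory column {required!r} (found {cols})"
                )
        has_score = "score" in cols
        for lineno, row in enumerate(reader, 2):
            chem = (row["chemical_id"] or "").strip()
            gene = (row["gene"] or "").strip()
            if not chem or not gene:
                raise ParseError(f"line {lineno} of {path}: empty chemical or gene")
            gene = _check_symbol(gene, lineno, path).upper()
            score = None
            if has_score and row["score"] not in (None, ""):
                try:
                    score = float(row["score"])
                except ValueError:
                    raise ParseError(
                        f"line {lineno} of {path}: non-numeric score {row['score']!r}"
                    ) from None
            if score is not None and score < score_cutoff:
                continue
            chemicals.setdefault(chem, set()).add(gene)
            if score is not None:
                scores[(chem, gene)] = score
    return ChemicalGeneTable(
        {c: frozenset(g) for c, g in chemicals.items()}, scores
    )


def write_chemical_gene_table(table: ChemicalGeneTable, path) -> None:
    with_scores = bool(table.scores)
    with open(path, "w") as fh:
        fh.write("chemical_id\tgene" + ("\tscore" if with_scores else "") + "\n")
        for chem in sorted(table.chemicals):
            for gene in sorted(table.chemicals[chem]):
                row = f"{chem}\t{gene}"
                if with_scores:
                    s = table.scores.get((chem, gene))
                    row += "\t" + (FLOAT_FORMAT % s if s is not None else "")
                fh.write(row + "\n")


def read_known_positives(path) -> KnownPositiveList:
    """Read a known-positive TSV (``chemical_id`` column, optional
    ``category``), preserving file order."""
    entries: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if "chemical_id" not in cols:
            raise ValidationError(f"{path}: missing mandatory column 'chemical_id'")
        has_cat = "category" in cols
        for lineno, row in enumerate(reader, 2):
            chem = (row["chemical_id"] or "").strip()
            if not chem:
                raise ParseError(f"line {lineno} of {path}: empty chemical id")
            cat = (row["category"] or "").strip() if has_cat else ""
            entries.append((chem, cat))
    return KnownPositiveList(entries)


def write_known_positives(known: KnownPositiveList, path) -> None:
    with open(path, "w") as fh:
        fh.write("chemical_id\tcategory\n")
        for chem, cat in known.entries:
            fh.write(f"{chem}\t{cat}\n")


def _read_two_column_tsv(path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.lower().split("\t")[0] in (
                "gene",
                "human_gene",
            ):
                continue  # optional header
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"line {lineno} of {path}: malformed {what} row {line!r}"
                )
            rows.append((fields[0].strip(), fields[1].strip()))
    if not rows:
        raise ValidationError(f"{path}: empty {what} file")
    return rows


def read_phenotype_annotations(path) -> PhenotypeAnnotationTable:
    """Read a two-column TSV ``gene<TAB>phenotype`` (MGD-style).

    Mouse symbols are kept case-sensitive.
    """
    annotations: dict[str, set[str]] = {}
    for gene, phen in _read_two_column_tsv(path, "gene-phenotype"):
        annotations.setdefault(phen, set()).add(gene)
    return PhenotypeAnnotationTable(
        {p: frozenset(g) for p, g in annotations.items()}
    )


def write_phenotype_annotations(table: PhenotypeAnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tphenotype\n")
        for phen in sorted(table.annotations):
            for gene in sorted(table.annotations[phen]):
                fh.write(f"{gene}\t{phen}\n")


def read_homolog_map(path) -> HomologMap:
    """Read a two-column TSV ``human_gene<TAB>mouse_gene``.

    Human symbols are uppercased; mouse symbols kept as-is. Mapping may be
    one-to-many.
    """
    pairs: dict[str, set[str]] = {}
    for human, mouse in _read_two_column_tsv(path, "homolog"):
        pairs.setdefault(human.upper(), set()).add(mouse)
    return HomologMap({h: frozenset(m) for h, m in pairs.items()})


def write_homolog_map(homologs: HomologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("human_gene\tmouse_gene\n")
        for human in sorted(homologs.pairs):
            for mouse in sorted(homologs.pairs[human]):
                fh.write(f"{human}\t{mouse}\n")
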