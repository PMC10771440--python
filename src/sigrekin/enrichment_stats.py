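"""Functional-class overrepresentation tests and regulon set arithmetic.

Gene functional classes are flat labels (the Sanger annotation scheme for
*S. coelicolor*, e.g. "Periplasmic/exported/lipoproteins").  Enrichment of a
class in a gene set against the genome is the upper-tail hypergeometric
probability P(X >= k) for X ~ Hypergeometric(N, K, n); fold enrichment is the
ratio of the in-set fraction to the genome-wide background fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import ParameterError, StructuralError

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnnotationTable:
    """One functional-class label per gene."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> set[str]:
        return set(self.labels.values())

    def class_size(self, cls: str) -> int:
        return sum(1 for v in self.labels.values() if v == cls)

    def label(self, gene_id: str) -> str:
        return self.labels.get(gene_id, UNCLASSIFIED)


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail overrepresentation p-value P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` in-set genes of the class, set size ``n``, class size ``K`` in a
    genome of ``N`` genes.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(k, n, K, N) < 0:
        raise ParameterError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, background_fraction: float) -> float:
    """(k/n) divided by the genome-wide background fraction of the class."""
    if n <= 0:
        raise ParameterError("set size n must be positive")
    if background_fraction <= 0:
        raise ParameterError("background_fraction must be positive")
    return (k / n) / background_fraction


def regulon_overlap(a: GeneSet, b: GeneSet) -> tuple[int, int, int, int]:
    """Set cardinalities (|a|, |b|, |a & b|, |a | b|)."""
    inter = len(a.members & b.members)
    return (len(a), len(b), inter, len(a) + len(b) - inter)


def class_percentages(
    genes: GeneSet, annotations: AnnotationTable, cls: str
) -> tuple[int, int, int]:
    """(k, n, percent) of set members carrying the class label.

    Members absent from the annotation count as unclassified; the percentage
    is rounded half-up to the nearest integer (16/28 -> 57, 6/16 -> 38,
    17/47 -> 36).
    """
    n = len(genes)
    if n == 0:
        raise ParameterError("gene set is empty")
    k = sum(1 for g in genes.members if annotations.label(g) == cls)
    percent = int(100 * k / n + 0.5)
    return k, n, percent


@dataclass(frozen=True)
class EnrichmentRow:
    cls: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p_value: float
    p_adjusted: float | None = None


def enrichment_report(
    genes: GeneSet,
    annotations: AnnotationTable,
    adjust: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of every annotated class in a set.

    The genome universe is the annotation table.  Raw p-values by default
    (matching how such screens are usually reported at p < 0.05);
    ``adjust=True`` adds Benjamini-Hochberg adjusted values.
    """
    N = len(annotations)
    if N == 0:
        raise ParameterError("annotation table is empty")
    in_universe = [g for g in genes.members if g in annotations.labels]
    n = len(in_universe)
    if n == 0:
        raise StructuralError("no gene of the set is in the annotation universe")
    rows = []
    for cls in sorted(annotations.classes):
        K = annotations.class_size(cls)
        k = sum(1 for g in in_universe if annotations.labels[g] == cls)
        fold = fold_enrichment(k, n, K / N) if K else float("nan")
        p = hypergeometric_enrichment(k, n, K, N)
        rows.append(EnrichmentRow(cls, k, n, K, N, fold, p))
    if adjust:
        adj = stats.false_discovery_control([r.p_value for r in rows], method="bh")
        rows = [
            EnrichmentRow(r.cls, r.k, r.n, r.K, r.N, r.fold, r.p_value, float(a))
            for r, a in zip(rows, adj)
        ]
    return rows


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene ID per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        members = {
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        }
    return GeneSet(name or str(path), members)


def write_gene_set(genes: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes.members):
            fh.write(g + "\n")


def read_annotation_tsv(path) -> AnnotationTable:
    """Two-column TSV: gene_id, class (header optional but recommended)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "class"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["gene_id", "class"])
    if df["gene_id"].duplicated().any():
        raise StructuralError("duplicate gene IDs in annotation table")
    return AnnotationTable(dict(zip(df["gene_id"], df["class"])))


def write_annotation_tsv(annotations: AnnotationTable, path) -> None:
    df = pd.DataFrame(
        sorted(annotations.labels.items()), columns=["gene_id", "class"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path) -> None:
    df = pd.DataFrame(
        [
            {
                "class": r.cls, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold": r.fold, "p": r.p_value,
                **({"p_adjusted": r.p_adjusted} if r.p_adjusted is not None else {}),
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
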