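"""Fisher's exact over-representation test against an annotation table.

Each gene-ontology-style term is tested for over-representation of a query
gene list (a kinetic cluster, or the set of cell-composition-driven genes)
against a reference universe — the genes expressed on the array.  One-sided
Fisher's exact p-values are BH-adjusted across tested terms; a term is
reported as enriched when it overlaps the query in at least ``min_genes``
genes and its adjusted p-value is below the FDR threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .differential import adjust

__all__ = ["AnnotationTable", "fisher_pvalue", "fisher_enrichment"]


@dataclass
class AnnotationTable:
    """Term -> gene-set annotation with uppercase-normalized symbols."""

    terms: dict  # term_id -> set of gene symbols
    names: dict  # term_id -> term name

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]], names: Mapping[str, str] | None = None):
        terms = {t: {str(g).upper() for g in genes} for t, genes in mapping.items()}
        terms = {t: g for t, g in terms.items() if g}  # drop empty terms
        names = dict(names or {})
        return cls(terms=terms, names={t: names.get(t, t) for t in terms})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read a long TSV with columns term_id, term_name, gene."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"term_id", "term_name", "gene"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation TSV needs columns {sorted(required)}")
        mapping = df.groupby("term_id")["gene"].apply(set).to_dict()
        names = df.drop_duplicates("term_id").set_index("term_id")["term_name"].to_dict()
        return cls.from_mapping(mapping, names)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"term_id": t, "term_name": self.names[t], "gene": g}
            for t in sorted(self.terms)
            for g in sorted(self.terms[t])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided (over-representation) Fisher p for an overlap of ``k``.

    ``K`` genes of the ``N``-gene reference carry the term and ``n`` were
    queried: the p-value is the hypergeometric probability of an overlap of
    at least ``k``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError("inconsistent 2x2 margins")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    query: Iterable[str],
    reference: Iterable[str],
    annotation: AnnotationTable,
    min_genes: int = 3,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every annotated term for over-representation of ``query``.

    Query genes absent from the reference are dropped with a warning (and
    listed in the returned warnings table).  All terms with at least one
    reference gene are tested and enter the BH family; the ``enriched``
    column additionally requires an overlap of ``min_genes`` and adjusted
    p < ``fdr``.

    Returns (term table with columns term, name, k, K, n, N, p, adj_p,
    enriched, genes) and the dropped-gene warnings table.
    """
    reference = {str(g).upper() for g in reference}
    query_raw = [str(g).upper() for g in query]
    dropped = sorted(set(query_raw) - reference)
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from the reference were dropped"
        )
    query_set = set(query_raw) & reference
    n, N = len(query_set), len(reference)

    records = []
    for term, genes in annotation.terms.items():
        K_set = genes & reference
        if not K_set:
            continue
        overlap = sorted(query_set & K_set)
        k, K = len(overlap), len(K_set)
        records.append(
            {
                "term": term,
                "name": annotation.names[term],
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": fisher_pvalue(k, K, n, N),
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(records)
    if len(table):
        table["adj_p"] = adjust(table["p"].values, "BH")
        table["enriched"] = (table["k"] >= min_genes) & (table["adj_p"] < fdr)
        table = table.sort_values(["adj_p", "p", "term"], kind="stable").reset_index(drop=True)
    warnings_table = pd.DataFrame({"dropped_gene": dropped})
    return table, warnings_table
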