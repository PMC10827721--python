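"""Term overrepresentation for gene sets.

One-sided Fisher's exact test (hypergeometric upper tail) per annotation
term, with fold enrichment ``(k/n) / (K/N)`` and Benjamini-Hochberg
correction across terms — the overrepresentation statistic computed
locally rather than through an annotation web service. Annotations are
read from GMT files (term_id <tab> term_name <tab> gene...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import GeneSet, bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["Annotation", "read_gmt", "fisher_enrichment"]


@dataclass
class Annotation:
    """term_id -> (term_name, gene set), plus the population universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        empty = [t for t, (_, genes) in self.terms.items() if not genes]
        if empty:
            raise ValueError(f"empty annotation terms: {empty[:5]}")
        stray = set().union(*(g for _, g in self.terms.values())) - self.universe
        if stray:
            raise ValueError(f"annotated genes outside universe: {sorted(stray)[:5]}")


def read_gmt(path: str | Path, universe=None) -> Annotation:
    """Parse a GMT file. If ``universe`` is None it defaults to the union
    of all annotated genes; with an explicit universe, term gene sets
    are intersected with it."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need id, name, >=1 gene): {line[:60]!r}")
        term_id, name, genes = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
        if universe is not None:
            genes = genes & frozenset(universe)
        if genes:
            terms[term_id] = (name, genes)
    uni = frozenset(universe) if universe is not None else frozenset().union(
        *(g for _, g in terms.values())
    )
    return Annotation(terms=terms, universe=uni)


def fisher_enrichment(
    study: GeneSet | set, annotation: Annotation, two_sided: bool = False
) -> pd.DataFrame:
    """Per-term overrepresentation of a study set in the population.

    For a term with K annotated genes in the universe of N, and k hits
    among the n study genes, the one-sided p is
    ``P[X >= k], X ~ Hypergeometric(N, K, n)``; fold enrichment is
    ``(k/n) / (K/N)``. Terms absent from the universe (K = 0) are
    skipped with a log message. BH q-values are computed across the
    tested terms. ``two_sided=True`` switches to the two-sided Fisher
    exact p.
    """
    study_genes = frozenset(study.genes if isinstance(study, GeneSet) else study)
    if not study_genes:
        raise ValueError("empty study set")
    outside = study_genes - annotation.universe
    if outside:
        raise ValueError(f"study genes outside universe: {sorted(outside)[:10]}")
    n = len(study_genes)
    n_pop = len(annotation.universe)
    rows = []
    for term_id, (name, genes) in sorted(annotation.terms.items()):
        k_pop = len(genes)
        if k_pop == 0:
            logger.info("skipping term %s: no annotated genes in universe", term_id)
            continue
        k = len(study_genes & genes)
        fold = (k / n) / (k_pop / n_pop)
        if two_sided:
            table = [[k, n - k], [k_pop - k, n_pop - k_pop - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, n_pop, k_pop, n))
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "k": k,
                "n": n,
                "K": k_pop,
                "N": n_pop,
                "fold_enrichment": fold,
                "pvalue": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "n", "K", "N", "fold_enrichment", "pvalue"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
        table = table.sort_values(["pvalue", "term_id"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = []
    return table
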