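"""Low/high-CpG classification and GO-term enrichment between the classes.

Genes are split at the density-intersection threshold x* (ties classify
as "low"). For every GO term present in the annotation, a 2x2 table of
(annotated vs not) x (low vs high class) is tested with Fisher's exact
test (two-sided, minimum-likelihood convention) and the false discovery
rate is controlled at q < alpha by Benjamini-Hochberg, separately within
each ontology category (BP, CC, MF). The universe of each category is
all classified genes — genes with no term in a category count in the
"not annotated" cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cpgoe.seqio import GO_CATEGORIES


@dataclass(frozen=True)
class ClassifiedGene:
    gene_id: str
    oe: float
    cls: str  # "low" | "high"


@dataclass(frozen=True)
class EnrichmentRow:
    """One GO term's 2x2 association with the low/high classes.

    a: low-class genes carrying the term, b: high-class genes carrying it,
    c/d: the remaining low/high genes. q is BH-adjusted within the term's
    ontology category.
    """

    go_id: str
    category: str
    a: int
    b: int
    c: int
    d: int
    p: float
    q: float
    enriched_in: str  # "low" | "high" | "none"
    significant: bool


def classify(oe_rows: pd.DataFrame, x_star: float) -> list[ClassifiedGene]:
    """Partition genes into low (oe <= x*) and high (oe > x*) classes.

    Expects columns gene_id and oe; every oe must be defined (finite).
    """
    oe = oe_rows["oe"].to_numpy(dtype=float)
    if not np.all(np.isfinite(oe)):
        raise ValueError("classify requires defined (finite) oe for every row")
    return [
        ClassifiedGene(gene_id=g, oe=float(v), cls="low" if v <= x_star else "high")
        for g, v in zip(oe_rows["gene_id"], oe)
    ]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of m * p_(j) / j with ranks over the sorted
    p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich(
    classified: Iterable[ClassifiedGene],
    annotations: Mapping[str, Iterable[tuple[str, str]]],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """GO-term enrichment between the low and high classes.

    ``annotations`` maps gene_id to an iterable of (go_id, category)
    pairs; classified genes missing from the mapping carry no terms. BH
    correction runs separately within each category; rows with q < alpha
    are flagged significant with the side holding the larger annotated
    fraction.
    """
    classified = list(classified)
    n_low = sum(1 for g in classified if g.cls == "low")
    n_high = len(classified) - n_low

    term_counts: dict[tuple[str, str], list[int]] = {}
    for gene in classified:
        for go_id, category in annotations.get(gene.gene_id, ()):
            if category not in GO_CATEGORIES:
                raise ValueError(f"unknown GO category {category!r} for {go_id}")
            counts = term_counts.setdefault((go_id, category), [0, 0])
            counts[0 if gene.cls == "low" else 1] += 1

    partial = []
    for (go_id, category), (a, b) in sorted(term_counts.items()):
        c, d = n_low - a, n_high - b
        p = fisher_two_sided(a, b, c, d)
        rate_low = a / (a + c) if (a + c) else 0.0
        rate_high = b / (b + d) if (b + d) else 0.0
        if rate_low > rate_high:
            side = "low"
        elif rate_high > rate_low:
            side = "high"
        else:
            side = "none"
        partial.append((go_id, category, a, b, c, d, p, side))

    rows: list[EnrichmentRow] = []
    for category in sorted(GO_CATEGORIES):
        in_cat = [t for t in partial if t[1] == category]
        if not in_cat:
            continue
        qs = bh_adjust([t[6] for t in in_cat])
        for (go_id, cat, a, b, c, d, p, side), q in zip(in_cat, qs):
            rows.append(
                EnrichmentRow(
                    go_id=go_id,
                    category=cat,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    p=p,
                    q=q,
                    enriched_in=side,
                    significant=bool(q < alpha and side != "none"),
                )
            )
    return rows


def enrichment_table(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.go_id, r.category, r.a, r.b, r.c, r.d, r.p, r.q, r.enriched_in, r.significant)
            for r in rows
        ],
        columns=["go_id", "category", "a", "b", "c", "d", "p", "q", "enriched_in", "significant"],
    )
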