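"""Annotation-repeat GO term enrichment.

Statistics are computed over annotation *repeats* (one gene–term pair is
one repeat), not distinct genes.  For a term with ``m`` repeats genome-wide,
``k`` repeats among the queried genes, ``Q`` total repeats across the
queried genes and ``G`` total repeats genome-wide:

    expected = m * Q / G
    fold     = k / expected
    p        = P(X >= k),  X ~ Hypergeometric(population G, successes m,
                                              draws Q)

Terms are reported as enriched when p ≤ p_max (default 0.05) and
fold ≥ fold_min (default 2).  No multiple-testing correction is applied;
the p column is labelled "raw hypergeometric p".  A gene-based population
(distinct genes rather than repeats) is available via ``population="genes"``
in :func:`enrich_terms`.

Computation is at full precision; :func:`round_half_up` is for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .data_io import AnnotationTable, ValidationError


@dataclass
class TermEnrichment:
    term_id: str
    term_label: str
    m: int          # genome-wide repeats of the term
    k: int          # repeats observed among the queried genes
    Q: int          # total repeats across the queried genes
    G: int          # total repeats genome-wide
    expected: float
    fold: float
    p_value: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for report display (13.395 → 13.40)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def count_repeats(annotations: AnnotationTable,
                  query_genes: Iterable[str]
                  ) -> tuple[pd.DataFrame, int, int]:
    """Per-term genome (m) and query (k) repeat counts, plus Q and G.

    Query genes absent from the annotation table contribute zero repeats.
    Returns (per-term frame with columns term_id/term_label/m/k, Q, G).
    """
    query = set(query_genes)
    if not query:
        raise ValidationError("empty query gene set")
    pairs = annotations.pairs
    per_term = (pairs.groupby(["term_id"], sort=True)
                .agg(term_label=("term_label", "first"),
                     m=("gene_id", "size"))
                .reset_index())
    in_query = pairs[pairs["gene_id"].isin(query)]
    k_counts = in_query.groupby("term_id").size()
    per_term["k"] = per_term["term_id"].map(k_counts).fillna(0).astype(int)
    Q = int(per_term["k"].sum())
    return per_term, Q, annotations.genome_total_repeats


def expected_count(m: int, Q: int, G: int) -> float:
    """Expected repeats of a term among the query under proportional
    sampling: m·Q/G, unrounded."""
    if G <= 0:
        raise ValidationError("G must be positive")
    return m * Q / G


def fold_enrichment(k: int, expected: float) -> float:
    """Observed over expected repeats, using the unrounded expectation.

    expected = 0 with k > 0 → +inf sentinel; expected = 0 with k = 0 → nan.
    """
    if expected < 0:
        raise ValidationError("expected must be ≥ 0")
    if expected == 0:
        return math.inf if k > 0 else math.nan
    return k / expected


def hypergeometric_pvalue(k: int, m: int, Q: int, G: int) -> float:
    """Upper-tail P(X ≥ k), X ~ Hypergeometric(G, m, Q)."""
    if not (0 <= k <= min(m, Q)) or m > G or Q > G or min(k, m, Q) < 0:
        raise ValidationError(
            f"inconsistent counts k={k}, m={m}, Q={Q}, G={G}")
    return float(hypergeom.sf(k - 1, G, m, Q))


def enrich_terms(annotations: AnnotationTable,
                 query_genes: Iterable[str],
                 population: str = "repeats") -> list[TermEnrichment]:
    """Full per-term enrichment for the queried genes.

    ``population="repeats"`` (default) parameterizes everything over
    annotation repeats.  ``population="genes"`` instead uses distinct genes
    (m = genes carrying the term in the table, Q = annotated query genes,
    G = annotated genes in the table); expected/fold follow the same m·Q/G
    form on those counts.
    """
    if population not in {"repeats", "genes"}:
        raise ValidationError(f"unknown population {population!r}")
    query = set(query_genes)
    if population == "repeats":
        per_term, Q, G = count_repeats(annotations, query)
        rows = list(per_term.itertuples(index=False))
        counts = [(r.term_id, r.term_label, int(r.m), int(r.k))
                  for r in rows]
    else:
        pairs = annotations.pairs
        G = int(pairs["gene_id"].nunique())
        annotated_query = set(pairs["gene_id"]) & query
        Q = len(annotated_query)
        if not query:
            raise ValidationError("empty query gene set")
        grouped = pairs.groupby("term_id")
        counts = []
        for term_id, grp in grouped:
            genes = set(grp["gene_id"])
            counts.append((term_id, grp["term_label"].iloc[0],
                           len(genes), len(genes & annotated_query)))
    out = []
    for term_id, label, m, k in counts:
        e = expected_count(m, Q, G)
        out.append(TermEnrichment(
            term_id=term_id, term_label=label, m=m, k=k, Q=Q, G=G,
            expected=e, fold=fold_enrichment(k, e),
            p_value=hypergeometric_pvalue(k, m, Q, G)))
    return out


def enrich_select(results: Sequence[TermEnrichment],
                  p_max: float = 0.05,
                  fold_min: float = 2.0) -> list[TermEnrichment]:
    """Terms with p ≤ p_max and fold ≥ fold_min (both inclusive), sorted by
    fold descending, ties by term id."""
    kept = [r for r in results if r.p_value <= p_max and r.fold >= fold_min]
    return sorted(kept, key=lambda r: (-r.fold, r.term_id))


def write_enrichment_report(results: Sequence[TermEnrichment],
                            path: str | Path) -> None:
    """Tab-separated report; expected and fold are shown at 2 dp (half-up),
    the p column is raw (no multiple-testing correction)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tterm_label\tgenome_repeats\tquery_repeats\t"
                 "expected\tfold_enrichment\traw hypergeometric p\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.term_label}\t{r.m}\t{r.k}\t"
                     f"{round_half_up(r.expected):.2f}\t"
                     f"{round_half_up(r.fold):.2f}\t{r.p_value:.4g}\n")
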