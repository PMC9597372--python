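"""Over-representation analysis of PLM-containing gene sets.

Flat gene -> term tables (no ontology propagation) are tested with a
one-sided hypergeometric test per term, P(X >= k), against a reference
list — by convention all genes retained for detection on the same side.
P-values are Benjamini-Hochberg adjusted; a term is enriched when its
adjusted p-value is below alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """term_id -> gene set, with optional labels and a namespace tag."""

    terms: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespace: str = ""

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items() if g}

    @classmethod
    def from_table(cls, table: pd.DataFrame, namespace: str = "") -> "AnnotationMap":
        """Build from a long table with gene_id / term_id (/ term_label) columns."""
        terms: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        for row in table.itertuples(index=False):
            terms.setdefault(row.term_id, set()).add(row.gene_id)
            if hasattr(row, "term_label"):
                labels[row.term_id] = row.term_label
        return cls(terms={t: frozenset(g) for t, g in terms.items()},
                   labels=labels, namespace=namespace)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int          # set genes carrying the term
    n: int          # set size (within reference)
    K: int          # reference genes carrying the term
    N: int          # reference size
    p_value: float
    adjusted_p: float = float("nan")
    label: str = ""


def hypergeometric_overrep(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_set(
    gene_set,
    annotation: AnnotationMap,
    reference,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One hypergeometric test per term; results sorted by (adjusted_p, term_id).

    Genes outside the reference are ignored on both sides of the test.
    """
    reference = frozenset(reference)
    genes = frozenset(gene_set) & reference
    N, n = len(reference), len(genes)
    raw = []
    for term_id in sorted(annotation.terms):
        members = annotation.terms[term_id] & reference
        K = len(members)
        if K == 0:
            continue
        k = len(members & genes)
        raw.append((term_id, k, K, hypergeometric_overrep(k, n, K, N)))
    adjusted = bh_adjust([p for *_, p in raw])
    results = [
        EnrichmentResult(term_id=t, k=k, n=n, K=K, N=N, p_value=p,
                         adjusted_p=float(q),
                         label=annotation.labels.get(t, ""))
        for (t, k, K, p), q in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term_id))
    return results


def significant_terms(results, alpha: float = 0.05) -> set[str]:
    return {r.term_id for r in results if r.adjusted_p < alpha}


def specific_terms(results_by_class: dict[str, list[EnrichmentResult]],
                   alpha: float = 0.05) -> dict[str, set[str]]:
    """Terms significant for exactly one class of gene sets (set difference)."""
    sig = {c: significant_terms(r, alpha) for c, r in results_by_class.items()}
    return {
        c: terms - set().union(*(sig[o] for o in sig if o != c))
        if len(sig) > 1 else terms
        for c, terms in sig.items()
    }


def enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "label": [r.label for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
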