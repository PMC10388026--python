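"""Over-representation analysis of gene lists against term-gene mappings.

One-sided hypergeometric upper-tail test per term (the standard ORA choice),
Benjamini-Hochberg FDR across tested terms.  Term-gene maps come from GMT
files or 2-column TSVs, so analyses are hermetic — no web service is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .io_formats import canonical

log = logging.getLogger(__name__)


@dataclass
class TermGeneMap:
    """term id -> member genes, plus the background universe.

    Every member gene is in the background; empty terms are dropped.
    """

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        cleaned = {}
        for term, members in self.terms.items():
            members = frozenset(members) & self.background
            if members:
                cleaned[term] = members
        self.terms = cleaned

    @classmethod
    def from_memberships(cls, terms: dict[str, set[str]], background=None) -> "TermGeneMap":
        terms = {t: frozenset(canonical(g) for g in gs) for t, gs in terms.items()}
        if background is None:
            background = frozenset().union(*terms.values()) if terms else frozenset()
        else:
            background = frozenset(canonical(g) for g in background)
        return cls(terms=terms, background=background)

    @classmethod
    def from_gmt(cls, path, background=None) -> "TermGeneMap":
        terms: dict[str, set[str]] = {}
        with open(Path(path)) as fh:
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 3:
                    continue
                terms[cols[0]] = {g for g in cols[2:] if g.strip()}
        return cls.from_memberships(terms, background)

    @classmethod
    def from_tsv(cls, path, background=None) -> "TermGeneMap":
        """2-column TSV: term <tab> gene (one membership per line)."""
        terms: dict[str, set[str]] = {}
        with open(Path(path)) as fh:
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                    continue
                terms.setdefault(cols[0].strip(), set()).add(cols[1])
        return cls.from_memberships(terms, background)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                genes = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\tna\t{genes}\n")


def hypergeometric_test(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= x <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} x={x}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(query_genes, term_map: TermGeneMap, alpha: float = 0.05) -> pd.DataFrame:
    """ORA of a gene list against the map; rows sorted by adjusted p.

    Query genes outside the background are dropped with a warning.  Only terms
    overlapping the query are tested; BH adjustment runs across those tests.
    """
    query = {canonical(g) for g in query_genes}
    outside = query - term_map.background
    if outside:
        log.warning("enrich: %d query genes outside the background dropped", len(outside))
        query &= term_map.background
    if not query:
        raise ValueError("query is empty after background filtering")
    N = len(term_map.background)
    n = len(query)
    rows = []
    for term in sorted(term_map.terms):
        members = term_map.terms[term]
        overlap = members & query
        if not overlap:
            continue
        K = len(members)
        x = len(overlap)
        rows.append(
            {
                "term": term,
                "n_background": N,
                "n_term": K,
                "n_query": n,
                "n_overlap": x,
                "p_raw": hypergeometric_test(N, K, n, x),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term", "n_background", "n_term", "n_query", "n_overlap",
            "p_raw", "overlap_genes",
        ],
    )
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
        result["is_significant"] = result["p_adj"] < alpha
        result = result.sort_values(
            ["p_adj", "p_raw", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["is_significant"] = []
    return result
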