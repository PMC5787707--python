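"""Over-representation of annotation terms among hit genes.

For a term with K annotated genes in a screened-library universe of size N,
and k annotated among the n hit genes, the enrichment p-value is the
hypergeometric upper tail P(X >= k). Benjamini-Hochberg-adjusted p-values
are reported alongside the raw ones.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (term_id, gene) delimited file into term -> gene set."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        out[str(term)] = set(sub["gene"])
    return out


def gmt_to_annotations(path) -> dict[str, set[str]]:
    """Convert GMT-style gene sets (term, description, genes...) to term -> set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def hypergeom_enrichment(
    hits: Set[str] | Iterable[str],
    universe: Set[str] | Iterable[str],
    annotations: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation test.

    Returns a table with k, K, n, N, the enrichment ratio (k/n)/(K/N),
    p_raw = P(X >= k) and BH-adjusted p. Terms with no annotated gene in
    the universe are skipped. Hits must be a subset of the universe.
    """
    hits = set(hits)
    universe = set(universe)
    offenders = sorted(hits - universe)
    if offenders:
        raise ValueError(f"hit genes absent from the universe: {offenders}")
    N, n = len(universe), len(hits)
    rows = []
    for term, genes in sorted(annotations.items()):
        K = len(genes & universe)
        if K == 0:
            continue
        k = len(genes & hits)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        ratio = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "enrichment_ratio": ratio, "p_raw": p_raw})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "enrichment_ratio", "p_raw"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
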