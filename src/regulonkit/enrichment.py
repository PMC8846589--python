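"""Set-overrepresentation testing: one-sided hypergeometric p-values with
Benjamini-Hochberg adjustment, for annotating gene sets against term
memberships.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TermMembership",
    "read_term_tsv",
    "hypergeom_overrep",
    "bh_adjust",
    "enrich",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class TermMembership:
    term_id: str
    member_genes: frozenset[str]
    term_name: str = ""


def read_term_tsv(
    path: str | Path, name_map: dict[str, str] | None = None
) -> list[TermMembership]:
    """Read 2-column TSV (term_id, gene_id) into term memberships."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], dtype=str)
    terms = []
    for term_id, grp in df.groupby("term_id", sort=True):
        terms.append(
            TermMembership(
                term_id=str(term_id),
                member_genes=frozenset(grp["gene_id"]),
                term_name=(name_map or {}).get(str(term_id), ""),
            )
        )
    return terms


def hypergeom_overrep(
    selected: set[str], term: TermMembership, universe: set[str]
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    k = |selected ∩ members|, K = |members ∩ universe|, n = |selected|,
    N = |universe|.  Term members are intersected with the universe before
    testing; ``selected`` must be a subset of the universe.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    members = term.member_genes & universe
    k = len(selected & members)
    K = len(members)
    n = len(selected)
    N = len(universe)
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Adjusted values are >= the raw ones, capped at 1, and monotone
    non-decreasing when sorted by raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def enrich(
    selected: set[str],
    terms: Sequence[TermMembership],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every term; return a table sorted by adjusted then raw p-value.

    Columns: term_id, term_name, k, K, n, N, p, padj, significant (padj < alpha).
    """
    rows = []
    for t in terms:
        members = t.member_genes & universe
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "k": len(selected & members),
                "K": len(members),
                "n": len(selected),
                "N": len(universe),
                "p": hypergeom_overrep(selected, t, universe),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["padj"] = bh_adjust(df["p"].tolist())
        df["significant"] = df["padj"] < alpha
        df = df.sort_values(["padj", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["padj"] = []
        df["significant"] = []
    return df


def write_enrichment_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
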