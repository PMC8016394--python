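"""Over-representation analysis of gene lists against GMT gene-set collections.

A generic hypergeometric ORA standing in for pathway (e.g. KEGG)
enrichment: the statistical core is shared with the PPI neighborhood
screen (:func:`coexpnet.netops.fisher_upper_tail`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from coexpnet.netops import bh_fdr, fisher_upper_tail

__all__ = ["GeneSetCollection", "read_gmt", "ora_test"]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (uppercased symbols) with an optional universe."""

    sets: dict[str, set]
    source: str = ""
    universe: set | None = None

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, member symbols...).

    Symbols are uppercased and duplicates within a set collapse.  Lines
    with fewer than three fields are logged and skipped.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                log.warning("skipping GMT line %d with %d fields", lineno, len(parts))
                continue
            name = parts[0].strip()
            members = {m.strip().upper() for m in parts[2:] if m.strip()}
            if not members:
                log.warning("skipping empty GMT set %r on line %d", name, lineno)
                continue
            sets[name] = members
    if not sets:
        log.warning("GMT file %s produced an empty collection", path)
    return GeneSetCollection(sets=sets, source=str(path))


def ora_test(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    For each set: ``N = |universe|``, ``K = |set & universe|``,
    ``n = |query & universe|``, overlap ``a``; p is the hypergeometric
    upper tail and q the BH adjustment across all sets.  Query genes
    outside the universe are dropped with a warning.  Rows are sorted by
    p then set name, so results are invariant to set ordering in the
    source file.
    """
    universe = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in query}
    outside = query - universe
    if outside:
        log.warning("%d query genes outside the universe were dropped", len(outside))
    query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        K = len(members)
        overlap = sorted(query & members)
        a = len(overlap)
        p = fisher_upper_tail(a, n - a, K, N) if K else 1.0
        rows.append({"set": name, "overlap": a, "set_size": K,
                     "gene_ratio": a / n, "p": p, "genes": "/".join(overlap)})
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return result
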