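"""Generic over-representation analysis of candidate sets against GMT gene sets.

One-sided hypergeometric tail P(X >= overlap) per gene set, with
Benjamini-Hochberg adjustment across the tested sets.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "ora_enrichment"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def ora_enrichment(
    candidates,
    gene_sets: dict[str, list[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``candidates`` in each gene set.

    All sets are intersected with the universe first; empty sets are skipped
    with a warning. Returns a table sorted by p-value with columns
    (set, set_size, overlap, expected, p, p_adjusted).
    """
    universe = set(universe)
    candidates = set(candidates)
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    N, n = len(universe), len(candidates)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"gene set {name!r} has no members in the universe", stacklevel=2)
            continue
        K = len(in_universe)
        overlap = len(in_universe & candidates)
        p = float(hypergeom.sf(overlap - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": overlap,
                "expected": n * K / N,
                "p": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "expected", "p"])
    if table.empty:
        table["p_adjusted"] = []
        return table
    table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values("p").reset_index(drop=True)
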