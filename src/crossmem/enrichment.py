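"""Gene-set overrepresentation by the hypergeometric upper tail.

Hit lists from the co-expression screen are tested against a GMT-backed
gene-set collection: with a universe of N genes of which K belong to the
set and a hit list of n genes overlapping the set in k, the p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n), BH-adjusted across sets.
Symbols are harmonized upper-case before any counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .de import bh_fdr

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "enrichment_test"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def harmonized(self) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: {g.upper() for g in s} for n, s in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-delimited: name, description, members...).

    Raises ``ValueError`` naming the line number for lines with fewer than
    3 fields or duplicated set names.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set name {name!r}")
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def enrichment_test(
    hit_genes: list[str] | set[str],
    gene_sets: GeneSetCollection,
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of hits in each set.

    Hits and sets are intersected with the universe (upper-cased) before
    counting. Returns a DataFrame sorted by ascending p with columns
    ``k`` (overlap), ``K`` (set size in universe), ``n`` (hits), ``N``
    (universe), ``p``, ``q`` (BH across sets) and ``overlap_genes``.
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    hits = {str(g).upper() for g in hit_genes} & uni
    harmonized = gene_sets.harmonized()
    n, big_n = len(hits), len(uni)
    rows = []
    for name, members in harmonized.sets.items():
        in_uni = members & uni
        if not in_uni:
            continue
        overlap = sorted(in_uni & hits)
        k, big_k = len(overlap), len(in_uni)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "set": name,
                "description": gene_sets.descriptions.get(name, ""),
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["description", "k", "K", "n", "N", "p", "overlap_genes"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable")
    else:
        out["q"] = pd.Series(dtype=float)
    return out
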