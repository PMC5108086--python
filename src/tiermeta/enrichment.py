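"""Tier 2: hypergeometric over-representation of disease genes in pathways.

For a disease with ``n`` significant genes out of a universe of ``N``
measured genes, a pathway covering ``K`` universe genes and overlapping
``k`` significant genes is scored by the upper hypergeometric tail
``P(X >= k)`` — the probability of seeing ``k`` or more significant genes
in the pathway by chance.  The universe is the set of genes that received a
combined p-value in the disease (what was testable), not the collection's
own gene union.
"""

from __future__ import annotations

import fnmatch
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["pathway", "disease_id", "N", "K", "n", "k", "p", "overlap_genes"]


def filter_collection(
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 300,
    exclude: Sequence[str] = (),
) -> GeneSetCollection:
    """Drop too-small (< min_size) and too-large (> max_size) gene sets.

    Sizes are measured within the collection, mirroring how pathway
    databases are pruned before any study-specific universe intersection.
    ``exclude`` holds shell-style name patterns (e.g. ``"*DISEASE*"``) for
    removing unwanted set families.
    """
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    for name, (desc, genes) in collection.sets.items():
        if not (min_size <= len(genes) <= max_size):
            continue
        if any(fnmatch.fnmatch(name, pat) for pat in exclude):
            continue
        kept[name] = (desc, genes)
    if not kept:
        raise ValueError("no gene sets remain after filtering")
    dropped = len(collection) - len(kept)
    if dropped:
        logger.info("filter_collection: removed %d of %d sets", dropped, len(collection))
    return GeneSetCollection(sets=kept)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``N`` universe genes, ``K`` of them in the pathway, ``n`` drawn
    (significant), ``k`` observed in the overlap.  ``k = 0`` gives 1 by
    convention.
    """
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_disease(
    sig_genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    disease_id: str = "",
) -> pd.DataFrame:
    """One hypergeometric test per pathway for one disease.

    ``sig_genes`` must be a subset of ``universe``.  Pathway size ``K`` and
    overlap ``k`` are computed after intersecting with the universe;
    pathways disjoint from the universe are reported with ``K = 0`` and
    ``p = 1`` (the no-overlap convention).
    """
    universe = frozenset(universe)
    sig = frozenset(sig_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not sig <= universe:
        stray = sorted(sig - universe)
        raise ValueError(f"significant genes outside the universe: {stray[:5]}")
    N, n = len(universe), len(sig)
    rows = []
    overlaps = []
    for name in collection.names:
        members = collection.genes(name) & universe
        hit = members & sig
        rows.append((name, len(members), len(hit)))
        overlaps.append(",".join(sorted(hit)))
    df = pd.DataFrame(rows, columns=["pathway", "K", "k"])
    # vectorized tail; sf(-1) = 1 covers the k = 0 convention
    p = stats.hypergeom.sf(df["k"].to_numpy() - 1, N, df["K"].to_numpy(), n)
    df["p"] = np.clip(np.where(df["k"] == 0, 1.0, p), 0.0, 1.0)
    df["N"] = N
    df["n"] = n
    df["disease_id"] = disease_id
    df["overlap_genes"] = overlaps
    return df[ENRICH_COLUMNS]
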