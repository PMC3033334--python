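"""Hypergeometric enrichment and depletion of gene sets.

For a cluster of n genes drawn from an annotated universe of N genes, and
a category with m members in that universe, the overlap k is referred to
the hypergeometric(N, m, n) distribution:

    expected = m * n / N
    p_enrich = P(X >= k)      (upper tail, one-sided)
    p_deplete = P(X <= k)     (lower tail, one-sided)

A category is flagged enriched when p_enrich < p_cutoff AND k >= min_observed
(default: p < 0.001 and observed > 3); depleted when p_deplete < p_cutoff.
No multiple-testing correction enters the flags — the observed-count floor
plays that role — but a Benjamini-Hochberg column is emitted alongside for
diagnostics.  External gene lists (e.g. stem-cell signatures, tumor gene
sets in another species) use the same machinery after optional ortholog
translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats as _sps

from .io import GeneSetCollection, PairTable

logger = logging.getLogger(__name__)

__all__ = ["EnrichConfig", "hypergeom_tail", "enrich", "list_overlap"]


@dataclass(frozen=True)
class EnrichConfig:
    p_cutoff: float = 0.001
    min_observed: int = 4  # "observed > 3"
    universe_mode: str = "annotated_only"  # or "full_array"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.universe_mode not in ("annotated_only", "full_array"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")


def hypergeom_tail(N: int, m: int, n: int, k: int, tail: str = "upper") -> float:
    """Exact one-sided tail of the hypergeometric(N, m, n) distribution.

    upper: P(X >= k); lower: P(X <= k); computed via scipy's log-space
    survival/cdf machinery.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got N={N}, m={m}, n={n}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"need 0 <= k <= min(m, n); got k={k}")
    dist = _sps.hypergeom(N, m, n)
    if tail == "upper":
        return float(min(1.0, dist.sf(k - 1)))
    if tail == "lower":
        return float(min(1.0, dist.cdf(k)))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def _one_result(
    cluster_name: str,
    category_name: str,
    cluster: frozenset[str],
    category: frozenset[str],
    universe: frozenset[str],
    cfg: EnrichConfig,
) -> dict:
    N = len(universe)
    m = len(category & universe)
    n = len(cluster & universe)
    k = len(cluster & category & universe)
    expected = m * n / N if N else 0.0
    p_en = hypergeom_tail(N, m, n, k, "upper")
    p_de = hypergeom_tail(N, m, n, k, "lower")
    if p_en < cfg.p_cutoff and k >= cfg.min_observed:
        flag = "enriched"
    elif p_de < cfg.p_cutoff:
        flag = "depleted"
    else:
        flag = "none"
    return {
        "cluster": cluster_name,
        "category": category_name,
        "N": N,
        "m": m,
        "n": n,
        "observed": k,
        "expected": expected,
        "p_enrich": p_en,
        "p_deplete": p_de,
        "flag": flag,
    }


def _with_bh(df: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted enrichment p-values (diagnostic only)."""
    df = df.copy()
    df["bh_enrich"] = _sps.false_discovery_control(df["p_enrich"], method="bh")
    return df


def enrich(
    clusters: GeneSetCollection | dict[str, frozenset[str]],
    categories: GeneSetCollection,
    universe: frozenset[str] | None = None,
    cfg: EnrichConfig | None = None,
) -> pd.DataFrame:
    """Enrichment/depletion of every (cluster, category) pair.

    With ``universe_mode="annotated_only"`` (default) the universe is the
    union of category members, matching the convention of scoring against
    the annotated portion of the array; ``full_array`` requires an explicit
    universe.  Cluster genes outside the universe are dropped with a logged
    count.
    """
    cfg = cfg or EnrichConfig()
    cluster_map = clusters.sets if isinstance(clusters, GeneSetCollection) else dict(clusters)
    if cfg.universe_mode == "annotated_only":
        universe = frozenset().union(*categories.sets.values()) if categories.sets else frozenset()
    elif universe is None:
        universe = categories.universe
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for cname in sorted(cluster_map):
        cset = frozenset(map(str, cluster_map[cname]))
        outside = len(cset - universe)
        if outside:
            logger.info("cluster %s: %d genes outside universe dropped", cname, outside)
        for cat in categories.names():
            rows.append(_one_result(cname, cat, cset, categories[cat], universe, cfg))
    return _with_bh(pd.DataFrame.from_records(rows))


def list_overlap(
    clusters: GeneSetCollection | dict[str, frozenset[str]],
    external_lists: GeneSetCollection,
    universe: frozenset[str],
    ortholog_map: PairTable | None = None,
    cfg: EnrichConfig | None = None,
) -> pd.DataFrame:
    """Overlap significance of clusters against external gene lists.

    When an ortholog map is supplied (rows = (internal_id, external_id)),
    external identifiers are translated onto the internal namespace before
    intersecting; a many-to-many map counts each internal gene once, and
    untranslatable identifiers are counted in the ``untranslated`` column.
    Observed and expected overlaps are reported in the "64 observed versus
    17 expected" style (k and m*n/N).
    """
    cfg = cfg or EnrichConfig()
    cluster_map = clusters.sets if isinstance(clusters, GeneSetCollection) else dict(clusters)
    if not universe:
        raise ValueError("empty universe")
    back = ortholog_map.mapping(reverse=True) if ortholog_map is not None else None
    rows = []
    for lname in external_lists.names():
        ext = external_lists[lname]
        untranslated = 0
        if back is not None:
            translated: set[str] = set()
            for ident in ext:
                partners = back.get(ident)
                if partners:
                    translated |= partners
                else:
                    untranslated += 1
            ext = frozenset(translated)
        for cname in sorted(cluster_map):
            cset = frozenset(map(str, cluster_map[cname]))
            row = _one_result(cname, lname, cset, ext, universe, cfg)
            row["untranslated"] = untranslated
            rows.append(row)
    return _with_bh(pd.DataFrame.from_records(rows))
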