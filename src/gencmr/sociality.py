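"""Spatial-association social networks from co-deposited dung samples.

Two individuals are associated when any pair of their samples was
collected on the same day, within a chosen radius of one another, and
judged to be of the same deposition age (freshness class). Association is
evidence of group co-membership, so a single qualifying co-deposition
creates an (unweighted) edge; edges carry pairwise genetic relatedness as
weight and a kinship-order class for styling. Individuals never found in
association are excluded from the network, and the network's connected
components are the inferred social units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .identify import Individual


def find_associations(
    individuals: Sequence[Individual],
    radius: float,
    require_same_day: bool = True,
    require_same_freshness: bool = True,
    exclude_freshness: frozenset[str] = frozenset({"aged"}),
) -> set[tuple[str, str]]:
    """Pairs of individuals with at least one qualifying sample co-deposition.

    Samples carrying a freshness class in ``exclude_freshness`` (visibly
    older or younger than the surrounding deposits) are dropped before
    pairing. Distance is Euclidean in meters.
    """
    pairs: set[tuple[str, str]] = set()
    flat = [
        (ind.individual_id, s)
        for ind in individuals
        for s in ind.samples
        if s.freshness_class not in exclude_freshness
    ]
    for i in range(len(flat)):
        id1, s1 = flat[i]
        for j in range(i + 1, len(flat)):
            id2, s2 = flat[j]
            if id1 == id2:
                continue
            if require_same_day and s1.date != s2.date:
                continue
            if require_same_freshness and s1.freshness_class != s2.freshness_class:
                continue
            if math.hypot(s1.x - s2.x, s1.y - s2.y) <= radius:
                pairs.add(tuple(sorted((id1, id2))))
    return pairs


def build_network(
    associations: Iterable[tuple[str, str]],
    individuals: Sequence[Individual],
    relatedness: Mapping[tuple[str, str], float] | None = None,
    kinship_order: Mapping[tuple[str, str], str] | None = None,
    include_males: bool = True,
    include_unknown_sex: bool = True,
    radius: float | None = None,
) -> nx.Graph:
    """Social network over associated individuals.

    Vertices carry sex and haplotype attributes; edges carry relatedness
    (``r``) and kinship-order (``order``) attributes. Excluding males (or
    unknown-sex individuals) drops those vertices and their incident
    edges; isolated vertices are always removed.
    """
    by_id = {ind.individual_id: ind for ind in individuals}
    g = nx.Graph(radius=radius, includes_males=include_males)
    for a, b in associations:
        if a == b:
            continue
        ia, ib = by_id[a], by_id[b]
        keep = True
        for ind in (ia, ib):
            if not include_males and ind.sex == "male":
                keep = False
            if not include_unknown_sex and ind.sex == "unknown":
                keep = False
        if not keep:
            continue
        key = tuple(sorted((a, b)))
        r = relatedness.get(key) if relatedness else None
        order = kinship_order.get(key) if kinship_order else None
        g.add_edge(a, b, r=r if r is not None else float("nan"), order=order or "none")
    for node in g.nodes:
        ind = by_id[node]
        g.nodes[node]["sex"] = ind.sex
        g.nodes[node]["haplotype"] = ind.haplotype or ""
    return g


@dataclass
class ComponentSummary:
    members: list[str]
    size: int
    n_female: int
    n_male: int
    n_unknown: int
    female_haplotypes: set[str] = field(default_factory=set)
    has_unhaplotyped_female: bool = False

    @property
    def multi_female(self) -> bool:
        return self.n_female > 1

    @property
    def assessable(self) -> bool:
        """Haplotype composition can be judged only if every female is typed."""
        return self.multi_female and not self.has_unhaplotyped_female

    @property
    def monomorphic(self) -> bool | None:
        if not self.assessable:
            return None
        return len(self.female_haplotypes) == 1


@dataclass
class NetworkStats:
    n_vertices: int
    n_edges: int
    n_components: int
    components: list[ComponentSummary]
    n_multi_female: int
    n_assessable: int
    n_monomorphic: int
    prop_monomorphic: float | None
    mean_dyadic_r: float | None
    se_dyadic_r: float | None


def component_stats(
    network: nx.Graph,
    relatedness: Mapping[tuple[str, str], float] | None = None,
) -> NetworkStats:
    """Composition summary of the network's connected components.

    Multi-female components containing a haplotype-unknown female are
    counted as unassessable rather than dropped; the monomorphic
    proportion is computed over assessable components only. The dyadic
    relatedness summary averages over all within-component pairs (not
    just edges) for which relatedness is defined.
    """
    comps: list[ComponentSummary] = []
    dyad_rs: list[float] = []
    for nodes in nx.connected_components(network):
        members = sorted(nodes)
        sexes = [network.nodes[m]["sex"] for m in members]
        haps = {m: network.nodes[m]["haplotype"] for m in members}
        females = [m for m in members if network.nodes[m]["sex"] == "female"]
        summary = ComponentSummary(
            members=members,
            size=len(members),
            n_female=sexes.count("female"),
            n_male=sexes.count("male"),
            n_unknown=sexes.count("unknown"),
            female_haplotypes={haps[m] for m in females if haps[m]},
            has_unhaplotyped_female=any(not haps[m] for m in females),
        )
        comps.append(summary)
        if relatedness is not None:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    r = relatedness.get((members[i], members[j]))
                    if r is not None and math.isfinite(r):
                        dyad_rs.append(r)
    multi = [c for c in comps if c.multi_female]
    assessable = [c for c in multi if c.assessable]
    mono = [c for c in assessable if c.monomorphic]
    mean_r = float(np.mean(dyad_rs)) if dyad_rs else None
    se_r = float(np.std(dyad_rs, ddof=1) / math.sqrt(len(dyad_rs))) if len(dyad_rs) > 1 else None
    return NetworkStats(
        n_vertices=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        n_components=nx.number_connected_components(network),
        components=comps,
        n_multi_female=len(multi),
        n_assessable=len(assessable),
        n_monomorphic=len(mono),
        prop_monomorphic=len(mono) / len(assessable) if assessable else None,
        mean_dyadic_r=mean_r,
        se_dyadic_r=se_r,
    )


def mantel_test(
    association: np.ndarray,
    relatedness: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided Mantel test of matrix correlation.

    r is the Pearson correlation of the vectorized off-diagonal entries;
    the null distribution comes from simultaneous row/column permutation
    of the relatedness matrix; p = (permuted r >= observed + 1) /
    (permutations + 1), upper tail, matching the directional hypothesis
    that associated dyads are more related. Off-diagonal NaNs in the
    relatedness matrix are excluded (and follow their labels under
    permutation). A constant matrix has no defined correlation and raises.
    """
    a = np.asarray(association, dtype=float)
    r = np.asarray(relatedness, dtype=float)
    if a.shape != r.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(r, r.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(rmat: np.ndarray) -> float:
        x = a[iu]
        y = rmat[iu]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            raise ValueError("constant matrix: Mantel r undefined")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(r)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(r[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return r_obs, p


def association_matrix(
    individuals: Sequence[Individual],
    associations: Iterable[tuple[str, str]],
) -> tuple[np.ndarray, list[str]]:
    """Binary symmetric matrix over all individuals (diagonal zero)."""
    ids = [ind.individual_id for ind in individuals]
    index = {iid: i for i, iid in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for a, b in associations:
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = 1.0
    return m, ids


def write_graphml(network: nx.Graph, path: str) -> None:
    g = network.copy()
    for _, _, data in g.edges(data=True):
        if data.get("r") is None or not math.isfinite(data.get("r", float("nan"))):
            data["r"] = 0.0
    nx.write_graphml(g, path)


def write_edge_list(network: nx.Graph, path: str) -> None:
    rows = [
        {"from": a, "to": b, "r": d.get("r"), "order": d.get("order")}
        for a, b, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["from", "to", "r", "order"]).to_csv(path, sep="\t", index=False)


def component_table(stats: NetworkStats) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(stats.components, 1):
        rows.append(
            {
                "component": i,
                "size": c.size,
                "n_female": c.n_female,
                "n_male": c.n_male,
                "n_unknown": c.n_unknown,
                "n_female_haplotypes": len(c.female_haplotypes),
                "assessable": c.assessable,
                "monomorphic": c.monomorphic,
                "members": ";".join(c.members),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ComponentSummary",
    "NetworkStats",
    "association_matrix",
    "build_network",
    "component_stats",
    "component_table",
    "find_associations",
    "mantel_test",
    "write_edge_list",
    "write_graphml",
]
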