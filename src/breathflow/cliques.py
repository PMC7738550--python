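"""Pseudo-compound grouping of co-eluting features (one sample at a time).

Features of one sample become nodes of a similarity network; an edge
joins two features that co-elute within an RT tolerance and whose raw
EIC shapes agree (cosine over the union of integration windows).
Connected components of the pruned network are that sample's
pseudo-compounds.  Per-sample groupings are then reconciled into
cohort-level clique compounds by majority vote across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .eic import BinnedRun, bin_run
from .msio import RawRun
from .peakpick import Feature, FeatureGroup

__all__ = [
    "CliqueCompound",
    "build_similarity_network",
    "find_cliques",
    "annotate_all_samples",
]

DEFAULT_RT_TOL = 0.05  # minutes — the workflow's universal RT tolerance
DEFAULT_MIN_COSINE = 0.8


@dataclass
class CliqueCompound:
    """Cohort-level pseudo-compound: co-grouped FeatureGroups plus support."""

    clique_id: str
    rt: float
    member_groups: list[FeatureGroup]
    support: float


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def build_similarity_network(
    features: list[Feature],
    run: RawRun,
    rt_tol: float = DEFAULT_RT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    binned: BinnedRun | None = None,
) -> nx.Graph:
    """Feature-similarity network of one sample.

    Edge between two features iff |ΔRT| <= rt_tol and the cosine
    similarity of their raw EIC shapes over the union integration window
    is >= min_cosine; the edge weight is that cosine.
    """
    br = binned if binned is not None else bin_run(run)
    g = nx.Graph()
    for f in features:
        g.add_node(f.feature_id, feature=f)
    order = sorted(range(len(features)), key=lambda i: features[i].rt)
    for ii, i in enumerate(order):
        fi = features[i]
        for j in order[ii + 1 :]:
            fj = features[j]
            if fj.rt - fi.rt > rt_tol:
                break
            lo = min(fi.rt_lo, fj.rt_lo)
            hi = max(fi.rt_hi, fj.rt_hi)
            sel = (br.rts >= lo) & (br.rts <= hi)
            cos = _cosine(br.eic(fi.mz)[sel], br.eic(fj.mz)[sel])
            if cos >= min_cosine:
                g.add_edge(fi.feature_id, fj.feature_id, weight=cos)
    return g


def find_cliques(graph: nx.Graph, min_cosine: float = DEFAULT_MIN_COSINE) -> list[set]:
    """Partition features into per-sample pseudo-compounds.

    Edges below ``min_cosine`` are pruned, then each connected component
    is one group.  Every node belongs to exactly one group; the result is
    ordered deterministically.
    """
    pruned = nx.Graph()
    pruned.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        if d.get("weight", 1.0) >= min_cosine:
            pruned.add_edge(u, v)
    comps = [set(c) for c in nx.connected_components(pruned)]
    comps.sort(key=lambda c: sorted(c)[0])
    return comps


def annotate_all_samples(
    runs_features: dict[str, list[Feature]],
    runs: dict[str, RawRun],
    feature_to_group: dict[str, str],
    groups_by_id: dict[str, FeatureGroup],
    rt_tol: float = DEFAULT_RT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
) -> list[CliqueCompound]:
    """Per-sample clique grouping lifted to cohort-level compounds.

    Two FeatureGroups land in the same CliqueCompound iff they co-occur
    in the same per-sample clique in a majority of the samples where both
    are present.  ``support`` is the achieved co-occurrence fraction
    averaged over the compound's reconciled pairs (1.0 for singletons).
    """
    co: dict[tuple[str, str], int] = {}
    both: dict[tuple[str, str], int] = {}
    present: dict[str, set[str]] = {}

    for sample_id, features in runs_features.items():
        run = runs[sample_id]
        graph = build_similarity_network(features, run, rt_tol, min_cosine)
        cliques = find_cliques(graph, min_cosine)
        sample_groups: set[str] = set()
        for comp in cliques:
            gids = sorted(
                {
                    feature_to_group[fid]
                    for fid in comp
                    if fid in feature_to_group
                }
            )
            sample_groups.update(gids)
            for a in range(len(gids)):
                for b in range(a + 1, len(gids)):
                    co[(gids[a], gids[b])] = co.get((gids[a], gids[b]), 0) + 1
        for gid in sample_groups:
            present.setdefault(gid, set()).add(sample_id)

    gids_sorted = sorted(present)
    meta = nx.Graph()
    meta.add_nodes_from(gids_sorted)
    pair_frac: dict[tuple[str, str], float] = {}
    for a_i in range(len(gids_sorted)):
        for b_i in range(a_i + 1, len(gids_sorted)):
            a, b = gids_sorted[a_i], gids_sorted[b_i]
            n_both = len(present[a] & present[b])
            if n_both == 0:
                continue
            n_co = co.get((a, b), 0) + co.get((b, a), 0)
            if n_co > 0.5 * n_both:
                meta.add_edge(a, b)
                pair_frac[(a, b)] = n_co / n_both

    compounds: list[CliqueCompound] = []
    comps = [sorted(c) for c in nx.connected_components(meta)]
    comps.sort(key=lambda c: c[0])
    counter = 0
    for comp in comps:
        member_groups = [groups_by_id[g] for g in comp]
        rts = np.array([g.rt_median for g in member_groups])
        med = float(np.median(rts))
        # enforce co-elution: a member drifting past the tolerance of the
        # compound median is split out as its own compound
        keep = [g for g in member_groups if abs(g.rt_median - med) <= 2 * rt_tol]
        strays = [g for g in member_groups if abs(g.rt_median - med) > 2 * rt_tol]
        for batch in ([keep] if keep else []) + [[s] for s in strays]:
            counter += 1
            rts_b = [g.rt_median for g in batch]
            ids = {g.group_feature_id for g in batch}
            fracs = [
                v
                for (a, b), v in pair_frac.items()
                if a in ids and b in ids
            ]
            compounds.append(
                CliqueCompound(
                    clique_id=f"clique_{counter:04d}",
                    rt=float(np.median(rts_b)),
                    member_groups=batch,
                    support=float(np.mean(fracs)) if fracs else 1.0,
                )
            )
    return compounds
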