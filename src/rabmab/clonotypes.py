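"""CDR3-based clonotype clustering and per-animal/bleed categorization.

Antibodies descending from one B-cell lineage share (near-)identical
CDR-H3 and CDR-L3 loops.  Two clones are linked when both CDR3s have equal
length and each differs by at most a small number of replacements
(default 2); clusters are the single-linkage transitive closure of that
relation.  Clones in no cluster are *unique* — the fraction of unique
clones is the headline diversity figure of a campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import networkx as nx
import pandas as pd

from .annotation import AnnotatedClone


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (report convention; avoids banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    out = Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(out) if decimals else int(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def cdr3_pair_distance(
    a: AnnotatedClone, b: AnnotatedClone
) -> tuple[int, int] | None:
    """Per-chain CDR3 mismatch counts, or None when the pair is incomparable.

    Chains compare by Hamming distance at equal CDR3 length; a length
    difference in either chain (an indel, not a replacement) makes the whole
    pair incomparable.
    """
    if None in (a.cdr3_h, a.cdr3_l, b.cdr3_h, b.cdr3_l):
        return None
    if len(a.cdr3_h) != len(b.cdr3_h) or len(a.cdr3_l) != len(b.cdr3_l):
        return None
    return hamming(a.cdr3_h, b.cdr3_h), hamming(a.cdr3_l, b.cdr3_l)


@dataclass
class ClonotypeClustering:
    """Partition of clones into CDR3 clusters plus unique singletons."""

    clusters: list[set[str]]
    unique_ids: set[str]
    threshold: int
    linkage: str = "single"

    def label_of(self) -> dict[str, str]:
        labels = {cid: "unique" for cid in self.unique_ids}
        for i, cluster in enumerate(self.clusters):
            for cid in cluster:
                labels[cid] = f"cluster{i + 1:03d}"
        return labels

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_clonotypes(
    clones: Sequence[AnnotatedClone],
    threshold: int = 2,
    linkage: str = "single",
) -> ClonotypeClustering:
    """Cluster clones whose CDR-H3 and CDR-L3 each differ by <= threshold.

    ``single`` linkage (default) takes the transitive closure of the
    pairwise relation; ``complete`` requires every within-cluster pair to
    satisfy it (greedy agglomeration, deterministic by clone order).
    Clones that fail annotation are excluded from clustering and counted as
    neither unique nor clustered.
    """
    if not clones:
        raise ValueError("need at least one clone")
    eligible = [c for c in clones if c.cdr3_h is not None and c.cdr3_l is not None]
    graph = nx.Graph()
    graph.add_nodes_from(c.clone_id for c in eligible)
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            d = cdr3_pair_distance(a, b)
            if d is not None and d[0] <= threshold and d[1] <= threshold:
                graph.add_edge(a.clone_id, b.clone_id)

    if linkage == "single":
        components = [set(comp) for comp in nx.connected_components(graph)]
    elif linkage == "complete":
        components = _complete_linkage(eligible, graph)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    clusters = sorted(
        (comp for comp in components if len(comp) >= 2), key=lambda s: sorted(s)[0]
    )
    unique = {c.clone_id for c in eligible} - set().union(*clusters) if clusters else {
        c.clone_id for c in eligible
    }
    return ClonotypeClustering(
        clusters=clusters, unique_ids=unique, threshold=threshold, linkage=linkage
    )


def _complete_linkage(eligible, graph) -> list[set[str]]:
    clusters: list[set[str]] = []
    for clone in eligible:
        placed = False
        for cluster in clusters:
            if all(graph.has_edge(clone.clone_id, other) for other in cluster):
                cluster.add(clone.clone_id)
                placed = True
                break
        if not placed:
            clusters.append({clone.clone_id})
    return clusters


def categorize(
    clustering: ClonotypeClustering, clones: Sequence[AnnotatedClone]
) -> dict:
    """Per-(animal, bleed) diversity accounting plus cluster-sharing flags.

    The summary table mirrors the campaign report layout: clone counts,
    unique/clustered split with % unique (integer, half-up), and counts of
    clones sharing an identical CDR-H3 / CDR-L3 / both / full VH / VL / both
    with at least one other clone of the same stratum.
    """
    by_id = {c.clone_id: c for c in clones}
    labels = clustering.label_of()

    def n_sharing(group: list[AnnotatedClone], key) -> int:
        vals = [key(c) for c in group]
        counts: dict = {}
        for v in vals:
            if v is not None:
                counts[v] = counts.get(v, 0) + 1
        return sum(1 for v in vals if v is not None and counts[v] >= 2)

    strata: dict[tuple[str, int], list[AnnotatedClone]] = {}
    for c in clones:
        strata.setdefault((c.animal, c.bleed), []).append(c)

    rows = []
    for (animal, bleed), group in sorted(strata.items(), key=lambda x: (x[0][1], x[0][0])):
        ids = [c.clone_id for c in group]
        n_unique = sum(1 for cid in ids if labels.get(cid) == "unique")
        n_clustered = sum(
            1 for cid in ids if cid in labels and labels[cid] != "unique"
        )
        rows.append(
            {
                "bleed": bleed,
                "animal": animal,
                "n_clones": len(group),
                "n_unique": n_unique,
                "pct_unique": round_half_up(100.0 * n_unique / len(group))
                if group
                else 0,
                "n_clustered": n_clustered,
                "identical_cdr3_h": n_sharing(group, lambda c: c.cdr3_h),
                "identical_cdr3_l": n_sharing(group, lambda c: c.cdr3_l),
                "identical_cdr3_pair": n_sharing(
                    group,
                    lambda c: (c.cdr3_h, c.cdr3_l)
                    if c.cdr3_h is not None and c.cdr3_l is not None
                    else None,
                ),
                "identical_vh": n_sharing(group, lambda c: c.vh or None),
                "identical_vl": n_sharing(group, lambda c: c.vl or None),
                "identical_vh_vl": n_sharing(
                    group, lambda c: (c.vh, c.vl) if c.vh and c.vl else None
                ),
            }
        )
    table = pd.DataFrame(rows)

    shared_across_bleeds: list[int] = []
    shared_across_animals: list[int] = []
    for i, cluster in enumerate(clustering.clusters):
        members = [by_id[cid] for cid in cluster if cid in by_id]
        animals = {c.animal for c in members}
        bleeds_per_animal = {
            a: {c.bleed for c in members if c.animal == a} for a in animals
        }
        if len(animals) > 1:
            shared_across_animals.append(i)
        if any(len(b) > 1 for b in bleeds_per_animal.values()):
            shared_across_bleeds.append(i)

    return {
        "table": table,
        "shared_across_bleeds": shared_across_bleeds,
        "shared_across_animals": shared_across_animals,
    }
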