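"""Transcription-factor cooperation from distance-constrained TFBS
co-occurrence.

A co-occurrence event is an unordered pair of non-overlapping binding sites
in the same promoter whose edge-to-edge gap lies within a fixed window
(default 5..20 bp inclusive — close enough for physical cooperation, far
enough apart to exclude overlapping/competing sites).  Pairs are scored by
pointwise mutual information

    PMI(A;B) = log2[ p(A,B) / (kappa * p(A) * p(B)) ],

with p(A,B) the pair's share of all events, p(A) the TF's share of all
sites, and kappa = 2 for A != B (either ordering realises the unordered
pair) or 1 for self-pairs.  PMI values are z-standardised within a trait's
pair population; cooperation is called significant at z >= 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "PairCountTable",
    "TFPairScore",
    "CooperationNetwork",
    "count_cooccurrences",
    "pmi_scores",
    "significance",
    "build_network",
    "cross_trait_summary",
]


@dataclass
class PairCountTable:
    """Co-occurrence events per unordered TF pair plus site totals."""

    pair_counts: dict[tuple[str, str], int]
    site_counts: dict[str, int]
    n_sequences: int

    @property
    def total_events(self) -> int:
        return sum(self.pair_counts.values())

    @property
    def total_sites(self) -> int:
        return sum(self.site_counts.values())


@dataclass
class TFPairScore:
    tf_a: str
    tf_b: str
    events: int
    pmi: float
    z: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.tf_b < self.tf_a:
            self.tf_a, self.tf_b = self.tf_b, self.tf_a


@dataclass
class CooperationNetwork:
    """Significant TF pairs of one trait as a graph (self-loops allowed)."""

    trait: str
    graph: nx.Graph

    @property
    def n_tfs(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_pairs(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"tf_a": min(a, b), "tf_b": max(a, b), **data}
            for a, b, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["tf_a", "tf_b"]).reset_index(drop=True) \
            if rows else pd.DataFrame(columns=["tf_a", "tf_b", "pmi", "z"])


def count_cooccurrences(
    hits: pd.DataFrame, d_min: int = 5, d_max: int = 20
) -> PairCountTable:
    """Count distance-constrained co-occurrence events per unordered TF pair.

    ``hits`` is an overlap-resolved table with columns gene_id, tf, start,
    end (0-based half-open).  An event is a hit pair in the same promoter
    with edge-to-edge gap g = start(downstream) - end(upstream) satisfying
    d_min <= g <= d_max; each qualifying hit pair counts once, same-TF pairs
    count as self-pair events.  Site counts tally every hit.
    """
    if d_min > d_max:
        raise ValueError("d_min must be <= d_max")
    pair_counts: dict[tuple[str, str], int] = {}
    site_counts: dict[str, int] = {}
    n_sequences = 0
    for _, group in hits.groupby("gene_id", sort=True):
        n_sequences += 1
        recs = sorted(group.itertuples(index=False), key=lambda r: (r.start, r.end))
        for r in recs:
            site_counts[r.tf] = site_counts.get(r.tf, 0) + 1
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                gap = b.start - a.end
                if gap > d_max:
                    break  # starts are sorted; later hits only further away
                if gap < d_min:
                    continue
                key = (a.tf, b.tf) if a.tf <= b.tf else (b.tf, a.tf)
                pair_counts[key] = pair_counts.get(key, 0) + 1
    return PairCountTable(pair_counts, site_counts, n_sequences)


def pmi_scores(counts: PairCountTable) -> dict[tuple[str, str], float]:
    """Pointwise mutual information (bits) of every observed pair."""
    T = counts.total_events
    S = counts.total_sites
    if S == 0:
        raise ValueError("no binding sites counted")
    if T < 1:
        return {}
    out = {}
    for (a, b), n_ab in counts.pair_counts.items():
        if n_ab == 0:
            continue
        p_ab = n_ab / T
        p_a = counts.site_counts[a] / S
        p_b = counts.site_counts[b] / S
        kappa = 1.0 if a == b else 2.0
        out[(a, b)] = math.log2(p_ab / (kappa * p_a * p_b))
    return out


def significance(
    pmi_map: dict[tuple[str, str], float],
    counts: PairCountTable | None = None,
    z_threshold: float = 3.0,
) -> list[TFPairScore]:
    """z-standardise PMI values within the trait and flag z >= threshold.

    With fewer than 3 scored pairs no z distribution exists: all pairs are
    flagged non-significant.  A degenerate (zero-variance) distribution
    likewise yields no significant pair.  Output is sorted by ascending z
    within the significant set, then ascending z among the rest, so "top"
    pairs read off the tail.
    """
    import warnings

    import numpy as np

    pairs = sorted(pmi_map)
    if not pairs:
        return []
    values = np.array([pmi_map[p] for p in pairs])
    if len(pairs) < 3:
        warnings.warn("fewer than 3 scored pairs; no z distribution", stacklevel=2)
        z = np.full(len(pairs), np.nan)
        sig = np.zeros(len(pairs), bool)
    else:
        sd = values.std()
        if sd == 0:
            z = np.zeros(len(pairs))
            sig = np.zeros(len(pairs), bool)
        else:
            z = (values - values.mean()) / sd
            sig = z >= z_threshold
    scores = [
        TFPairScore(
            a, b,
            events=counts.pair_counts[(a, b)] if counts else 0,
            pmi=float(v), z=float(zz), significant=bool(s),
        )
        for (a, b), v, zz, s in zip(pairs, values, z, sig)
    ]
    return sorted(scores, key=lambda s: (not s.significant, s.z if s.z == s.z else 0.0))


def build_network(scores: list[TFPairScore], trait: str) -> CooperationNetwork:
    """Graph of significant pairs; nodes are TFs incident to >= 1 edge."""
    g = nx.Graph()
    for s in sorted(
        (s for s in scores if s.significant), key=lambda s: (s.tf_a, s.tf_b)
    ):
        g.add_edge(s.tf_a, s.tf_b, pmi=s.pmi, z=s.z, events=s.events)
    return CooperationNetwork(trait=trait, graph=g)


def cross_trait_summary(networks: list[CooperationNetwork]) -> dict:
    """TFs common to every network, union counts and per-TF partner sets.

    The partner table shows, per TF and trait, which partners the TF
    cooperates with — the raw material for spotting partner switching
    between traits.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    node_sets = [set(n.graph.nodes) for n in networks]
    consistent = set.intersection(*node_sets) if node_sets else set()
    all_tfs = set.union(*node_sets)
    all_pairs = set()
    partner_rows = []
    for net in networks:
        for a, b in net.graph.edges:
            all_pairs.add((min(a, b), max(a, b)))
        for tf in sorted(net.graph.nodes):
            partners = sorted(
                {other for other in net.graph.neighbors(tf)}
                | ({tf} if net.graph.has_edge(tf, tf) else set())
            )
            partner_rows.append(
                {"trait": net.trait, "tf": tf, "partners": ";".join(partners)}
            )
    return {
        "consistent_tfs": sorted(consistent),
        "n_unique_tfs": len(all_tfs),
        "n_unique_pairs": len(all_pairs),
        "partner_table": pd.DataFrame(partner_rows, columns=["trait", "tf", "partners"]),
    }
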