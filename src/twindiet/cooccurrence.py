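"""Food-description frequencies and within-record co-occurrence networks.

Items are de-duplicated within each one-day record, unordered pairs are
enumerated, and counts summed across records.  Two variants mirror common
practice for diet diaries: the all-day network with staple beverages (milk,
coffee, tea, wine) removed so they do not swamp every edge, and a breakfast
network restricted to entries timed strictly between 06:00 and 11:00.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .foods import BEVERAGE_EXCLUSIONS
from .ingest import parse_clock_time

__all__ = [
    "CooccurrenceNetwork",
    "word_frequencies",
    "phrase_frequencies",
    "build_cooccurrence",
]


@dataclass
class CooccurrenceNetwork:
    nodes: pd.DataFrame  # food_key_id, count, share
    edges: pd.DataFrame  # item_a, item_b, count, share
    variant: str

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, r in self.nodes.iterrows():
            g.add_node(r["food_key_id"], count=int(r["count"]), share=float(r["share"]))
        for _, r in self.edges.iterrows():
            g.add_edge(r["item_a"], r["item_b"], weight=int(r["count"]), share=float(r["share"]))
        return g


_WORD = re.compile(r"[a-z]+")


def word_frequencies(descriptions, top: int | None = 100) -> pd.DataFrame:
    """Case-folded word counts across descriptions, count-descending then alphabetical."""
    counts = Counter()
    for d in descriptions:
        if d is None or (isinstance(d, float) and pd.isna(d)):
            continue
        counts.update(_WORD.findall(str(d).lower()))
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["word", "count"])
    return df.head(top) if top else df


def phrase_frequencies(entries: pd.DataFrame, top: int | None = 100) -> pd.DataFrame:
    """Per canonical item: occurrences, share of all occurrences, and the mean
    number of occasions per record among records containing the item."""
    total = len(entries)
    per_rec = entries.groupby(["food_key_id", "record_id"], sort=True).size()
    rows = []
    for key, sub in per_rec.groupby(level=0, sort=True):
        count = int(sub.sum())
        rows.append(
            {
                "food_key_id": key,
                "count": count,
                "share": count / total,
                "mean_occasions": float(sub.mean()),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["count", "food_key_id"], ascending=[False, True], ignore_index=True
    )
    return df.head(top) if top else df


def build_cooccurrence(
    entries: pd.DataFrame,
    variant: str = "all_day_no_beverages",
    beverage_ids: frozenset[str] = BEVERAGE_EXCLUSIONS,
) -> CooccurrenceNetwork:
    """Co-occurrence network of distinct items consumed within the same record.

    ``all_day_no_beverages`` drops items in ``beverage_ids`` before pairing;
    ``breakfast`` keeps only entries timed strictly between 06:00 and 11:00
    (beverages retained).
    """
    if variant not in ("all_day_no_beverages", "breakfast"):
        raise ValueError(f"unknown variant {variant!r}")
    work = entries
    if variant == "all_day_no_beverages":
        work = work[~work["food_key_id"].isin(beverage_ids)]
    else:
        mins = work["meal_time"].map(parse_clock_time)
        work = work[(mins > 6 * 60) & (mins < 11 * 60)]
        if work.empty:
            warnings.warn("breakfast variant: no timed entries in (06:00, 11:00)")

    node_counts: Counter = Counter()
    edge_counts: Counter = Counter()
    for _, grp in work.groupby("record_id", sort=True):
        items = sorted(set(grp["food_key_id"]))
        node_counts.update(items)
        edge_counts.update(combinations(items, 2))

    total_nodes = sum(node_counts.values()) or 1
    total_edges = sum(edge_counts.values()) or 1
    nodes = pd.DataFrame(
        [
            {"food_key_id": k, "count": c, "share": c / total_nodes}
            for k, c in sorted(node_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["food_key_id", "count", "share"],
    )
    edges = pd.DataFrame(
        [
            {"item_a": a, "item_b": b, "count": c, "share": c / total_edges}
            for (a, b), c in sorted(edge_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["item_a", "item_b", "count", "share"],
    )
    return CooccurrenceNetwork(nodes=nodes, edges=edges, variant=variant)
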