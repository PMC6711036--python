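"""Interaction and term co-occurrence networks.

Two graphs summarize the corpus:

* a directed **interaction graph** over users — an edge ``A -> B`` counts
  the mentions and retweets (and, by default, replies, since a reply embeds
  a mention) sent by A toward B, so high in-degree identifies the accounts
  receiving communication;
* an undirected **co-occurrence graph** over lexicon terms — two terms
  share an edge whenever they appear in the same tweet, weighted by the
  number of such tweets and colored by the modal sentiment of the
  contributing tweets (ties fall back to neutral).

Topology metrics (degree/betweenness/closeness centrality, clustering
coefficient, characteristic path length, average neighbors) use the
standard definitions; "communities" are weakly-connected components above a
size cut-off, with optional modularity-based detection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .ner import EntityMention
from .normalize import CleanTweet, RawTweet
from .profiler import UserProfile
from .sentiment import SentimentResult

__all__ = [
    "NodeMetrics",
    "GraphMetrics",
    "build_interaction_graph",
    "build_cooccurrence_graph",
    "compute_metrics",
    "extract_communities",
]


@dataclass
class NodeMetrics:
    node: object
    in_degree: int
    out_degree: int
    degree_centrality: float
    betweenness_centrality: float
    closeness_centrality: float
    clustering_coefficient: float


@dataclass
class GraphMetrics:
    nodes: dict = field(default_factory=dict)  # node -> NodeMetrics
    characteristic_path_length: float = 0.0
    average_neighbors: float = 0.0


def build_interaction_graph(
    tweets: Iterable[RawTweet | CleanTweet],
    profiles: Optional[Mapping[str, UserProfile]] = None,
    mentions_by_tweet: Optional[Mapping[str, Sequence[str]]] = None,
    include_replies: bool = True,
) -> nx.DiGraph:
    """Directed user graph weighted by mention + retweet (+ reply) counts.

    Accepts raw tweets; mention targets extracted by the normalizer may be
    supplied via ``mentions_by_tweet`` keyed on tweet id (they override the
    record's own mention list). Retweet edges point retweeter -> original
    author. A reply target counts as a mention unless already mentioned in
    the same tweet, or ``include_replies`` is false.
    """
    graph = nx.DiGraph()
    for tweet in tweets:
        user = getattr(tweet, "user", None)
        source = user.get("screen_name") if isinstance(user, dict) else None
        if source is None:
            continue
        graph.add_node(source)
        targets: list[str] = []
        if mentions_by_tweet is not None and tweet.id in mentions_by_tweet:
            targets.extend(mentions_by_tweet[tweet.id])
        else:
            targets.extend(getattr(tweet, "user_mentions", ()) or ())
        if getattr(tweet, "retweet_of_user", None):
            targets.append(tweet.retweet_of_user)
        reply_to = getattr(tweet, "in_reply_to_user", None)
        if include_replies and reply_to and reply_to not in targets:
            targets.append(reply_to)
        for target in targets:
            if graph.has_edge(source, target):
                graph[source][target]["weight"] += 1
            else:
                graph.add_edge(source, target, weight=1)
    if profiles:
        for node in graph.nodes:
            prof = profiles.get(node)
            graph.nodes[node]["account_type"] = (
                prof.account_type if prof else "unknown"
            )
    return graph


def build_cooccurrence_graph(
    mentions: Iterable[EntityMention],
    sentiments: Optional[Mapping[str, SentimentResult | str]] = None,
) -> nx.Graph:
    """Undirected term graph: +1 weight per tweet containing both terms.

    Each edge carries ``sentiment_majority``, the modal polarity label of
    its contributing tweets (ties -> neutral). Node size attribute is the
    number of distinct tweets mentioning the term.
    """
    terms_by_tweet: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    for m in mentions:
        terms_by_tweet.setdefault(m.tweet_id, set()).add(m.term)
        category[m.term] = m.meta_category
    graph = nx.Graph()
    labels: dict[tuple[str, str], Counter] = {}
    tweet_count: Counter = Counter()
    for tweet_id, terms in terms_by_tweet.items():
        label = None
        if sentiments is not None:
            res = sentiments.get(tweet_id)
            label = res.label if isinstance(res, SentimentResult) else res
        for term in terms:
            tweet_count[term] += 1
        for a, b in combinations(sorted(terms), 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
            if label is not None:
                labels.setdefault((a, b), Counter())[label] += 1
    for term in tweet_count:
        graph.add_node(term)
        graph.nodes[term]["n_tweets"] = tweet_count[term]
        graph.nodes[term]["meta_category"] = category[term]
    for (a, b), counter in labels.items():
        ranked = counter.most_common()
        top = ranked[0][1]
        leaders = [lab for lab, c in ranked if c == top]
        graph[a][b]["sentiment_majority"] = (
            leaders[0] if len(leaders) == 1 else "neutral"
        )
    for a, b in graph.edges:
        graph[a][b].setdefault("sentiment_majority", "neutral")
    return graph


def compute_metrics(graph: nx.Graph | nx.DiGraph) -> GraphMetrics:
    """Per-node centralities plus whole-graph summary statistics.

    Degree centrality is degree/(n-1); betweenness is the normalized pair
    fraction; closeness uses the plain component-wise form
    (reachable-1)/sum(distances). The clustering coefficient is computed on
    the undirected projection. Characteristic path length averages shortest
    paths over connected (ordered, for digraphs) node pairs.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be non-empty")
    n = graph.number_of_nodes()
    directed = graph.is_directed()
    undirected = graph.to_undirected() if directed else graph
    if n == 1:
        node = next(iter(graph.nodes))
        metrics = GraphMetrics(average_neighbors=0.0, characteristic_path_length=0.0)
        metrics.nodes[node] = NodeMetrics(node, 0, 0, 0.0, 0.0, 0.0, 0.0)
        return metrics
    degree_c = nx.degree_centrality(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=True, weight=None)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    clustering = nx.clustering(undirected)
    path_sum, path_pairs = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        for target, dist in dists.items():
            if dist > 0:
                path_sum += dist
                path_pairs += 1
    if not directed:
        pass  # each unordered pair counted twice; the mean is unchanged
    metrics = GraphMetrics(
        characteristic_path_length=path_sum / path_pairs if path_pairs else 0.0,
        average_neighbors=sum(dict(undirected.degree()).values()) / n,
    )
    for node in graph.nodes:
        metrics.nodes[node] = NodeMetrics(
            node=node,
            in_degree=graph.in_degree(node) if directed else graph.degree(node),
            out_degree=graph.out_degree(node) if directed else graph.degree(node),
            degree_centrality=degree_c[node],
            betweenness_centrality=betweenness[node],
            closeness_centrality=closeness[node],
            clustering_coefficient=clustering[node],
        )
    return metrics


def extract_communities(
    graph: nx.Graph | nx.DiGraph,
    min_size: int = 5,
    method: str = "components",
) -> list[set]:
    """Communities larger than ``min_size`` users, biggest first.

    ``method="components"`` (default) takes weakly-connected components;
    ``method="modularity"`` applies greedy modularity maximization on the
    undirected projection instead.
    """
    if graph.number_of_nodes() == 0:
        return []
    undirected = graph.to_undirected() if graph.is_directed() else graph
    if method == "components":
        groups = (
            nx.weakly_connected_components(graph)
            if graph.is_directed()
            else nx.connected_components(graph)
        )
    elif method == "modularity":
        groups = nx.community.greedy_modularity_communities(undirected)
    else:
        raise ValueError(f"unknown community method {method!r}")
    selected = [set(g) for g in groups if len(g) > min_size]
    selected.sort(key=lambda g: (-len(g), sorted(g)[0] if g else ""))
    return selected
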