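"""Graph construction and topology-metric tests with brute-force oracles."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from bowelwatch.graphs import (
    build_cooccurrence_graph,
    build_interaction_graph,
    compute_metrics,
    extract_communities,
)
from bowelwatch.ner import EntityMention
from bowelwatch.normalize import RawTweet


def _tweet(i, user, mentions=(), retweet_of=None, reply_to=None):
    return RawTweet(
        id=f"t{i}",
        text="",
        user={"screen_name": user},
        user_mentions=list(mentions),
        retweet_of_user=retweet_of,
        in_reply_to_user=reply_to,
    )


class TestInteractionGraph:
    def test_mentions_and_retweets_sum(self):
        tweets = [
            _tweet(0, "A", mentions=["B", "B"]),
            _tweet(1, "A", retweet_of="B"),
        ]
        graph = build_interaction_graph(tweets)
        assert graph["A"]["B"]["weight"] == 3

    def test_no_interactions_gives_no_edges(self):
        graph = build_interaction_graph([_tweet(0, "A"), _tweet(1, "B")])
        assert graph.number_of_edges() == 0
        assert set(graph.nodes) == {"A", "B"}

    def test_star_in_degree(self):
        tweets = [_tweet(i, f"u{i}", mentions=["hub"]) for i in range(6)]
        graph = build_interaction_graph(tweets)
        assert graph.in_degree("hub") == 6

    def test_replies_count_unless_excluded(self):
        tweets = [_tweet(0, "A", reply_to="B")]
        assert build_interaction_graph(tweets)["A"]["B"]["weight"] == 1
        assert (
            build_interaction_graph(tweets, include_replies=False).number_of_edges()
            == 0
        )

    def test_degree_sums_equal_total_interactions(self, english_tweets):
        graph = build_interaction_graph(english_tweets)
        total = sum(d["weight"] for _, _, d in graph.edges(data=True))
        assert sum(w for _, w in graph.in_degree(weight="weight")) == total
        assert sum(w for _, w in graph.out_degree(weight="weight")) == total


def _mention(tweet_id, term, category="Disease"):
    return EntityMention(tweet_id, term, category, (0, 1))


class TestCooccurrenceGraph:
    def test_pair_enumeration(self):
        mentions = [
            _mention("t1", "cannabis", "Drug"),
            _mention("t1", "pain", "Symptom"),
            _mention("t1", "diarrhea"),
        ]
        graph = build_cooccurrence_graph(mentions)
        assert graph.number_of_edges() == 3
        assert all(d["weight"] == 1 for _, _, d in graph.edges(data=True))

    def test_single_term_no_edges(self):
        graph = build_cooccurrence_graph([_mention("t1", "pain")])
        assert graph.number_of_edges() == 0
        assert graph.nodes["pain"]["n_tweets"] == 1

    def test_sentiment_majority_modal_and_tie(self):
        mentions = [
            _mention(t, term)
            for t in ("t1", "t2", "t3")
            for term in ("a", "b")
        ]
        sentiments = {"t1": "negative", "t2": "negative", "t3": "positive"}
        graph = build_cooccurrence_graph(mentions, sentiments)
        assert graph["a"]["b"]["sentiment_majority"] == "negative"
        tie = build_cooccurrence_graph(
            mentions[:4], {"t1": "negative", "t2": "positive"}
        )
        assert tie["a"]["b"]["sentiment_majority"] == "neutral"

    def test_total_weight_identity(self, normalizer, lexicon, english_tweets):
        """Total edge weight equals sum over tweets of C(k_t, 2)."""
        from bowelwatch.ner import recognize

        mentions = []
        for tweet in english_tweets[:150]:
            mentions.extend(recognize(normalizer.normalize(tweet), lexicon))
        graph = build_cooccurrence_graph(mentions)
        per_tweet: dict[str, set] = {}
        for m in mentions:
            per_tweet.setdefault(m.tweet_id, set()).add(m.term)
        expected = sum(len(t) * (len(t) - 1) // 2 for t in per_tweet.values())
        assert sum(d["weight"] for _, _, d in graph.edges(data=True)) == expected


# ---------------------------------------------------------------------------
# brute-force metric oracle (enumeration; no networkx algorithms)


def _oracle_distances(nodes, edges, directed):
    dist = {(a, b): float("inf") for a in nodes for b in nodes}
    for a in nodes:
        dist[(a, a)] = 0
    for a, b in edges:
        dist[(a, b)] = 1
        if not directed:
            dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[(i, k)] + dist[(k, j)] < dist[(i, j)]:
                    dist[(i, j)] = dist[(i, k)] + dist[(k, j)]
    return dist


def _count_shortest_paths(nodes, adjacency, source, target, dist):
    """Enumerate shortest source->target paths by depth-limited DFS; returns
    (count, interior-node multiset)."""
    limit = dist[(source, target)]
    if limit == float("inf") or source == target:
        return 0, []
    count = 0
    interior: list = []
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if len(path) - 1 > limit:
            continue
        if node == target:
            if len(path) - 1 == limit:
                count += 1
                interior.extend(path[1:-1])
            continue
        for nxt in adjacency[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return count, interior


def _oracle_metrics(graph):
    nodes = list(graph.nodes)
    n = len(nodes)
    directed = graph.is_directed()
    edges = list(graph.edges)
    dist = _oracle_distances(nodes, edges, directed)
    adjacency = {a: sorted(graph.successors(a) if directed else graph.neighbors(a)) for a in nodes}

    betweenness = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            sigma, interior = _count_shortest_paths(nodes, adjacency, s, t, dist)
            if sigma == 0:
                continue
            for v in set(interior):
                betweenness[v] += interior.count(v) / sigma
    scale = (n - 1) * (n - 2) if n > 2 else 1
    if not directed:
        # each unordered pair was visited twice
        betweenness = {v: b / 2 for v, b in betweenness.items()}
        scale = scale / 2 if n > 2 else 1
    betweenness = {v: b / scale for v, b in betweenness.items()}

    closeness = {}
    for v in nodes:
        incoming = [dist[(u, v)] for u in nodes if u != v and dist[(u, v)] < float("inf")]
        closeness[v] = len(incoming) / sum(incoming) if incoming and sum(incoming) else 0.0

    undirected = graph.to_undirected() if directed else graph
    clustering = {}
    for v in nodes:
        neighbors = list(undirected.neighbors(v))
        k = len(neighbors)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(neighbors, 2) if undirected.has_edge(a, b)
        )
        clustering[v] = 2 * links / (k * (k - 1))

    finite = [d for (a, b), d in dist.items() if a != b and d < float("inf")]
    cpl = sum(finite) / len(finite) if finite else 0.0
    degree_c = {
        v: (
            (graph.in_degree(v) + graph.out_degree(v)) if directed else graph.degree(v)
        )
        / (n - 1)
        for v in nodes
    }
    return degree_c, betweenness, closeness, clustering, cpl


class TestMetrics:
    def test_path_graph_betweenness_and_clustering(self):
        graph = nx.path_graph(["a", "b", "c"])
        metrics = compute_metrics(graph)
        assert metrics.nodes["b"].betweenness_centrality == pytest.approx(1.0)
        assert all(m.clustering_coefficient == 0.0 for m in metrics.nodes.values())

    def test_triangle(self):
        metrics = compute_metrics(nx.complete_graph(3))
        assert all(
            m.clustering_coefficient == pytest.approx(1.0)
            for m in metrics.nodes.values()
        )
        assert metrics.characteristic_path_length == pytest.approx(1.0)

    def test_star_center_degree_centrality(self):
        metrics = compute_metrics(nx.star_graph(4))
        assert metrics.nodes[0].degree_centrality == pytest.approx(1.0)

    def test_single_node_graph(self):
        graph = nx.Graph()
        graph.add_node("only")
        metrics = compute_metrics(graph)
        node = metrics.nodes["only"]
        assert (
            node.degree_centrality
            == node.betweenness_centrality
            == node.closeness_centrality
            == 0.0
        )

    @pytest.mark.parametrize("directed", [False, True])
    def test_metrics_match_bruteforce_oracle(self, directed):
        rng = random.Random(7 if directed else 8)
        for trial in range(30):
            n = rng.randint(2, 12)
            p = rng.choice([0.15, 0.3, 0.5])
            graph = (
                nx.gnp_random_graph(n, p, seed=rng.randint(0, 10**6), directed=directed)
            )
            metrics = compute_metrics(graph)
            degree_c, betweenness, closeness, clustering, cpl = _oracle_metrics(graph)
            for v in graph.nodes:
                node = metrics.nodes[v]
                assert node.degree_centrality == pytest.approx(degree_c[v])
                assert node.betweenness_centrality == pytest.approx(betweenness[v])
                assert node.closeness_centrality == pytest.approx(closeness[v])
                assert node.clustering_coefficient == pytest.approx(clustering[v])
            assert metrics.characteristic_path_length == pytest.approx(cpl)


class TestCommunities:
    def test_size_cutoff(self):
        graph = nx.Graph()
        graph.add_edges_from(nx.path_graph(range(7)).edges)
        graph.add_edges_from([(10, 11), (11, 12)])
        communities = extract_communities(graph, min_size=5)
        assert [len(c) for c in communities] == [7]

    def test_empty_graph(self):
        assert extract_communities(nx.Graph()) == []

    def test_complete_graph_single_community(self):
        assert [len(c) for c in extract_communities(nx.complete_graph(10))] == [10]

    def test_directed_uses_weak_connectivity(self):
        graph = nx.DiGraph([(i, i + 1) for i in range(6)])
        assert [len(c) for c in extract_communities(graph, min_size=5)] == [7]
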