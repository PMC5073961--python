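"""Interpret a fitted dynamic topic model.

Hard topic assignment per compound-time condition (argmax of P(T|D)),
time-resolved gene rankings from P(W|T)_t, representative-gene sets
(top-n at every time point), topic-membership counts, and one-sided
Fisher's-exact gene-set over-representation with Benjamini-Hochberg
correction.  Enrichment operates at gene level: the ``_up`` / ``_down``
direction tags are stripped and duplicates collapsed before testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "assign_topics", "rank_genes", "top_n", "representative_genes",
    "topic_membership_counts", "fisher_enrichment", "GeneSetCollection",
    "strip_direction",
]


def assign_topics(fitted) -> pd.DataFrame:
    """Assign each document to its argmax topic of P(T|D).

    Ties are broken toward the lowest topic index (and logged).  Returns a
    DataFrame with ``doc_id``, ``topic``, ``probability`` and ``margin``
    (gap to the runner-up; 0 for K = 1).
    """
    P = np.asarray(fitted.doc_topic_)
    top = P.argmax(axis=1)
    n_max = (P == P[np.arange(len(P)), top][:, None]).sum(axis=1)
    for d in np.nonzero(n_max > 1)[0]:
        logger.info("document %d: %d-way tie broken toward topic %d",
                    d, n_max[d], top[d])
    if P.shape[1] > 1:
        part = np.partition(P, -2, axis=1)
        margin = part[:, -1] - part[:, -2]
    else:
        margin = np.zeros(len(P))
    doc_ids = getattr(fitted, "doc_ids_", list(range(len(P))))
    return pd.DataFrame({
        "doc_id": doc_ids,
        "topic": top,
        "probability": P[np.arange(len(P)), top],
        "margin": margin,
    })


def rank_genes(fitted, topic: int, slice_index: int) -> pd.DataFrame:
    """Rank vocabulary words by P(W|T) for one topic at one time slice.

    Descending probability; ties broken by ascending word id.  Ranks start
    at 1.
    """
    pi = np.asarray(fitted.topic_word_)
    T, K, W = pi.shape
    if not 0 <= topic < K:
        raise IndexError(f"topic {topic} out of range [0, {K})")
    if not 0 <= slice_index < T:
        raise IndexError(f"slice {slice_index} out of range [0, {T})")
    p = pi[slice_index, topic]
    order = np.lexsort((np.arange(W), -p))
    vocab = getattr(fitted, "vocabulary_", None)
    words = [vocab.word(int(w)) for w in order] if vocab is not None else order.tolist()
    return pd.DataFrame({
        "topic": topic,
        "slice": slice_index,
        "rank": np.arange(1, W + 1),
        "word_id": order,
        "word": words,
        "probability": p[order],
    })


def top_n(ranking: pd.DataFrame, n: int = 300) -> list:
    """First ``min(n, W)`` words of a ranking (the conventional top-300 cut)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return ranking["word"].head(n).tolist()


def representative_genes(fitted, topic: int, n: int = 300) -> list:
    """Words ranked within the top n at *every* time slice for a topic.

    The intersection over slices; returned in slice-0 rank order.
    """
    T = np.asarray(fitted.topic_word_).shape[0]
    per_slice = [top_n(rank_genes(fitted, topic, t), n) for t in range(T)]
    common = set(per_slice[0]).intersection(*map(set, per_slice[1:]))
    return [w for w in per_slice[0] if w in common]


def topic_membership_counts(fitted, n: int = 300, per_slice: bool = False) -> dict:
    """For each word, in how many topics' top-n lists it appears.

    By default a word counts toward a topic if it is in that topic's top n
    at *any* slice; with ``per_slice=True`` the count is over (topic, slice)
    pairs instead.
    """
    pi = np.asarray(fitted.topic_word_)
    T, K, W = pi.shape
    counts: dict = {}
    for k in range(K):
        seen = set()
        for t in range(T):
            members = top_n(rank_genes(fitted, k, t), n)
            if per_slice:
                for w in members:
                    counts[w] = counts.get(w, 0) + 1
            else:
                seen.update(members)
        if not per_slice:
            for w in seen:
                counts[w] = counts.get(w, 0) + 1
    return counts


def strip_direction(word: str) -> str:
    """Collapse a direction-split word back to its gene id."""
    if word.endswith(("_up", "_down")):
        return word.rsplit("_", 1)[0]
    return word


class GeneSetCollection:
    """Named, non-empty gene sets (e.g. KEGG pathways, GO terms)."""

    def __init__(self, sets: dict, source: str = ""):
        if len(set(sets)) != len(sets):
            raise ValueError("set names must be unique")
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(members) for name, members in sets.items()}
        self.source = source

    def __len__(self):
        return len(self.sets)

    def items(self):
        return self.sets.items()


def fisher_enrichment(word_list, collection: GeneSetCollection, universe,
                      topic=None, slice_index=None) -> pd.DataFrame:
    """One-sided (over-representation) Fisher's exact test per gene set.

    ``word_list`` may contain direction-split words; they are collapsed to
    genes and de-duplicated.  For each set the 2x2 table is built against
    ``universe`` and the upper hypergeometric tail
    ``P(X >= a)`` with ``X ~ Hypergeom(N, K_s, n)`` is the raw p-value;
    Benjamini-Hochberg adjustment is applied across the sets of this query.
    Sets with no member in the universe are skipped with a warning.
    """
    universe = {strip_direction(w) for w in universe}
    if not universe:
        raise ValueError("empty gene universe")
    genes = {strip_direction(w) for w in word_list}
    if not genes:
        raise ValueError("empty query gene list")
    outside = genes - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")

    N, n = len(universe), len(genes)
    rows = []
    for name, members in collection.items():
        inset = members & universe
        if not inset:
            logger.warning("gene set %r has no member in the universe; skipped", name)
            continue
        Ks = len(inset)
        a = len(genes & inset)
        b = n - a
        c = Ks - a
        d = N - Ks - b
        p = float(hypergeom.sf(a - 1, N, Ks, n))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({
            "topic": topic, "slice": slice_index, "set": name,
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds, "p_raw": min(p, 1.0),
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adj"] = multipletests(result["p_raw"], method="fdr_bh")[1]
    return result
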