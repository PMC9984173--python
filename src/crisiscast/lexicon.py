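"""Candidate text-feature construction.

Three stages build the lexicon of food-insecurity text features:

* **seed expansion** — starting from the three initial seed phrases
  ("food insecurity", "hunger crisis", "famine"), rank corpus n-grams by
  word mover's distance (WMD) to the nearest seed and keep the closest
  ``keep_k``, with bigrams/trigrams required to contain "food" or "hunger";
* **the four-step semantic-frame filter** — keep frames with at least one
  "cause" and one "effect" role, whose effect constituent contains a seed
  phrase, and whose trigger is a causal link; then emit every unigram,
  bigram and trigram of the surviving cause/effect constituents;
* **keyword expansion** — add corpus n-grams whose WMD to an original
  feature is strictly below a cutoff (near-synonyms the frames missed).

WMD is the exact optimal-transport cost between the uniform bag-of-words
distributions of two token lists under the Euclidean ground metric,
solved as a linear program.  An n-gram is treated as a document of its
tokens, so phrases compare via transport rather than averaged vectors.
Out-of-vocabulary tokens are dropped before transport; a fully
out-of-vocabulary document has no defined distance.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from crisiscast.embeddings import EmbeddingTable

INITIAL_SEEDS = ("food insecurity", "hunger crisis", "famine")


class DistanceUndefinedError(ValueError):
    """A document is empty after out-of-vocabulary filtering."""


def _bag(tokens: Sequence[str], emb: EmbeddingTable) -> tuple[list[str], np.ndarray]:
    """Unique in-vocabulary words and their uniform-over-instances weights."""
    counts = Counter(t for t in tokens if t in emb)
    if not counts:
        raise DistanceUndefinedError(f"no in-vocabulary tokens in {list(tokens)!r}")
    words = sorted(counts)
    weights = np.array([counts[w] for w in words], dtype=float)
    return words, weights / weights.sum()


def wmd(doc_a: Sequence[str], doc_b: Sequence[str], emb: EmbeddingTable) -> float:
    """Exact word mover's distance between two token lists.

    Solves the transport LP ``min <C, P>`` subject to row sums ``a`` and
    column sums ``b`` with Euclidean costs ``C`` between word vectors.
    Symmetric; zero iff the (in-vocabulary) bags are identical.

    Raises
    ------
    DistanceUndefinedError
        If either document is empty after dropping out-of-vocabulary tokens.
    """
    words_a, wa = _bag(doc_a, emb)
    words_b, wb = _bag(doc_b, emb)
    if words_a == words_b and np.allclose(wa, wb):
        return 0.0
    cost = cdist(emb.matrix_for(words_a), emb.matrix_for(words_b))
    na, nb = len(words_a), len(words_b)
    if na == 1:
        return float(wb @ cost[0])
    if nb == 1:
        return float(wa @ cost[:, 0])
    # equality constraints: row sums = wa, column sums = wb (one redundant)
    a_eq = np.zeros((na + nb, na * nb))
    for i in range(na):
        a_eq[i, i * nb : (i + 1) * nb] = 1.0
    for j in range(nb):
        a_eq[na + j, j::nb] = 1.0
    res = linprog(
        cost.ravel(),
        A_eq=a_eq[:-1],  # drop one redundant constraint for numerical rank
        b_eq=np.concatenate([wa, wb])[:-1],
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - tiny LPs are always feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def min_distance_to_any(
    phrase: str, references: Iterable[str], emb: EmbeddingTable
) -> float:
    """Smallest WMD from ``phrase`` to any reference phrase (inf if undefined)."""
    best = np.inf
    toks = phrase.split()
    for ref in references:
        try:
            d = wmd(toks, ref.split(), emb)
        except DistanceUndefinedError:
            continue
        best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# seed expansion
# ---------------------------------------------------------------------------


def _multiword_allowed(phrase: str) -> bool:
    """Bigrams/trigrams must contain the word "food" or the word "hunger"."""
    toks = phrase.split()
    return len(toks) == 1 or ("food" in toks or "hunger" in toks)


def expand_seeds(
    initial: Sequence[str],
    candidates: Sequence[str],
    emb: EmbeddingTable,
    keep_k: int = 100,
) -> pd.DataFrame:
    """Expand the initial seed phrases with the closest corpus n-grams.

    Candidates are ranked by minimum WMD to any initial seed; the ``keep_k``
    closest are kept, ties broken lexicographically.  Bigrams and trigrams
    lacking both "food" and "hunger" are excluded regardless of distance,
    as are candidates with no defined distance (fully out of vocabulary).

    Returns a frame with columns ``phrase``, ``origin`` (initial|expanded)
    and ``distance`` (0 for initial seeds); initial seeds are always members.
    """
    if keep_k < 1:
        raise ValueError("keep_k must be >= 1")
    initial = list(dict.fromkeys(initial))
    rows = [(s, "initial", 0.0) for s in initial]
    scored: list[tuple[float, str]] = []
    seen = set(initial)
    for cand in dict.fromkeys(candidates):
        if cand in seen or not _multiword_allowed(cand):
            continue
        d = min_distance_to_any(cand, initial, emb)
        if np.isfinite(d):
            scored.append((d, cand))
    scored.sort(key=lambda t: (t[0], t[1]))
    rows += [(c, "expanded", d) for d, c in scored[:keep_k]]
    return pd.DataFrame(rows, columns=["phrase", "origin", "distance"])


# ---------------------------------------------------------------------------
# the four-step semantic-frame filter
# ---------------------------------------------------------------------------


def extract_ngrams(tokens: Sequence[str], max_n: int = 3) -> list[str]:
    """All contiguous 1..max_n-grams of a token sequence, in order."""
    out = []
    for n in range(1, max_n + 1):
        out += [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]
    return out


def _contains_phrase(tokens: list[str], phrase: str) -> bool:
    """Case-insensitive contiguous-token containment of ``phrase``."""
    needle = phrase.lower().split()
    hay = [t.lower() for t in tokens]
    k = len(needle)
    return any(hay[i : i + k] == needle for i in range(len(hay) - k + 1))


def select_frame_features(
    frames: Iterable[dict],
    seeds: Sequence[str],
    causal_links: Iterable[str],
    origin: str = "frame_news",
) -> pd.DataFrame:
    """Apply the four-step filter and emit candidate text features.

    In order: (1) keep frames whose constituent roles include at least one
    "cause" and one "effect"; (2) keep frames with a seed phrase inside an
    effect constituent (case-insensitive contiguous token match); (3) keep
    frames whose trigger is a causal link; (4) emit every unigram, bigram
    and trigram occurring in a cause or effect constituent of the
    surviving frames, deduplicated.

    The same operation serves news and scholarly frame streams; only the
    recorded ``origin`` differs.  Output is invariant to frame order and
    duplicate frames.
    """
    links = {str(x).lower() for x in causal_links}
    if not links:
        raise ValueError("causal_links must be non-empty")
    ngrams: set[str] = set()
    for frame in frames:
        cons = frame.get("constituents", [])
        roles = [str(c.get("role", "")).lower() for c in cons]
        if "cause" not in roles or "effect" not in roles:
            continue
        effect_tokens = [
            str(c["text"]).split() for c in cons if str(c.get("role", "")).lower() == "effect"
        ]
        if not any(_contains_phrase(toks, s) for toks in effect_tokens for s in seeds):
            continue
        if str(frame.get("trigger", "")).lower() not in links:
            continue
        for c in cons:
            if str(c.get("role", "")).lower() in ("cause", "effect"):
                ngrams.update(extract_ngrams(str(c["text"]).split()))
    return pd.DataFrame(
        {"ngram": sorted(ngrams), "origin": origin, "status": "candidate"}
    )


# ---------------------------------------------------------------------------
# keyword expansion
# ---------------------------------------------------------------------------


def corpus_ngram_counts(articles: Iterable[dict]) -> Counter:
    """Occurrence counts of every n-gram appearing in article token bags."""
    counts: Counter = Counter()
    for art in articles:
        counts.update(art["ngrams"])
    return counts


def expand_keywords(
    features: pd.DataFrame,
    corpus_counts: Counter,
    emb: EmbeddingTable,
    dist_max: float = 6.0,
    min_count: int = 1000,
) -> pd.DataFrame:
    """Add corpus n-grams semantically close to an original feature.

    Candidates are every corpus unigram plus bigrams/trigrams occurring
    strictly more than ``min_count`` times.  A candidate joins the feature
    list (origin ``expansion``) iff its WMD to some original feature is
    strictly below ``dist_max``.  Original features are never removed.
    """
    if dist_max <= 0:
        raise ValueError("dist_max must be positive")
    originals = list(features["ngram"])
    existing = set(originals)
    added = []
    for cand, count in sorted(corpus_counts.items()):
        if cand in existing:
            continue
        if len(cand.split()) > 1 and count <= min_count:
            continue
        d = min_distance_to_any(cand, originals, emb)
        if d < dist_max:
            added.append((cand, "expansion", "candidate"))
    out = pd.concat(
        [features, pd.DataFrame(added, columns=["ngram", "origin", "status"])],
        ignore_index=True,
    )
    return out.drop_duplicates(subset="ngram", keep="first").reset_index(drop=True)


def build_lexicon(
    frames: Iterable[dict],
    articles: Iterable[dict],
    emb: EmbeddingTable,
    seeds: Sequence[str] = INITIAL_SEEDS,
    causal_links: Iterable[str] = ("lead_to", "cause", "due_to", "result_in"),
    dist_max: float = 6.0,
    min_count: int = 100,
    scholarly_frames: Iterable[dict] | None = None,
) -> pd.DataFrame:
    """Frame filter + keyword expansion in one call (news and optional scholarly)."""
    feats = select_frame_features(frames, seeds, causal_links, origin="frame_news")
    if scholarly_frames is not None:
        extra = select_frame_features(
            scholarly_frames, seeds, causal_links, origin="frame_scholarly"
        )
        feats = (
            pd.concat([feats, extra], ignore_index=True)
            .drop_duplicates(subset="ngram", keep="first")
            .reset_index(drop=True)
        )
    counts = corpus_ngram_counts(articles)
    return expand_keywords(feats, counts, emb, dist_max=dist_max, min_count=min_count)
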