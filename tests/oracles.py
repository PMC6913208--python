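"""Independent brute-force oracles used to validate the fast implementations.

Everything here favors obviousness over speed: exhaustive enumeration for
chain CRF quantities and a plain re-derivation of greedy pair merging for
BPE.  These never call the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_chain(
    emission: np.ndarray,
    transition: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
):
    """All-path enumeration: log-partition, best path/score, marginals."""
    T, L = emission.shape
    scores = {}
    for path in itertools.product(range(L), repeat=T):
        s = start[path[0]] + stop[path[-1]]
        for t, y in enumerate(path):
            s += emission[t, y]
        for t in range(1, T):
            s += transition[path[t - 1], path[t]]
        scores[path] = s
    vals = np.array(list(scores.values()))
    m = vals.max()
    log_z = m + np.log(np.exp(vals - m).sum())
    # among co-optimal paths report the lexicographically smallest; callers
    # comparing paths use continuous random scores where ties are null
    best_path = min(
        (p for p, s in scores.items() if s == max(scores.values()))
    )
    best_score = scores[best_path]
    unary = np.zeros((T, L))
    pairwise = np.zeros((max(T - 1, 0), L, L))
    for path, s in scores.items():
        p = np.exp(s - log_z)
        for t, y in enumerate(path):
            unary[t, y] += p
        for t in range(1, T):
            pairwise[t - 1, path[t - 1], path[t]] += p
    return float(log_z), list(best_path), float(best_score), unary, pairwise


def bpe_reference(words: dict[str, int], n_merges: int, marker: str = "-"):
    """Plain re-derivation of greedy BPE training.

    Returns the ordered merge list and the final segmentation of every
    training word.  Pair counts are frequency-weighted and count each
    non-overlapping left-to-right occurrence; ties break on the smaller
    (left, right) string pair.
    """
    segs: dict[str, list[str]] = {
        w: [marker + w[0]] + list(w[1:]) for w in words
    }
    merges: list[tuple[str, str]] = []
    for _ in range(n_merges):
        counts: dict[tuple[str, str], int] = {}
        for w, pieces in segs.items():
            j = 0
            while j + 1 < len(pieces):
                pair = (pieces[j], pieces[j + 1])
                counts[pair] = counts.get(pair, 0) + words[w]
                if pieces[j] == pieces[j + 1]:
                    j += 2
                else:
                    j += 1
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = sorted(p for p, c in counts.items() if c == best_count)[0]
        merges.append(best)
        for w, pieces in segs.items():
            out: list[str] = []
            j = 0
            while j < len(pieces):
                if (
                    j + 1 < len(pieces)
                    and (pieces[j], pieces[j + 1]) == best
                ):
                    out.append(pieces[j] + pieces[j + 1])
                    j += 2
                else:
                    out.append(pieces[j])
                    j += 1
            segs[w] = out
    return merges, segs


def random_bio_sequence(rng: np.random.Generator, n: int,
                        categories: tuple[str, ...]) -> list[str]:
    """A random well-formed BIO sequence of length n."""
    labels = []
    i = 0
    while i < n:
        if rng.random() < 0.4:
            cat = categories[int(rng.integers(len(categories)))]
            run = min(int(rng.integers(1, 4)), n - i)
            labels.append(f"B-{cat}")
            labels.extend([f"I-{cat}"] * (run - 1))
            i += run
        else:
            labels.append("O")
            i += 1
    return labels
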