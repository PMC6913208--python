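"""Linear-chain CRF primitives.

Shared by the feature tagger and the neural decode head: stable
log-partition (forward algorithm), Viterbi decoding, unary/pairwise
marginals (forward-backward), and the negative log-likelihood with its
exact gradients.  Scores are plain NumPy arrays:

* ``emission``: ``(T, L)`` per-position label scores,
* ``transition``: ``(L, L)`` scores for label ``i`` followed by ``j``,
* optional ``start``/``stop``: ``(L,)`` boundary scores.

A path's score is ``start[y0] + sum_t emission[t, yt] +
sum_t transition[y_{t-1}, y_t] + stop[y_{T-1}]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = -1e30  # used instead of -inf to keep arithmetic NaN-free


def logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Stable log-sum-exp (local, loop-friendly: no dispatch overhead)."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True)) + m
    return out.item() if axis is None else np.squeeze(out, axis=axis)


@dataclass
class ChainScores:
    emission: np.ndarray
    transition: np.ndarray
    start: np.ndarray | None = None
    stop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.emission.ndim != 2:
            raise ValueError("emission must be (T, L)")
        T, L = self.emission.shape
        if T < 1:
            raise ValueError("empty sequence")
        if self.transition.shape != (L, L):
            raise ValueError("transition must be (L, L)")
        self.start = (
            np.zeros(L) if self.start is None else np.asarray(self.start, float)
        )
        self.stop = (
            np.zeros(L) if self.stop is None else np.asarray(self.stop, float)
        )


def log_partition(scores: ChainScores) -> float:
    """log sum over all label paths of exp(path score)."""
    alpha = scores.start + scores.emission[0]
    for t in range(1, scores.emission.shape[0]):
        alpha = (
            logsumexp(alpha[:, None] + scores.transition, axis=0)
            + scores.emission[t]
        )
    return float(logsumexp(alpha + scores.stop))


def viterbi(scores: ChainScores) -> tuple[list[int], float]:
    """Best label path and its score; ties resolve to the lowest index."""
    T, L = scores.emission.shape
    delta = scores.start + scores.emission[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + scores.transition  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)  # argmax picks lowest index on ties
        delta = cand[back[t], np.arange(L)] + scores.emission[t]
    delta = delta + scores.stop
    last = int(np.argmax(delta))
    best = float(delta[last])
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best


def marginals(scores: ChainScores) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward.

    Returns ``(unary, pairwise, logZ)`` where ``unary[t, y] = P(y_t = y)``
    and ``pairwise[t, i, j] = P(y_t = i, y_{t+1} = j)``.
    """
    T, L = scores.emission.shape
    alpha = np.zeros((T, L))
    alpha[0] = scores.start + scores.emission[0]
    for t in range(1, T):
        alpha[t] = (
            logsumexp(alpha[t - 1][:, None] + scores.transition, axis=0)
            + scores.emission[t]
        )
    beta = np.zeros((T, L))
    beta[T - 1] = scores.stop
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(
            scores.transition + (scores.emission[t + 1] + beta[t + 1])[None, :],
            axis=1,
        )
    log_z = float(logsumexp(alpha[T - 1] + scores.stop))
    unary = np.exp(alpha + beta - log_z)
    if T > 1:
        log_p = (
            alpha[:-1, :, None]
            + scores.transition[None, :, :]
            + (scores.emission[1:] + beta[1:])[:, None, :]
            - log_z
        )
        pairwise = np.exp(log_p)
    else:
        pairwise = np.zeros((0, L, L))
    return unary, pairwise, log_z


def path_score(scores: ChainScores, path: list[int]) -> float:
    T = scores.emission.shape[0]
    if len(path) != T:
        raise ValueError("path length mismatch")
    s = scores.start[path[0]] + scores.stop[path[-1]]
    s += sum(scores.emission[t, y] for t, y in enumerate(path))
    s += sum(
        scores.transition[path[t - 1], path[t]] for t in range(1, T)
    )
    return float(s)


def nll_and_gradient(
    scores: ChainScores, gold: list[int]
) -> tuple[float, dict[str, np.ndarray]]:
    """NLL = logZ − score(gold); gradients = marginals − gold indicators.

    Gradient keys: ``emission`` (T, L), ``transition`` (L, L), ``start``
    and ``stop`` (L,).
    """
    T, L = scores.emission.shape
    if any(not (0 <= y < L) for y in gold):
        raise ValueError("gold path contains an invalid label index")
    unary, pairwise, log_z = marginals(scores)
    nll = log_z - path_score(scores, gold)
    d_em = unary.copy()
    d_tr = pairwise.sum(axis=0) if T > 1 else np.zeros((L, L))
    d_start = unary[0].copy()
    d_stop = unary[-1].copy()
    for t, y in enumerate(gold):
        d_em[t, y] -= 1.0
    for t in range(1, T):
        d_tr[gold[t - 1], gold[t]] -= 1.0
    d_start[gold[0]] -= 1.0
    d_stop[gold[-1]] -= 1.0
    return float(nll), {
        "emission": d_em,
        "transition": d_tr,
        "start": d_start,
        "stop": d_stop,
    }


# ---------------------------------------------------------------------------
# BIO label sets and transition constraints
# ---------------------------------------------------------------------------


def bio_labels(categories: tuple[str, ...] | list[str]) -> list[str]:
    """``["O", "B-c1", "I-c1", ...]`` — 19 labels for the nine categories."""
    labels = ["O"]
    for c in categories:
        labels.extend([f"B-{c}", f"I-{c}"])
    return labels


def bio_transition_mask(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of allowed (transition, start) under the BIO grammar.

    ``I-X`` may only follow ``B-X`` or ``I-X`` and may not start a
    sequence; everything else is allowed.
    """
    L = len(labels)
    trans = np.ones((L, L), dtype=bool)
    start = np.ones(L, dtype=bool)
    for j, lab_j in enumerate(labels):
        if not lab_j.startswith("I-"):
            continue
        cat = lab_j[2:]
        start[j] = False
        for i, lab_i in enumerate(labels):
            if lab_i not in (f"B-{cat}", f"I-{cat}"):
                trans[i, j] = False
    return trans, start


def apply_bio_mask(scores: ChainScores, labels: list[str]) -> ChainScores:
    """Return a copy of ``scores`` with disallowed BIO moves set to -∞."""
    trans_ok, start_ok = bio_transition_mask(labels)
    transition = np.where(trans_ok, scores.transition, NEG_INF)
    start = np.where(start_ok, scores.start, NEG_INF)
    return ChainScores(scores.emission.copy(), transition, start, scores.stop.copy())
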