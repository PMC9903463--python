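"""Linear-chain conditional random field over IOB2 tag sequences.

The CRF scores a tag sequence :math:`y_{1..T}` for a sentence as

.. math::

    s(y) = \\text{start}_{y_1} + \\sum_t e_{t, y_t}
           + \\sum_t A_{y_t, y_{t+1}} + \\text{stop}_{y_T}

where ``e`` are per-token emission scores (from the recurrent encoder) and
``A`` is a learned tag-transition matrix.  Training maximizes the sequence
log-likelihood ``s(gold) - log Z``; the partition function ``Z`` is
computed by the forward recursion in log space, and its gradient by
forward-backward marginals.  Decoding is Viterbi, optionally hard-masked
so the output always satisfies the IOB2 constraints (I never opens a
sequence, O-I never occurs).

All computations run over the non-PAD tag block; ``lengths`` mask padding
out of both loss and decoding.  Scores are float64 and stable for inputs
in at least [-50, 50].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleDecodeError, ValidationError

NEG_INF = -1e30  # finite stand-in for -inf; keeps arithmetic NaN-free


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis=axis) + np.log(
        np.sum(np.exp(x - m), axis=axis)
    )


@dataclass
class CrfParameters:
    """Transition/start/stop scores over the K non-PAD tags."""

    transitions: np.ndarray  # (K, K) score of tag j following tag i
    start: np.ndarray        # (K,)
    stop: np.ndarray         # (K,)

    @classmethod
    def zeros(cls, n_tags: int) -> "CrfParameters":
        return cls(np.zeros((n_tags, n_tags)), np.zeros(n_tags), np.zeros(n_tags))

    @property
    def n_tags(self) -> int:
        return self.start.shape[0]


def _check(emissions: np.ndarray, lengths: np.ndarray) -> None:
    if emissions.ndim != 3:
        raise ValidationError("emissions must be (batch, time, tags)")
    if np.any(lengths < 1):
        raise ValidationError("every sentence must have at least 1 unmasked token")
    if np.any(lengths > emissions.shape[1]):
        raise ValidationError("length exceeds emission time dimension")


def log_partition(emissions: np.ndarray, lengths: np.ndarray,
                  params: CrfParameters) -> np.ndarray:
    """Per-sentence log Z by the forward recursion (batched, log space)."""
    emissions = np.asarray(emissions, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.int64)
    _check(emissions, lengths)
    B, T, K = emissions.shape
    alpha = params.start[None, :] + emissions[:, 0]          # (B, K)
    logZ = np.empty(B)
    done = lengths == 1
    logZ[done] = _logsumexp(alpha[done] + params.stop[None, :], axis=1)
    for t in range(1, T):
        active = lengths > t
        if not np.any(active):
            break
        nxt = _logsumexp(
            alpha[active][:, :, None] + params.transitions[None, :, :], axis=1
        ) + emissions[active, t]
        alpha[active] = nxt
        ending = active & (lengths == t + 1)
        if np.any(ending):
            logZ[ending] = _logsumexp(alpha[ending] + params.stop[None, :], axis=1)
    return logZ


def gold_score(emissions: np.ndarray, tags: np.ndarray, lengths: np.ndarray,
               params: CrfParameters) -> np.ndarray:
    """Per-sentence score of the gold tag path (direct summation)."""
    emissions = np.asarray(emissions, dtype=np.float64)
    tags = np.asarray(tags, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if tags.shape != emissions.shape[:2]:
        raise ValidationError("gold tags misaligned with emissions")
    B, T, _ = emissions.shape
    rows = np.arange(B)
    score = params.start[tags[:, 0]] + emissions[rows, 0, tags[:, 0]]
    for t in range(1, T):
        active = lengths > t
        score[active] += (
            params.transitions[tags[active, t - 1], tags[active, t]]
            + emissions[np.flatnonzero(active), t, tags[active, t]]
        )
    score += params.stop[tags[rows, lengths - 1]]
    return score


def _forward_backward(emissions, lengths, params):
    """Full alpha/beta lattices for marginal computation."""
    B, T, K = emissions.shape
    alpha = np.full((B, T, K), NEG_INF)
    alpha[:, 0] = params.start[None, :] + emissions[:, 0]
    for t in range(1, T):
        active = lengths > t
        if not np.any(active):
            break
        alpha[active, t] = _logsumexp(
            alpha[active, t - 1][:, :, None] + params.transitions[None], axis=1
        ) + emissions[active, t]
    beta = np.full((B, T, K), NEG_INF)
    beta[np.arange(B), lengths - 1] = params.stop[None, :]
    for t in range(T - 2, -1, -1):
        active = lengths > t + 1
        if not np.any(active):
            continue
        beta[active, t] = _logsumexp(
            params.transitions[None, :, :]
            + (emissions[active, t + 1] + beta[active, t + 1])[:, None, :],
            axis=2,
        )
    logZ = _logsumexp(alpha[np.arange(B), lengths - 1] + params.stop[None, :], axis=1)
    return alpha, beta, logZ


def negative_log_likelihood(
    emissions: np.ndarray,
    tags: np.ndarray,
    lengths: np.ndarray,
    params: CrfParameters,
    with_grad: bool = False,
):
    """Mean CRF loss ``log Z - s(gold)`` over the batch (always >= 0).

    With ``with_grad=True`` also returns the analytic gradients
    ``(d_emissions, d_transitions, d_start, d_stop)`` of the mean loss,
    computed from forward-backward marginals minus gold indicator counts.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    tags = np.asarray(tags, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    _check(emissions, lengths)
    B, T, K = emissions.shape
    alpha, beta, logZ = _forward_backward(emissions, lengths, params)
    score = gold_score(emissions, tags, lengths, params)
    losses = logZ - score
    loss = float(np.mean(losses))
    if not with_grad:
        return loss
    time_mask = np.arange(T)[None, :] < lengths[:, None]          # (B, T)
    # unary marginals P(y_t = k)
    log_unary = alpha + beta - logZ[:, None, None]
    unary = np.where(time_mask[:, :, None], np.exp(log_unary), 0.0)
    d_emissions = unary.copy()
    rows = np.arange(B)[:, None]
    cols = np.arange(T)[None, :]
    onehot = np.zeros_like(d_emissions)
    onehot[rows, cols, tags] = 1.0
    d_emissions -= np.where(time_mask[:, :, None], onehot, 0.0)
    d_emissions /= B
    # pairwise marginals P(y_t = i, y_{t+1} = j) for t+1 < length
    d_trans = np.zeros((K, K))
    for t in range(T - 1):
        active = lengths > t + 1
        if not np.any(active):
            break
        log_pair = (
            alpha[active, t][:, :, None]
            + params.transitions[None]
            + (emissions[active, t + 1] + beta[active, t + 1])[:, None, :]
            - logZ[active][:, None, None]
        )
        d_trans += np.exp(log_pair).sum(axis=0)
        np.subtract.at(d_trans, (tags[active, t], tags[active, t + 1]), 1.0)
    d_trans /= B
    d_start = (unary[:, 0].sum(axis=0) - np.bincount(tags[:, 0], minlength=K)) / B
    last = tags[np.arange(B), lengths - 1]
    d_stop = (
        unary[np.arange(B), lengths - 1].sum(axis=0)
        - np.bincount(last, minlength=K)
    ) / B
    return loss, (d_emissions, d_trans, d_start, d_stop)


def viterbi_decode(
    emissions: np.ndarray,
    lengths: np.ndarray,
    params: CrfParameters,
    allowed_transitions: np.ndarray | None = None,
    allowed_start: np.ndarray | None = None,
) -> tuple[list[list[int]], np.ndarray]:
    """Best tag sequence per sentence by (optionally constrained) Viterbi.

    ``allowed_transitions``/``allowed_start`` are boolean IOB2 feasibility
    masks; forbidden moves score ``-inf`` so the argmax path is always
    structurally valid.  Ties break toward the lowest tag index (argmax
    returns the first maximizer).  Raises :class:`InfeasibleDecodeError`
    when no feasible path exists.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.int64)
    _check(emissions, lengths)
    B, T, K = emissions.shape
    trans = params.transitions.copy()
    start = params.start.copy()
    if allowed_transitions is not None:
        trans = np.where(allowed_transitions, trans, NEG_INF)
    if allowed_start is not None:
        start = np.where(allowed_start, start, NEG_INF)
    delta = start[None, :] + emissions[:, 0]                  # (B, K)
    backptr = np.zeros((B, T, K), dtype=np.int64)
    for t in range(1, T):
        active = lengths > t
        if not np.any(active):
            break
        cand = delta[active][:, :, None] + trans[None]        # (b, from, to)
        backptr[active, t] = np.argmax(cand, axis=1)
        delta[active] = np.max(cand, axis=1) + emissions[active, t]
    paths: list[list[int]] = []
    best = np.empty(B)
    for b in range(B):
        L = int(lengths[b])
        final = delta[b] + params.stop
        if np.max(final) <= NEG_INF / 2:
            raise InfeasibleDecodeError(f"no feasible tag path for sentence {b}")
        tag = int(np.argmax(final))
        best[b] = float(final[tag])
        path = [tag]
        for t in range(L - 1, 0, -1):
            tag = int(backptr[b, t, tag])
            path.append(tag)
        paths.append(path[::-1])
    return paths, best
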