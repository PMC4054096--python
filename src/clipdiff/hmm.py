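"""Three-state HMM over per-cluster bin sequences.

Each CLIP cluster contributes one observation sequence; all sequences
share a single 3x3 transition matrix and the fixed mixture emissions
(state 0: stronger binding in condition 1; state 1: common; state 2:
stronger in condition 2). Training is Baum-Welch restricted to the
transition matrix — emissions and the uniform initial distribution are
never re-estimated — using the scaled forward-backward recursions with
expected transition counts pooled across sequences. Decoding is per-cluster
Viterbi in log space with a lowest-state-index tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_STATES = 3


def default_transitions() -> np.ndarray:
    """Initial transition matrix: diagonal 0.9, off-diagonal 0.05 —
    spatial persistence without bias toward any state."""
    return np.full((3, 3), 0.05) + np.eye(3) * 0.85


def uniform_initial() -> np.ndarray:
    return np.full(3, 1.0 / 3.0)


@dataclass
class HMMStopConfig:
    """Training stops at ``max_iterations`` or when every transition entry
    moves less than ``tolerance`` between successive iterations."""

    max_iterations: int = 100
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class HMMModel:
    transitions: np.ndarray = field(default_factory=default_transitions)
    initial_distribution: np.ndarray = field(default_factory=uniform_initial)

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        check_transition_matrix(self.transitions)
        if abs(self.initial_distribution.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")


@dataclass
class TrainResult:
    transitions: np.ndarray
    iterations_used: int
    converged: bool
    log_likelihood_trace: list[float]


def check_transition_matrix(pi: np.ndarray) -> None:
    if pi.shape != (N_STATES, N_STATES):
        raise ValueError("transition matrix must be 3x3")
    if (pi < 0).any() or np.abs(pi.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def _forward_backward(seq: np.ndarray, pi: np.ndarray, init: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for one emission-density sequence (L, 3).

    Returns (alpha, beta, scales, log_likelihood); alpha/beta carry the
    standard per-position normalization so posteriors are alpha * beta up
    to a row normalizer of 1.
    """
    L = seq.shape[0]
    alpha = np.empty((L, N_STATES))
    scales = np.empty(L)
    a = init * seq[0]
    scales[0] = a.sum()
    if scales[0] <= 0 or not np.isfinite(scales[0]):
        raise FloatingPointError("forward pass underflow at position 0")
    alpha[0] = a / scales[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ pi) * seq[t]
        scales[t] = a.sum()
        if scales[t] <= 0 or not np.isfinite(scales[t]):
            raise FloatingPointError(f"forward pass underflow at position {t}")
        alpha[t] = a / scales[t]
    beta = np.empty((L, N_STATES))
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (pi @ (seq[t + 1] * beta[t + 1])) / scales[t + 1]
    return alpha, beta, scales, float(np.sum(np.log(scales)))


def expected_transition_counts(seq: np.ndarray, pi: np.ndarray, init: np.ndarray
                               ) -> tuple[np.ndarray, float]:
    """Posterior expected transition counts for one sequence.

    xi[r, s] = sum_t Pr(I_t = r, I_{t+1} = s | sequence); returned with
    the sequence log-likelihood.
    """
    seq = np.asarray(seq, dtype=float)
    alpha, beta, scales, ll = _forward_backward(seq, pi, init)
    L = seq.shape[0]
    xi = np.zeros((N_STATES, N_STATES))
    for t in range(L - 1):
        xi += (alpha[t][:, None] * pi) * (seq[t + 1] * beta[t + 1])[None, :] / scales[t + 1]
    return xi, ll


def train_transitions(
    sequences: Sequence[np.ndarray],
    model: HMMModel | None = None,
    stop: HMMStopConfig | None = None,
) -> TrainResult:
    """Estimate the shared transition matrix from all cluster sequences.

    Each iteration pools expected transition counts over every sequence
    and renormalizes rows; emissions (already folded into the sequences as
    per-bin density triples) and the initial distribution stay fixed. A
    row whose state is never visited is reset to uniform with a warning.
    Stops when the largest entry change drops below ``stop.tolerance`` or
    at ``stop.max_iterations``.
    """
    model = model or HMMModel()
    stop = stop or HMMStopConfig()
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    if any(s.shape[0] == 0 for s in sequences):
        raise ValueError("every observation sequence must be non-empty")
    pi = model.transitions.copy()
    init = model.initial_distribution
    trace: list[float] = []
    if all(s.shape[0] < 2 for s in sequences):
        return TrainResult(pi, 0, True, trace)  # no transitions to estimate
    converged = False
    it = 0
    for it in range(1, stop.max_iterations + 1):
        counts = np.zeros((N_STATES, N_STATES))
        total_ll = 0.0
        for seq in sequences:
            if seq.shape[0] < 2:
                _, _, _, ll = _forward_backward(seq, pi, init)
                total_ll += ll
                continue
            xi, ll = expected_transition_counts(seq, pi, init)
            counts += xi
            total_ll += ll
        trace.append(total_ll)
        row_sums = counts.sum(axis=1, keepdims=True)
        new_pi = np.empty_like(pi)
        for r in range(N_STATES):
            if row_sums[r, 0] <= 0:
                logger.warning("state %d never visited; transition row reset to uniform", r)
                new_pi[r] = 1.0 / N_STATES
            else:
                new_pi[r] = counts[r] / row_sums[r, 0]
        delta = float(np.abs(new_pi - pi).max())
        pi = new_pi
        if delta < stop.tolerance:
            converged = True
            break
    logger.info("transition training: %d iterations, converged=%s, diagonal=%s",
                it, converged, np.round(np.diag(pi), 4).tolist())
    return TrainResult(pi, it, converged, trace)


def viterbi(seq: np.ndarray, model: HMMModel) -> np.ndarray:
    """Most probable state path for one emission-density sequence (L, 3).

    Dynamic program in log space; at every arg-max, ties break toward the
    lowest state index, making the decode deterministic.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.shape[0] == 0:
        raise ValueError("cannot decode an empty sequence")
    with np.errstate(divide="ignore"):
        log_e = np.log(seq)
        log_pi = np.log(model.transitions)
        log_init = np.log(model.initial_distribution)
    L = seq.shape[0]
    score = log_init + log_e[0]
    back = np.empty((L, N_STATES), dtype=np.int64)
    for t in range(1, L):
        cand = score[:, None] + log_pi  # cand[r, s]
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        score = cand[back[t], np.arange(N_STATES)] + log_e[t]
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = int(np.argmax(score))
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_all(sequences: Sequence[np.ndarray], model: HMMModel) -> list[np.ndarray]:
    """Independent Viterbi decode of every cluster sequence, in order."""
    return [viterbi(seq, model) for seq in sequences]
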