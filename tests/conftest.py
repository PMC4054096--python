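"""Shared fixtures: tiny hand-written SAM/FASTQ inputs and brute-force
HMM oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def sam_line(name, flag, chrom, pos1, cigar, seq, md=None, mapq=255):
    """One SAM record line; ``pos1`` is 1-based as in the format."""
    tags = f"\tMD:Z:{md}" if md is not None else ""
    return (f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t"
            f"{seq}\t{'I' * len(seq)}{tags}\n")


@pytest.fixture
def write_sam(tmp_path):
    def _write(lines, name="test.sam", header=SAM_HEADER):
        path = tmp_path / name
        path.write_text(header + "".join(lines))
        return str(path)
    return _write


@pytest.fixture
def write_fastq(tmp_path):
    def _write(seqs, name="test.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@read{i}\n{s}\n+\n{'I' * len(s)}\n")
        return str(path)
    return _write


# ---------------------------------------------------------------- HMM oracles

def enumerate_path_log_probs(seq, pi, init):
    """Log probability of every state path by exhaustive enumeration."""
    L = len(seq)
    out = {}
    for path in itertools.product(range(3), repeat=L):
        lp = np.log(init[path[0]]) + np.log(seq[0][path[0]])
        for t in range(1, L):
            lp += np.log(pi[path[t - 1], path[t]]) + np.log(seq[t][path[t]])
        out[path] = lp
    return out


def brute_force_viterbi(seq, pi, init):
    """(best_path, best_log_prob); ties broken toward the lexicographically
    smallest path, matching a lowest-state-index tie-break."""
    probs = enumerate_path_log_probs(seq, pi, init)
    best_lp = max(probs.values())
    best = min(p for p, lp in probs.items() if lp == best_lp)
    return np.array(best), best_lp


def brute_force_xi(seq, pi, init):
    """Posterior expected transition counts by summing over all 3^L paths."""
    probs = {p: np.exp(lp) for p, lp in enumerate_path_log_probs(seq, pi, init).items()}
    total = sum(probs.values())
    xi = np.zeros((3, 3))
    for path, pr in probs.items():
        for t in range(len(path) - 1):
            xi[path[t], path[t + 1]] += pr
    return xi / total


def random_hmm_instance(rng, L=None):
    """A random 3-state instance: emission densities, transitions, initial."""
    L = L or int(rng.integers(1, 7))
    seq = rng.uniform(0.05, 1.0, size=(L, 3))
    pi = rng.uniform(0.1, 1.0, size=(3, 3))
    pi /= pi.sum(axis=1, keepdims=True)
    init = rng.uniform(0.1, 1.0, size=3)
    init /= init.sum()
    return seq, pi, init
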