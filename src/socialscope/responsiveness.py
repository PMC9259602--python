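"""Shuffle-test classification of interaction-responsive neurons.

A neuron's coupling to a binary behavior vector b (1 during interaction
bouts of one stimulus) is measured by the similarity

    Sa = 2 (b . c) / (|b|^2 + |c|^2)

between b and its calcium trace c.  The null distribution Ss is built by
recomputing the similarity for random permutations of b (5000 by default);
the neuron is classified responsive when Sa is strictly greater than
99.95% of the Ss values.  Since a permutation preserves |b|^2, only the
dot product changes, which makes the test a single matrix product when one
set of permutations is shared across all neurons of a session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponsivenessResult",
    "similarity",
    "shuffle_test",
    "shuffle_test_population",
    "responsive_fraction",
    "behavior_vector",
]


@dataclass(frozen=True)
class ResponsivenessResult:
    """Outcome of the shuffle test for one neuron."""

    neuron_id: str
    sa: float
    percentile: float  # 100 x #{Ss < Sa} / n_shuffles
    responsive: bool
    n_shuffles: int
    seed: int | None
    ss_quantiles: tuple[float, ...] = ()  # (1%, 50%, 99%, 99.95%) summary


def behavior_vector(n_frames: int, bouts, stimulus: str) -> np.ndarray:
    """Per-frame 0/1 indicator of interaction with one stimulus."""
    b = np.zeros(n_frames)
    for bout in bouts:
        if bout.stimulus == stimulus:
            b[bout.start : bout.end] = 1.0
    return b


def similarity(b: np.ndarray, c: np.ndarray) -> float:
    """Sa = 2 (b . c) / (|b|^2 + |c|^2); 1 iff b == c, 0 on orthogonality."""
    b = np.asarray(b, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if b.shape != c.shape:
        raise ValueError(f"length mismatch: {b.size} vs {c.size}")
    denom = b @ b + c @ c
    if denom == 0:
        warnings.warn("similarity undefined: both vectors are zero")
        return float("nan")
    return float(2.0 * (b @ c) / denom)


def _shuffle_indices(
    n_frames: int, n_shuffles: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """Index matrix whose rows reorder the behavior vector.

    ``"permutation"`` draws unrestricted uniform permutations (the literal
    reading of random shuffling).  ``"circular"`` draws random cyclic
    rotations (a subgroup of the permutations) which preserve the temporal
    autocorrelation of the bout structure relative to the trace; this is
    the calibrated choice when traces are autocorrelated, because an
    unrestricted permutation destroys the correlation structure that the
    actual similarity Sa retains and therefore understates the null spread.
    """
    if mode == "permutation":
        idx = np.tile(np.arange(n_frames), (n_shuffles, 1))
        return rng.permuted(idx, axis=1)
    if mode == "circular":
        shifts = rng.integers(1, n_frames, size=n_shuffles)
        return (np.arange(n_frames)[None, :] - shifts[:, None]) % n_frames
    raise ValueError(f"unknown shuffle mode {mode!r}")


def shuffle_test_population(
    b: np.ndarray,
    traces: np.ndarray,
    neuron_ids: list[str] | None = None,
    n_shuffles: int = 5000,
    cutoff_pct: float = 99.95,
    seed: int | None = 0,
    shuffle: str = "permutation",
    chunk: int = 512,
) -> list[ResponsivenessResult]:
    """Run the shuffle test for all neurons with one shared permutation set.

    Sharing the random permutations of b across neurons is what the
    vectorized formulation requires (one (n_shuffles x frames) shuffled
    matrix against all traces); each neuron still gets its own Ss
    distribution because its trace differs.  Classification is strict:
    responsive iff Sa exceeds at least ``cutoff_pct`` percent of the Ss
    values, so a tie never passes.
    """
    b = np.asarray(b, dtype=float).ravel()
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    n_ones = int(np.count_nonzero(b))
    if n_ones == 0 or n_ones == b.size:
        raise ValueError("behavior vector must contain both zeros and ones")
    C = np.atleast_2d(np.asarray(traces, dtype=float))
    if C.shape[1] != b.size:
        raise ValueError(f"trace length {C.shape[1]} != behavior length {b.size}")
    n_neurons = C.shape[0]
    if neuron_ids is None:
        neuron_ids = [f"n{i:03d}" for i in range(n_neurons)]

    rng = np.random.default_rng(seed)
    idx = _shuffle_indices(b.size, n_shuffles, rng, shuffle)
    B_shuf = b[idx]  # (n_shuffles, frames); |b|^2 invariant under shuffling
    bb = b @ b

    results: list[ResponsivenessResult] = []
    for lo in range(0, n_neurons, chunk):
        Cc = C[lo : lo + chunk]
        cc = np.einsum("ij,ij->i", Cc, Cc)
        denom = bb + cc  # (chunk,)
        sa = 2.0 * (Cc @ b) / denom
        ss = 2.0 * (B_shuf @ Cc.T) / denom[None, :]  # (n_shuffles, chunk)
        count_less = (ss < sa[None, :]).sum(axis=0)
        pct = 100.0 * count_less / n_shuffles
        q = np.quantile(ss, [0.01, 0.5, 0.99, 0.9995], axis=0)
        for j in range(Cc.shape[0]):
            results.append(
                ResponsivenessResult(
                    neuron_id=neuron_ids[lo + j],
                    sa=float(sa[j]),
                    percentile=float(pct[j]),
                    responsive=bool(pct[j] >= cutoff_pct),
                    n_shuffles=n_shuffles,
                    seed=seed,
                    ss_quantiles=tuple(float(x) for x in q[:, j]),
                )
            )
    return results


def shuffle_test(
    b: np.ndarray,
    c: np.ndarray,
    n_shuffles: int = 5000,
    cutoff_pct: float = 99.95,
    seed: int | None = 0,
    shuffle: str = "permutation",
) -> ResponsivenessResult:
    """Shuffle test for a single neuron (see :func:`shuffle_test_population`)."""
    return shuffle_test_population(
        b, np.atleast_2d(c), n_shuffles=n_shuffles, cutoff_pct=cutoff_pct,
        seed=seed, shuffle=shuffle,
    )[0]


def responsive_fraction(results: list[ResponsivenessResult]) -> float:
    """Percent of recorded neurons classified responsive."""
    if not results:
        raise ValueError("no results")
    return 100.0 * sum(r.responsive for r in results) / len(results)
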