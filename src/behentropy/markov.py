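"""Jump-chain transition model and entropy rate.

Behavioral unpredictability is quantified on the *jump chain*: the sequence
of successive distinct behaviors, ignoring their durations. For a chain on
``k`` states with transition matrix ``P`` (structurally zero diagonal, since
a bout by definition ends when the behavior changes) and state weights ``w``,
the entropy rate is the weighted mean row entropy

    H = - sum_i w_i sum_j P_ij log_b P_ij,      0 log 0 := 0,

in units of the logarithm base ``b`` (bits for ``b = 2``). H is 0 for a
perfectly predictable (deterministic) chain and at most ``log_b (k - 1)``
when each behavior is followed by any of the other ``k - 1`` uniformly.

The model/results split follows the usual statistical-modeling idiom:
:class:`JumpChain` holds the data (bout sequences and ethogram) and
``fit()`` returns a :class:`TransitionModel` carrying counts, probabilities,
weights and derived quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .bouts import BoutSequence, segment_bouts
from .errors import (
    AnalysisError,
    NoTransitionsError,
    ParameterError,
)
from .ethogram import Ethogram
from .events import EventLog

_RESIDUAL_TOL = 1e-10


# ---------------------------------------------------------------------------
# functional layer

def count_transitions(
    sequences: list[BoutSequence], ethogram: Ethogram
) -> np.ndarray:
    """Count bout-to-bout transitions, pooled over sessions.

    ``N[i, j]`` is the number of adjacent bout pairs (behavior ``i`` then
    ``j``) within a session. Pairs never span a session boundary. Adjacent
    same-behavior bouts (which can only arise from unmerged gap-separated
    runs) are *not* transitions of the jump chain and are excluded, so the
    diagonal of ``N`` is always zero.
    """
    k = ethogram.k
    counts = np.zeros((k, k), dtype=np.int64)
    for seq in sequences:
        codes = [ethogram.code(b.behavior) for b in seq.bouts]
        for a, b in zip(codes, codes[1:]):
            if a != b:
                counts[a, b] += 1
    return counts


def estimate_transition_matrix(
    counts: np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """Row-normalize transition counts into conditional probabilities.

    With pseudocount ``a``, ``P[i, j] = (N[i, j] + a) / sum_{j != i}
    (N[i, j] + a)`` over the off-diagonal entries; ``a = 0`` is the maximum
    likelihood estimate. Rows with no outgoing transitions (and ``a = 0``)
    are left as NaN rather than normalized.
    """
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    if np.trace(counts) != 0:
        raise AnalysisError("transition counts have nonzero diagonal")
    if counts.sum() == 0 and pseudocount == 0:
        raise NoTransitionsError(
            "no transitions observed and pseudocount is 0"
        )
    off = ~np.eye(k, dtype=bool)
    work = counts + pseudocount * off
    row_sums = work.sum(axis=1)
    probs = np.full((k, k), np.nan)
    ok = row_sums > 0
    probs[ok] = work[ok] / row_sums[ok, None]
    probs[np.eye(k, dtype=bool)] = 0.0
    probs[~ok] = np.nan
    return probs


def empirical_weights(counts: np.ndarray) -> np.ndarray:
    """Source-state frequencies: ``w[i] =`` transitions out of ``i`` / total."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise NoTransitionsError("no transitions observed")
    return counts.sum(axis=1) / total


def stationary_distribution(probs: np.ndarray, tol: float = _RESIDUAL_TOL) -> np.ndarray:
    """Left fixed point ``w = wP`` of an exact row-stochastic matrix.

    ``P`` is restricted to its recurrent communicating classes: transient
    states receive weight 0. Raises :class:`AnalysisError` if there is more
    than one recurrent class (the long-run weights are then not unique) or
    if the fixed point cannot be solved to ``tol`` in L1 residual.
    """
    P = np.asarray(probs, dtype=float)
    k = P.shape[0]
    n_comp, labels = connected_components(
        csr_matrix(P > 0), directed=True, connection="strong"
    )
    # a recurrent class has no edge leaving it
    recurrent = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        outside = P[np.ix_(members, np.flatnonzero(labels != c))]
        if outside.size == 0 or not (outside > 0).any():
            recurrent.append(members)
    if len(recurrent) != 1:
        raise AnalysisError(
            f"chain has {len(recurrent)} recurrent classes; "
            "stationary weights are not unique"
        )
    members = recurrent[0]
    sub = P[np.ix_(members, members)]
    m = len(members)
    # solve w(P - I) = 0 with sum(w) = 1 by replacing one equation
    A = (sub - np.eye(m)).T
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    w_sub = np.linalg.solve(A, b)
    w = np.zeros(k)
    w[members] = w_sub
    residual = np.abs(w @ np.nan_to_num(P) - w).sum()
    if residual > tol or (w < -tol).any():
        raise AnalysisError(
            f"stationary solve failed: L1 residual {residual:.2e}"
        )
    return np.clip(w, 0.0, None) / w.sum()


def stationary_weights(
    counts: np.ndarray,
    probs: np.ndarray | None = None,
    method: str = "empirical",
) -> np.ndarray:
    """State weights for the entropy rate.

    ``empirical`` uses observed source-state frequencies and is robust on
    short, possibly non-irreducible observed chains. ``eigen`` solves the
    left fixed point of ``P`` (NaN rows treated as unreachable); if that
    fails (reducible chain, several recurrent classes) it falls back to the
    empirical weights with a warning. The two agree asymptotically.
    """
    if method == "empirical":
        return empirical_weights(counts)
    if method != "eigen":
        raise ParameterError(f"unknown weight method {method!r}")
    if probs is None:
        raise ParameterError("eigen weights require the probability matrix")
    P = np.array(probs, dtype=float)
    defined = ~np.isnan(P).any(axis=1)
    try:
        sub = P[np.ix_(defined, defined)]
        leak = P[defined].sum(axis=1) - sub.sum(axis=1)
        if (np.abs(leak) > 1e-12).any():
            raise AnalysisError(
                "transitions lead into states with undefined outgoing "
                "probabilities"
            )
        w_sub = stationary_distribution(sub)
        w = np.zeros(P.shape[0])
        w[defined] = w_sub
        return w
    except AnalysisError as exc:
        warnings.warn(
            f"eigen weights unavailable ({exc}); using empirical weights",
            stacklevel=2,
        )
        return empirical_weights(counts)


def entropy_rate(
    probs: np.ndarray, weights: np.ndarray, base: float = 2.0
) -> float:
    """Weighted mean row entropy of the jump chain, in units of ``base``."""
    if base <= 1:
        raise ParameterError(f"log base must exceed 1, got {base}")
    P = np.asarray(probs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ParameterError("weights must sum to 1")
    used = w > 0
    if np.isnan(P[used]).any():
        raise AnalysisError(
            "a state with positive weight has undefined transition "
            "probabilities"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P[used] > 0, P[used] * np.log(P[used]), 0.0)
    return float(-(w[used, None] * plogp).sum() / np.log(base))


def max_entropy_rate(k: int, base: float = 2.0) -> float:
    """Upper bound ``log_base(k - 1)`` for a diagonal-zero chain."""
    return float(np.log(k - 1) / np.log(base))


def simulate_jump_chain(
    probs: np.ndarray, n_steps: int, rng: np.random.Generator,
    initial: int | None = None,
) -> np.ndarray:
    """Sample a state-index path of length ``n_steps + 1`` from ``P``.

    Used for Monte-Carlo checks of closed-form entropies; the initial state
    defaults to a draw from the stationary distribution.
    """
    P = np.nan_to_num(np.asarray(probs, dtype=float))
    cum = P.cumsum(axis=1)
    if initial is None:
        w = stationary_distribution(np.asarray(probs, dtype=float))
        initial = int(np.searchsorted(np.cumsum(w), rng.random()))
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = initial
    u = rng.random(n_steps)
    s = initial
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t]))
        path[t + 1] = s
    return path


# ---------------------------------------------------------------------------
# model / results layer

class JumpChain:
    """Jump-chain model of a dam's bout sequences.

    Parameters
    ----------
    sequences
        Bout sequences (one per session) within the analysis scope.
    ethogram
        State space of the chain.
    """

    def __init__(self, sequences: list[BoutSequence], ethogram: Ethogram):
        self.sequences = list(sequences)
        self.ethogram = ethogram

    @classmethod
    def from_event_log(
        cls,
        log: EventLog,
        ethogram: Ethogram,
        phase: str | None = None,
        merge_gap: int = 0,
    ) -> "JumpChain":
        sessions = log.sessions_in_phase(phase)
        seqs = [segment_bouts(s, merge_gap=merge_gap) for s in sessions]
        return cls(seqs, ethogram)

    def fit(
        self, pseudocount: float = 0.0, weight_method: str = "empirical"
    ) -> "TransitionModel":
        """Estimate transition probabilities and state weights."""
        counts = count_transitions(self.sequences, self.ethogram)
        probs = estimate_transition_matrix(counts, pseudocount=pseudocount)
        weights = stationary_weights(counts, probs, method=weight_method)
        return TransitionModel(
            ethogram=self.ethogram,
            counts=counts,
            probs=probs,
            weights=weights,
            weight_method=weight_method,
            pseudocount=pseudocount,
        )


@dataclass
class TransitionModel:
    """Fitted transition model for one dam (or dam x phase).

    Attributes
    ----------
    counts
        ``k x k`` transition count matrix ``N`` (zero diagonal).
    probs
        Row-normalized conditional probabilities; rows with no outgoing
        transitions are NaN.
    weights
        State weights used for the entropy rate (sum to 1).
    """

    ethogram: Ethogram
    counts: np.ndarray
    probs: np.ndarray
    weights: np.ndarray
    weight_method: str = "empirical"
    pseudocount: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def entropy_rate(self, base: float = 2.0) -> float:
        key = ("H", base)
        if key not in self._cache:
            self._cache[key] = entropy_rate(self.probs, self.weights, base=base)
        return self._cache[key]

    def to_frame(self) -> pd.DataFrame:
        """Probability matrix as a labeled DataFrame (heat-map's numeric twin)."""
        labels = list(self.ethogram.labels)
        return pd.DataFrame(self.probs, index=labels, columns=labels)

    def simulate(
        self, n_steps: int, rng: np.random.Generator, initial: int | None = None
    ) -> np.ndarray:
        return simulate_jump_chain(self.probs, n_steps, rng, initial=initial)

    def plot_heatmap(self, ax=None, **kwargs):
        from .plotting import plot_transition_heatmap

        return plot_transition_heatmap(
            self.probs, self.ethogram.labels, ax=ax, **kwargs
        )

    def summary(self) -> str:
        lines = [
            "Jump-chain transition model",
            f"  states:        {self.ethogram.k}",
            f"  transitions:   {self.n_transitions}",
            f"  weight method: {self.weight_method}",
            f"  pseudocount:   {self.pseudocount}",
            f"  entropy rate:  {self.entropy_rate():.4f} bits "
            f"(max {max_entropy_rate(self.ethogram.k):.4f})",
            "",
            self.to_frame().round(3).to_string(),
        ]
        return "\n".join(lines)
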