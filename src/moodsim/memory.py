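"""Memory traces: emotion-weighted encoding, exponential forgetting,
deletion below a strength floor, refresh on retrieval, and mood-congruent
probabilistic recall.

Two surfaces are provided.  The reference surface works on explicit
:class:`Trace` objects (``encode_strength``, ``strength_at``, ``purge``,
``retrieve`` ...) and defines the semantics.  :class:`PairStore` /
:class:`AgentMemory` are column-oriented equivalents used by the engine so
that a society-scale run stays fast; a store query performs exactly the
same purge -> triangular-kernel Bernoulli -> refresh cycle, with one
uniform draw per surviving trace in storage order, so the two surfaces are
draw-for-draw interchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

__all__ = [
    "Trace",
    "MemoryParams",
    "encode_strength",
    "strength_at",
    "availability_duration",
    "purge",
    "retrieval_probability",
    "retrieve",
    "PairStore",
    "AgentMemory",
]

_EMPTY = np.empty(0, dtype=float)
_EMPTY_BOOL = np.empty(0, dtype=bool)


@dataclass
class Trace:
    """One remembered interaction.

    ``cooperation`` is the level the counterpart extended, ``emotion`` the
    emotion felt at encoding, ``initial_strength`` the encoding strength
    ``phi_0``, and ``encoded_at`` the round of the last encoding *or*
    refresh (decay is measured from there).  ``firsthand`` distinguishes a
    direct interaction from a broadcast gist.
    """

    counterpart_id: int
    cooperation: float
    emotion: float
    initial_strength: float
    encoded_at: int
    firsthand: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.cooperation <= 1.0:
            raise ValueError("cooperation must be in [0, 1]")
        if not -1.0 <= self.emotion <= 1.0:
            raise ValueError("emotion must be in [-1, 1]")
        if self.initial_strength <= 0:
            raise ValueError("initial_strength must be positive")


@dataclass(frozen=True)
class MemoryParams:
    """Per-agent memory parameters.

    forget_rate
        Exponential decay constant ``theta`` (per round), > 0.
    min_strength
        Deletion floor ``phi_min``; a trace whose strength falls below it
        is gone for good.
    grad_neg, grad_pos
        Encoding gradients ``k_N`` / ``k_P`` for negative and positive
        emotion; their ratio ``k_P / k_N`` is the emotional bias ``xi``.
    intercept
        Encoding strength ``c`` of an emotionally neutral event.
    mood_dependence
        Retrieval selectivity ``gamma`` >= 0; 0 retrieves everything,
        larger values restrict recall to traces whose stored emotion is
        close to the current mood.
    """

    forget_rate: float = 1e-2
    min_strength: float = 1.0
    grad_neg: float = 80.0
    grad_pos: float = 80.0
    intercept: float = 10.0
    mood_dependence: float = 1.0

    def __post_init__(self) -> None:
        if self.forget_rate <= 0:
            raise ValueError("forget_rate must be positive")
        if self.min_strength <= 0:
            raise ValueError("min_strength must be positive")
        if self.grad_neg <= 0 or self.grad_pos <= 0:
            raise ValueError("encoding gradients must be positive")
        if self.intercept <= 0:
            raise ValueError("intercept must be positive")
        if self.min_strength >= self.intercept:
            raise ValueError("min_strength must be below the encoding intercept")
        if self.mood_dependence < 0:
            raise ValueError("mood_dependence must be non-negative")

    @property
    def emotional_bias(self) -> float:
        """Bias ratio ``xi = k_P / k_N`` (> 1: positively biased)."""
        return self.grad_pos / self.grad_neg


def encode_strength(emotion: float, params: MemoryParams) -> float:
    """Initial strength of a trace as a function of the emotion felt.

    V-shaped in emotion: ``-k_N * e + c`` for ``e <= 0`` and
    ``k_P * e + c`` for ``e > 0``, so charged events are encoded more
    strongly than neutral ones and the two gradients implement the
    positive/negative bias.
    """
    if not -1.0 <= emotion <= 1.0:
        raise ValueError("emotion must be in [-1, 1]")
    if emotion <= 0:
        return -params.grad_neg * emotion + params.intercept
    return params.grad_pos * emotion + params.intercept


def strength_at(trace: Trace, t: int, params: MemoryParams) -> float:
    """Strength ``phi_0 * exp(-theta * elapsed)`` at round ``t``.

    Elapsed time runs from the last encoding or refresh.
    """
    if t < trace.encoded_at:
        raise ValueError("t precedes the trace's encoding time")
    return trace.initial_strength * math.exp(-params.forget_rate * (t - trace.encoded_at))


def availability_duration(phi0: float, params: MemoryParams) -> float:
    """Unrefreshed lifetime bound ``(1/theta) * ln(phi0 / phi_min)``.

    The trace survives exactly the rounds with elapsed time <= this bound.
    Used to label forgetting regimes: "perfect memory" when the bound at
    the weakest encoding exceeds the run length, "no memory" when the
    bound at the strongest encoding is below one round.
    """
    if phi0 < params.min_strength:
        raise ValueError("phi0 must be at least min_strength")
    return math.log(phi0 / params.min_strength) / params.forget_rate


def purge(traces: Iterable[Trace], t: int, params: MemoryParams) -> List[Trace]:
    """Drop every trace whose strength at ``t`` has fallen below the floor."""
    return [tr for tr in traces if strength_at(tr, t, params) >= params.min_strength]


def retrieval_probability(trace_emotion, mood, gamma):
    """Triangular mood-congruence kernel ``max(0, 1 - gamma * |e - nu|)``."""
    gamma_arr = np.asarray(gamma, dtype=float)
    if np.any(gamma_arr < 0):
        raise ValueError("gamma must be non-negative")
    e = np.asarray(trace_emotion, dtype=float)
    nu = np.asarray(mood, dtype=float)
    if np.any(np.abs(e) > 1.0) or np.any(np.abs(nu) > 1.0):
        raise ValueError("emotion and mood must be in [-1, 1]")
    p = np.maximum(0.0, 1.0 - gamma_arr * np.abs(e - nu))
    if p.ndim == 0:
        return float(p)
    return p


def retrieve(
    traces: Sequence[Trace],
    counterpart_id: int,
    mood: float,
    t: int,
    params: MemoryParams,
    rng: np.random.Generator,
) -> List[Trace]:
    """Mood-congruent recall of the traces about one counterpart.

    Filters to the counterpart, keeps each trace independently with the
    triangular-kernel probability (one uniform draw per trace, in storage
    order), and refreshes every retrieved trace by resetting its
    ``encoded_at`` to ``t`` (strength back to ``phi_0``).  The caller is
    expected to have purged the collection at ``t`` already.
    """
    gamma = params.mood_dependence
    retrieved: List[Trace] = []
    for tr in traces:
        if tr.counterpart_id != counterpart_id:
            continue
        p = retrieval_probability(tr.emotion, mood, gamma)
        if rng.random() < p:
            tr.encoded_at = t
            retrieved.append(tr)
    return retrieved


class PairStore:
    """Column-oriented traces one agent holds about one counterpart.

    Rows keep insertion order.  Alongside the trace fields each row
    carries its unrefreshed lifetime ``ln(phi0 / phi_min) / theta`` and
    the absolute round at which it expires; exponential decay against the
    deletion floor then reduces to an expiry comparison, and a refresh
    just re-anchors the expiry at the current round.  ``query`` purges
    expired rows in place, draws one uniform per surviving row against
    the triangular kernel, refreshes hits, and returns the retrieved
    cooperation levels.
    """

    _COLS = ("coop", "emotion", "phi0", "encoded_at", "lifetime", "expiry", "firsthand")

    __slots__ = _COLS + ("n", "min_expiry")

    def __init__(self) -> None:
        # columns are allocated lazily on the first append: most
        # (agent, counterpart) stores in a sparse society stay tiny
        for name in self._COLS:
            setattr(self, name, _EMPTY if name != "firsthand" else _EMPTY_BOOL)
        self.n = 0
        # lower bound on the earliest expiry; lets purge short-circuit
        # (refreshes only push expiries later, so the bound is safe)
        self.min_expiry = math.inf

    def _reserve(self, extra: int) -> None:
        need = self.n + extra
        cap = self.coop.shape[0]
        if need <= cap:
            return
        cap = max(cap, 32)
        while cap < need:
            cap *= 2
        for name in self._COLS:
            old = getattr(self, name)
            new = np.empty(cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def append(
        self,
        coop: float,
        emotion: float,
        phi0: float,
        t: float,
        params: MemoryParams,
        firsthand: bool = True,
    ) -> None:
        self._reserve(1)
        i = self.n
        self.coop[i] = coop
        self.emotion[i] = emotion
        self.phi0[i] = phi0
        self.encoded_at[i] = t
        life = math.log(phi0 / params.min_strength) / params.forget_rate
        self.lifetime[i] = life
        self.expiry[i] = t + life
        if t + life < self.min_expiry:
            self.min_expiry = t + life
        self.firsthand[i] = firsthand
        self.n = i + 1

    def extend_gists(self, coops: np.ndarray, ts: np.ndarray, params: MemoryParams) -> None:
        """Bulk-append secondhand gists (neutral emotion, intercept strength)."""
        k = coops.shape[0]
        if k == 0:
            return
        self._reserve(k)
        i, j = self.n, self.n + k
        self.coop[i:j] = coops
        self.emotion[i:j] = 0.0
        self.phi0[i:j] = params.intercept
        self.encoded_at[i:j] = ts
        life = math.log(params.intercept / params.min_strength) / params.forget_rate
        self.lifetime[i:j] = life
        self.expiry[i:j] = ts + life
        first = float(ts[0]) + life  # gist timestamps arrive in round order
        if first < self.min_expiry:
            self.min_expiry = first
        self.firsthand[i:j] = False
        self.n = j

    def _compact(self, alive: np.ndarray) -> None:
        m = int(alive.sum())
        if m == self.n:
            return
        for name in self._COLS:
            col = getattr(self, name)
            col[:m] = col[: self.n][alive]
        self.n = m

    def purge(self, t: float, params: MemoryParams = None) -> None:
        """Drop rows whose strength has decayed below the deletion floor."""
        if self.n == 0 or t <= self.min_expiry:
            return
        self._compact(self.expiry[: self.n] >= t)
        self.min_expiry = float(self.expiry[: self.n].min()) if self.n else math.inf

    def query(self, t: float, mood: float, params: MemoryParams, rng: np.random.Generator) -> np.ndarray:
        """Purge, then probabilistically retrieve; returns retrieved coops."""
        self.purge(t)
        n = self.n
        if n == 0:
            return _EMPTY
        p = 1.0 - params.mood_dependence * np.abs(self.emotion[:n] - mood)
        keep = rng.random(n) < p
        if not keep.any():
            return _EMPTY
        self.encoded_at[:n][keep] = t
        self.expiry[:n][keep] = t + self.lifetime[:n][keep]
        return self.coop[:n][keep]

    def traces(self, counterpart_id: int) -> List[Trace]:
        return [
            Trace(
                counterpart_id=counterpart_id,
                cooperation=float(self.coop[i]),
                emotion=float(self.emotion[i]),
                initial_strength=float(self.phi0[i]),
                encoded_at=int(self.encoded_at[i]),
                firsthand=bool(self.firsthand[i]),
            )
            for i in range(self.n)
        ]


class AgentMemory:
    """All traces of one agent, keyed by counterpart id."""

    __slots__ = ("stores",)

    def __init__(self) -> None:
        self.stores: dict[int, PairStore] = {}

    def store_for(self, counterpart_id: int) -> PairStore:
        store = self.stores.get(counterpart_id)
        if store is None:
            store = PairStore()
            self.stores[counterpart_id] = store
        return store

    def encode(
        self,
        counterpart_id: int,
        cooperation: float,
        emotion: float,
        t: float,
        params: MemoryParams,
        firsthand: bool = True,
    ) -> float:
        """Encode one trace; returns the initial strength assigned."""
        phi0 = encode_strength(emotion, params)
        self.store_for(counterpart_id).append(cooperation, emotion, phi0, t, params, firsthand)
        return phi0

    def retrieve_coop(
        self,
        counterpart_id: int,
        mood: float,
        t: float,
        params: MemoryParams,
        rng: np.random.Generator,
    ) -> np.ndarray:
        store = self.stores.get(counterpart_id)
        if store is None:
            return _EMPTY
        return store.query(t, mood, params, rng)

    def n_traces(self) -> int:
        return sum(store.n for store in self.stores.values())

    def all_traces(self) -> List[Trace]:
        out: List[Trace] = []
        for cid in sorted(self.stores):
            out.extend(self.stores[cid].traces(cid))
        return out
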