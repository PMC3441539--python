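"""Exact stochastic simulation (Gillespie direct method) of fragment rejoining.

Reaction channels over a :class:`~nhejsim.state_model.SystemState`:

* ``RECRUIT`` — one channel per FREE end, propensity ``k_f * n_E / V``;
* ``JOIN`` — one channel per unordered pair of distinct fragments with
  ``b_i`` and ``b_j`` BOUND ends, propensity ``(k_j / V) * b_i * b_j``
  (each bound-end pair is an elementary mass-action event);
* ``RELEASE`` — one channel per residue token, propensity ``k_r``.

The direct method draws an exponential waiting time at the total propensity
and picks the channel with a single uniform scanned against the cumulative
propensity in a fixed order: RECRUIT channels by (fragment id, end index),
JOIN channels by fragment-id pair (i < j), RELEASE channels by token id.
:func:`direct_method_step` evaluates that scan in O(n) per step using
per-fragment bound-end suffix sums instead of materialising the O(n^2)
JOIN list; :func:`select_channel` performs the literal scan over
:func:`enumerate_channels` and is the reference the fast path is tested
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .distributions import FragmentDistribution
from .state_model import (
    ContractError,
    EndStatus,
    SimParams,
    SystemState,
    apply_join,
    apply_recruitment,
    apply_release,
    site_capacity,
)

__all__ = [
    "Channel",
    "StalledStateError",
    "Trajectory",
    "build_initial_state",
    "direct_method_step",
    "enumerate_channels",
    "execute_channel",
    "rejoining_time",
    "select_channel",
    "simulate",
]

_KIND_ORDER = {"RECRUIT": 0, "JOIN": 1, "RELEASE": 2}


class StalledStateError(RuntimeError):
    """Total propensity is zero but more than one countable fragment remains."""


@dataclass(frozen=True)
class Channel:
    """A reaction channel: kind, target identifiers, propensity.

    ``target`` is ``(fragment_id, end_index)`` for RECRUIT, ``(id_i, id_j)``
    with ``id_i < id_j`` for JOIN, ``(residue_id,)`` for RELEASE.
    """

    kind: str
    target: Tuple[int, ...]
    propensity: float

    def sort_key(self):
        return (_KIND_ORDER[self.kind], self.target)


def enumerate_channels(state: SystemState, params: SimParams) -> List[Channel]:
    """Explicitly list every open reaction channel in the documented order."""
    channels: List[Channel] = []
    a_rec = params.recruit_propensity
    if a_rec > 0:
        for frag in state.fragments.values():
            for end, status in enumerate(frag.ends):
                if status is EndStatus.FREE:
                    channels.append(Channel("RECRUIT", (frag.id, end), a_rec))
    a_join = params.join_propensity
    if a_join > 0:
        frags = [f for f in state.fragments.values() if f.bound_count() > 0]
        for i, fi in enumerate(frags):
            bi = fi.bound_count()
            for fj in frags[i + 1 :]:
                channels.append(
                    Channel("JOIN", (fi.id, fj.id), a_join * bi * fj.bound_count())
                )
    if params.k_r > 0:
        for token_id in state.residues:
            channels.append(Channel("RELEASE", (token_id,), params.k_r))
    return channels


def select_channel(channels: Sequence[Channel], u: float) -> Channel:
    """Reference selection: scan the cumulative propensity with ``u`` in [0, a0)."""
    acc = 0.0
    for ch in channels:
        acc += ch.propensity
        if u < acc:
            return ch
    return channels[-1]  # guard against floating-point overrun


def _totals(state: SystemState, params: SimParams):
    """Per-class propensity totals plus the per-fragment bound-end counts."""
    frags = list(state.fragments.values())
    n_free = 0
    bounds = []
    b_sum = 0
    b_sq = 0
    for frag in frags:
        b = 0
        for status in frag.ends:
            if status is EndStatus.FREE:
                n_free += 1
            elif status is EndStatus.BOUND:
                b += 1
        bounds.append(b)
        b_sum += b
        b_sq += b * b
    a_recruit = n_free * params.recruit_propensity
    a_join = params.join_propensity * (b_sum * b_sum - b_sq) / 2.0
    a_release = len(state.residues) * params.k_r
    return frags, bounds, a_recruit, a_join, a_release


def direct_method_step(
    state: SystemState, params: SimParams, rng: np.random.Generator
) -> Tuple[float, Channel]:
    """One direct-method step: waiting time and chosen channel.

    Equivalent to drawing Exponential(a0) and scanning
    :func:`enumerate_channels` with a single uniform, computed in O(n).
    Raises :class:`StalledStateError` when no channel is open.
    """
    frags, bounds, a_recruit, a_join, a_release = _totals(state, params)
    a0 = a_recruit + a_join + a_release
    if a0 <= 0.0:
        raise StalledStateError("no open reaction channel (total propensity 0)")
    dt = rng.exponential(1.0 / a0)
    u = rng.random() * a0

    if u < a_recruit:
        a_rec = params.recruit_propensity
        for frag in frags:
            for end, status in enumerate(frag.ends):
                if status is EndStatus.FREE:
                    if u < a_rec:
                        return dt, Channel("RECRUIT", (frag.id, end), a_rec)
                    u -= a_rec
        # floating-point overrun: last FREE end
        for frag in reversed(frags):
            for end in range(frag.capacity - 1, -1, -1):
                if frag.ends[end] is EndStatus.FREE:
                    return dt, Channel("RECRUIT", (frag.id, end), a_rec)
    u -= a_recruit

    if u < a_join:
        a_pair = params.join_propensity
        jfrags = [(f, b) for f, b in zip(frags, bounds) if b > 0]
        suffix = 0
        suffixes = [0] * len(jfrags)
        for k in range(len(jfrags) - 1, -1, -1):
            suffixes[k] = suffix
            suffix += jfrags[k][1]
        chosen = None
        for k, (fi, bi) in enumerate(jfrags):
            block = a_pair * bi * suffixes[k]
            if u < block:
                for fj, bj in jfrags[k + 1 :]:
                    w = a_pair * bi * bj
                    if u < w:
                        chosen = Channel("JOIN", (fi.id, fj.id), w)
                        break
                    u -= w
                if chosen is None:  # overrun within the block
                    fj, bj = jfrags[-1]
                    chosen = Channel("JOIN", (fi.id, fj.id), a_pair * bi * bj)
                break
            u -= block
        if chosen is None:  # overrun across blocks
            fi, bi = jfrags[-2]
            fj, bj = jfrags[-1]
            chosen = Channel("JOIN", (fi.id, fj.id), a_pair * bi * bj)
        return dt, chosen
    u -= a_join

    token_ids = list(state.residues)
    idx = min(int(u / params.k_r), len(token_ids) - 1) if token_ids else -1
    if idx < 0:
        raise ContractError("selection fell through with no RELEASE channels")
    return dt, Channel("RELEASE", (token_ids[idx],), params.k_r)


def _lowest_bound_end(frag) -> int:
    for end, status in enumerate(frag.ends):
        if status is EndStatus.BOUND:
            return end
    raise ContractError(f"fragment {frag.id} has no BOUND end for a JOIN channel")


def execute_channel(state: SystemState, channel: Channel, params: SimParams) -> SystemState:
    """Apply the state update for a chosen channel (in place)."""
    if channel.kind == "RECRUIT":
        return apply_recruitment(state, *channel.target)
    if channel.kind == "JOIN":
        fa = state.fragments[channel.target[0]]
        fb = state.fragments[channel.target[1]]
        return apply_join(
            state, fa.id, _lowest_bound_end(fa), fb.id, _lowest_bound_end(fb), params
        )
    if channel.kind == "RELEASE":
        return apply_release(state, channel.target[0], params)
    raise ContractError(f"unknown channel kind {channel.kind!r}")


def build_initial_state(dist: FragmentDistribution, params: SimParams) -> SystemState:
    """Materialise the SSA state for an initial distribution (all ends FREE)."""
    dist.validate(params)
    state = SystemState()
    for length, count in dist.rows:
        capacity = site_capacity(length, params)
        for _ in range(count):
            state.add_fragment(length, [EndStatus.FREE] * capacity)
    return state


@dataclass
class Trajectory:
    """A time-stamped event log of one stochastic rejoining run.

    ``events`` holds ``(time, kind, fragment_count_after)`` with strictly
    increasing times and a non-increasing count column (the total fragment
    count, irreparables included). ``status`` is ``"completed"`` (countable
    fragments merged to one), ``"horizon"`` (t_max reached) or ``"stalled"``.
    """

    events: List[Tuple[float, str, int]]
    status: str
    final_state: SystemState
    m0_total: int
    m0_countable: int

    @property
    def join_count(self) -> int:
        return self.final_state.event_counts["JOIN"]

    @property
    def release_count(self) -> int:
        return self.final_state.event_counts["RELEASE"]

    def counts_at(self, times: Sequence[float]) -> np.ndarray:
        """Total fragment count at each query time (last event at or before t)."""
        times = np.asarray(times, dtype=float)
        if self.events:
            ev_t = np.array([e[0] for e in self.events])
            ev_c = np.array([e[2] for e in self.events])
        else:
            ev_t = np.empty(0)
            ev_c = np.empty(0, dtype=int)
        idx = np.searchsorted(ev_t, times, side="right")
        out = np.empty(times.shape, dtype=int)
        out[idx == 0] = self.m0_total
        mask = idx > 0
        out[mask] = ev_c[idx[mask] - 1]
        return out


def simulate(
    dist: FragmentDistribution, params: SimParams, seed
) -> Trajectory:
    """Run one SSA trajectory from ``dist`` until completion, horizon or stall.

    Completion means the countable fragments (capacity >= 1 at t = 0) have
    merged into a single fragment; residue release after the final join is
    not simulated, matching the fragment-count-based rejoining-time
    definition. Bit-identical trajectories are guaranteed for identical
    ``(dist, params, seed)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = build_initial_state(dist, params)
    m0_total = state.fragment_count
    m0_countable = state.countable_count
    events: List[Tuple[float, str, int]] = []
    status = "completed"
    countable = m0_countable
    while countable > 1:
        try:
            dt, channel = direct_method_step(state, params, rng)
        except StalledStateError:
            status = "stalled"
            break
        t_next = state.time + dt
        if params.t_max is not None and t_next > params.t_max:
            state.time = params.t_max
            status = "horizon"
            break
        state.time = t_next
        execute_channel(state, channel, params)
        if channel.kind == "JOIN":
            countable -= 1
        events.append((state.time, channel.kind, state.fragment_count))
    return Trajectory(events, status, state, m0_total, m0_countable)


def rejoining_time(trajectory: Trajectory) -> float:
    """Time of the (M0 - 1)-th join: initial countable fragments down to one.

    Defined only for completed trajectories; release events after the last
    join do not extend it. A single-fragment run rejoins at time 0.
    """
    if trajectory.status != "completed":
        raise ValueError(
            f"rejoining time undefined for a {trajectory.status!r} trajectory"
        )
    for time, kind, _ in reversed(trajectory.events):
        if kind == "JOIN":
            return time
    return 0.0
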