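"""Exact continuous-time Markov-chain oracle for small fragment systems.

For a handful of initial fragments the rejoining reaction network has a
small finite state space. This module enumerates it exhaustively
(breadth-first, using the same update rules and propensities as the
stochastic engine) and computes the exact mean rejoining time as the mean
first-passage time to the absorbing set — states with a single countable
fragment — by solving the standard linear system

    a0(s) * tau(s) - sum_t r(s -> t) * tau(t) = 1,    tau(absorbing) = 0.

States are canonicalised so fragment identity is irrelevant: a state is the
sorted tuple of fragment encodings ``(length, end codes)`` where each
tracked end is ``'F'`` (free), ``'B'`` (bound), ``'R'`` (blocked by a
short+short residue pair — one token per fragment covering every ``'R'``
end) or ``'r'`` (blocked by a one-sided residue; each ``'r'`` end carries
its own token). Ends are kept in order within a fragment.

This exact solver validates the SSA on small fixtures; at the scale of real
damage (hundreds of fragments) the state space is combinatorially
infeasible and the SSA is the tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .distributions import FragmentDistribution
from .gillespie import build_initial_state, enumerate_channels, execute_channel
from .state_model import ContractError, EndStatus, SimParams, SystemState

__all__ = [
    "StateSpace",
    "closed_form_two_short",
    "encode_state",
    "enumerate_state_space",
    "exact_mean_rejoining_time",
]

MAX_FRAGMENTS = 4  # exhaustive enumeration bound; beyond this use the SSA

_STATUS_CODE = {EndStatus.FREE: "F", EndStatus.BOUND: "B"}

StateKey = Tuple[Tuple[int, Tuple[str, ...]], ...]


def encode_state(state: SystemState) -> StateKey:
    """Canonical encoding: sorted fragments, per-end occupancy codes."""
    frags = []
    for frag in state.fragments.values():
        codes: List[str] = []
        for end, status in enumerate(frag.ends):
            if status is EndStatus.BLOCKED:
                kind = None
                for token in state.residues.values():
                    if token.fragment_id == frag.id and end in token.blocked_ends:
                        kind = token.kind
                        break
                if kind is None:
                    raise ContractError(
                        f"BLOCKED end ({frag.id}, {end}) without a residue token"
                    )
                codes.append(kind)
            else:
                codes.append(_STATUS_CODE[status])
        frags.append((frag.length, tuple(codes)))
    return tuple(sorted(frags))


def _decode_state(key: StateKey) -> SystemState:
    """Rebuild a concrete SystemState from a canonical encoding."""
    state = SystemState()
    for length, codes in key:
        ends = []
        for code in codes:
            ends.append(EndStatus.BLOCKED if code in ("R", "r") else
                        EndStatus.FREE if code == "F" else EndStatus.BOUND)
        frag = state.add_fragment(length, ends)
        r_ends = tuple(i for i, c in enumerate(codes) if c == "R")
        if r_ends:
            # a single short+short token covers every 'R' end of the fragment
            from .state_model import ResidueToken

            token = ResidueToken(state.next_residue_id, frag.id, r_ends, "R")
            state.residues[token.id] = token
            state.next_residue_id += 1
        for i, c in enumerate(codes):
            if c == "r":
                from .state_model import ResidueToken

                token = ResidueToken(state.next_residue_id, frag.id, (i,), "r")
                state.residues[token.id] = token
                state.next_residue_id += 1
    return state


def _countable(key: StateKey) -> int:
    return sum(1 for _, codes in key if codes)


@dataclass
class StateSpace:
    """Reachable canonical states, aggregated transition rates, absorbing set."""

    states: List[StateKey]
    index: Dict[StateKey, int]
    transitions: List[Dict[int, float]]  # per state: target index -> total rate
    absorbing: List[bool]

    @property
    def n_states(self) -> int:
        return len(self.states)


def enumerate_state_space(
    dist: FragmentDistribution, params: SimParams, max_fragments: int = MAX_FRAGMENTS
) -> StateSpace:
    """Breadth-first enumeration of every reachable canonical state.

    Absorption is defined on countable-fragment count == 1, matching the
    rejoining-time definition (residue release after the final join does
    not count towards first passage).
    """
    if dist.m0 > max_fragments:
        raise ValueError(
            f"{dist.m0} fragments exceed the exact-enumeration bound "
            f"({max_fragments}); use the stochastic engine"
        )
    initial = encode_state(build_initial_state(dist, params))
    states: List[StateKey] = [initial]
    index: Dict[StateKey, int] = {initial: 0}
    transitions: List[Dict[int, float]] = []
    absorbing: List[bool] = []
    frontier = [initial]
    while frontier:
        next_frontier: List[StateKey] = []
        for key in frontier:
            is_abs = _countable(key) <= 1
            absorbing.append(is_abs)
            out: Dict[int, float] = {}
            if not is_abs:
                base = _decode_state(key)
                for channel in enumerate_channels(base, params):
                    target = encode_state(
                        execute_channel(base.copy(), channel, params)
                    )
                    if target not in index:
                        index[target] = len(states)
                        states.append(target)
                        next_frontier.append(target)
                    j = index[target]
                    out[j] = out.get(j, 0.0) + channel.propensity
            transitions.append(out)
        frontier = next_frontier
    return StateSpace(states, index, transitions, absorbing)


def exact_mean_rejoining_time(
    dist: FragmentDistribution, params: SimParams, max_fragments: int = MAX_FRAGMENTS
) -> float:
    """Exact expected rejoining time via the first-passage linear system."""
    space = enumerate_state_space(dist, params, max_fragments)
    trans_idx = [i for i, a in enumerate(space.absorbing) if not a]
    if not trans_idx:
        return 0.0
    pos = {s: k for k, s in enumerate(trans_idx)}
    n = len(trans_idx)
    A = np.zeros((n, n))
    b = np.ones(n)
    for k, s in enumerate(trans_idx):
        out = space.transitions[s]
        a0 = sum(out.values())
        if a0 <= 0:
            raise ContractError(
                "non-absorbing state with zero outgoing rate (enumeration bug)"
            )
        A[k, k] = a0
        for j, rate in out.items():
            if not space.absorbing[j]:
                A[k, pos[j]] -= rate
    tau = np.linalg.solve(A, b)
    residual = np.max(np.abs(A @ tau - b)) / max(1.0, np.max(np.abs(b)))
    if residual > 1e-10:
        raise ContractError(f"first-passage solve residual {residual:.2e} > 1e-10")
    return float(tau[0])


def closed_form_two_short(params: SimParams) -> float:
    """Analytic mean rejoining time for two one-site (short) fragments.

    With per-end recruitment propensity a = k_f * n_E / V and pair joining
    propensity b = k_j / V, the chain (FREE, FREE) -> (BOUND, FREE) ->
    (BOUND, BOUND) -> joined has mean first-passage time
    1/(2a) + 1/a + 1/b = 3/(2a) + 1/b.
    """
    a = params.recruit_propensity
    b = params.join_propensity
    if a <= 0 or b <= 0:
        raise ValueError("closed form requires positive recruitment and joining rates")
    return 1.5 / a + 1.0 / b
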