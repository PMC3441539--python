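"""Domain types and deterministic update semantics for Ku-dependent fragment rejoining.

The model tracks a population of double-strand-break (DSB) fragments. Each
fragment long enough to bind the Ku heterodimer exposes one or two *tracked
ends*; repair protein is recruited to free ends, two protein-bound ends of
distinct fragments ligate into a longer fragment, and the protein residue
left at a junction involving a short partner must be released before the
blocked end(s) can recruit again.

Three irreversible reaction classes act on the state:

* **recruitment** — a FREE end becomes BOUND (protein arrives);
* **joining** — two BOUND ends of distinct fragments fuse; depending on the
  partners' binding-site capacities a residue token is created that blocks
  one or both ends of the product;
* **release** — a residue token is removed and the ends it blocked become
  FREE again.

All updates conserve total base-pair content and reduce the fragment count
only at join events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "ContractError",
    "EndStatus",
    "Fragment",
    "ResidueToken",
    "SimParams",
    "SystemState",
    "apply_join",
    "apply_recruitment",
    "apply_release",
    "site_capacity",
]


class ContractError(RuntimeError):
    """An internal precondition was violated (signals a bug, not bad input)."""


class EndStatus(Enum):
    FREE = "F"
    BOUND = "B"
    BLOCKED = "X"


@dataclass(frozen=True)
class SimParams:
    """Rate constants, length thresholds and simulation controls.

    Parameters
    ----------
    k_f
        Bimolecular recruitment rate constant (volume / time, per free end
        and per protein copy). The per-end recruitment propensity is
        ``k_f * n_E / V``.
    n_E
        Constant repair-protein (Ku) copy number. Ku is abundant in the
        nucleus, so the copy number is held fixed; users who think in
        pseudo-first-order terms set ``n_E = 1`` and fold the concentration
        into ``k_f``.
    k_j
        Bimolecular joining rate constant (volume / time). Each pair of
        bound ends on distinct fragments ligates with propensity ``k_j / V``.
    k_r
        First-order residue release rate (1 / time). Release of the Ku
        residue requires ubiquitylation or nuclease action and is the slow
        step of the cycle, hence the default an order of magnitude below
        the binding/joining constants.
    L_min
        Minimum fragment length (bp) able to hold one Ku; shorter fragments
        are irreparable by this pathway.
    L_c
        Critical length (bp) above which a fragment can hold two Ku
        simultaneously, one per end.
    V
        Nuclear volume in arbitrary consistent units; second-order
        propensities scale as 1/V.
    include_irreparable
        Comparison mode: accept initial fragments shorter than ``L_min``
        (they never react and set the plateau of the remaining-fragment
        kinetics).
    t_max
        Optional simulation horizon (time units); ``None`` runs to
        completion.
    """

    k_f: float = 1.0
    n_E: int = 1
    k_j: float = 1.0
    k_r: float = 0.1
    L_min: int = 20
    L_c: int = 42
    V: float = 1.0
    include_irreparable: bool = False
    t_max: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("k_f", "k_j", "k_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.V <= 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.n_E < 1:
            raise ValueError(f"n_E must be >= 1, got {self.n_E}")
        for name in ("L_min", "L_c"):
            value = getattr(self, name)
            if not isinstance(value, int):
                raise ValueError(f"{name} must be an integer, got {value!r}")
        if not 0 < self.L_min < self.L_c:
            raise ValueError(
                f"need 0 < L_min < L_c, got L_min={self.L_min}, L_c={self.L_c}"
            )
        if self.t_max is not None and self.t_max <= 0:
            raise ValueError(f"t_max must be > 0 when set, got {self.t_max}")

    @property
    def recruit_propensity(self) -> float:
        """Per-free-end recruitment propensity k_f * n_E / V."""
        return self.k_f * self.n_E / self.V

    @property
    def join_propensity(self) -> float:
        """Per bound-end-pair joining propensity k_j / V."""
        return self.k_j / self.V

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def site_capacity(length: int, params: SimParams) -> int:
    """Number of tracked Ku binding ends for a fragment of ``length`` bp.

    0 below ``L_min`` (cannot hold Ku at all), 1 between ``L_min`` and
    ``L_c`` (one end at a time), 2 at or above ``L_c`` (both ends
    simultaneously).
    """
    if not isinstance(length, (int,)) or isinstance(length, bool):
        raise ValueError(f"fragment length must be an integer, got {length!r}")
    if length < 1:
        raise ValueError(f"fragment length must be >= 1, got {length}")
    if length < params.L_min:
        return 0
    if length < params.L_c:
        return 1
    return 2


@dataclass
class Fragment:
    """A DNA piece with an integer length and per-end occupancy state.

    ``ends`` has one entry per tracked binding end (= ``site_capacity`` of
    the length at creation time). Capacity-1 fragments track a single end;
    the distal physical end becomes a real tracked end only when a join
    raises the product's capacity to 2. Capacity-0 fragments (irreparable)
    track no ends and never change state.
    """

    id: int
    length: int
    ends: list  # list[EndStatus], len == capacity

    @property
    def capacity(self) -> int:
        return len(self.ends)

    @property
    def countable(self) -> bool:
        """Fragments with at least one tracked end take part in rejoining."""
        return bool(self.ends)

    def bound_count(self) -> int:
        return sum(1 for s in self.ends if s is EndStatus.BOUND)

    def copy(self) -> "Fragment":
        return Fragment(self.id, self.length, list(self.ends))


@dataclass
class ResidueToken:
    """A Ku residue left at a junction, blocking recruitment on 1-2 ends.

    ``kind`` records the join that created it: ``"R"`` from a short+short
    join (a residue pair at the junction blocking the whole product) and
    ``"r"`` from a short+long join (blocking only the short partner's
    side). ``blocked_ends`` lists the owner fragment's tracked-end indices
    the token blocks; an R token on a product that is itself still short
    (capacity 1) blocks that single tracked end. One release event removes
    the token and frees every end it blocks.
    """

    id: int
    fragment_id: int
    blocked_ends: tuple
    kind: str  # "R" | "r"

    def copy(self) -> "ResidueToken":
        return ResidueToken(self.id, self.fragment_id, self.blocked_ends, self.kind)


@dataclass
class SystemState:
    """The full stochastic-simulation state: fragments, residues, clock, tallies."""

    fragments: dict = field(default_factory=dict)  # id -> Fragment, id-ordered
    residues: dict = field(default_factory=dict)  # id -> ResidueToken, id-ordered
    time: float = 0.0
    event_counts: dict = field(
        default_factory=lambda: {"RECRUIT": 0, "JOIN": 0, "RELEASE": 0}
    )
    next_fragment_id: int = 0
    next_residue_id: int = 0

    def add_fragment(self, length: int, ends: Iterable[EndStatus]) -> Fragment:
        frag = Fragment(self.next_fragment_id, length, list(ends))
        self.fragments[frag.id] = frag
        self.next_fragment_id += 1
        return frag

    @property
    def total_length(self) -> int:
        return sum(f.length for f in self.fragments.values())

    @property
    def fragment_count(self) -> int:
        return len(self.fragments)

    @property
    def countable_count(self) -> int:
        return sum(1 for f in self.fragments.values() if f.countable)

    def copy(self) -> "SystemState":
        return SystemState(
            fragments={i: f.copy() for i, f in self.fragments.items()},
            residues={i: t.copy() for i, t in self.residues.items()},
            time=self.time,
            event_counts=dict(self.event_counts),
            next_fragment_id=self.next_fragment_id,
            next_residue_id=self.next_residue_id,
        )


def apply_recruitment(state: SystemState, fragment_id: int, end_index: int) -> SystemState:
    """Bind repair protein to a FREE end (in place; returns ``state``)."""
    frag = state.fragments.get(fragment_id)
    if frag is None:
        raise ContractError(f"recruitment on unknown fragment {fragment_id}")
    if not 0 <= end_index < frag.capacity:
        raise ContractError(
            f"fragment {fragment_id} has no end {end_index} (capacity {frag.capacity})"
        )
    if frag.ends[end_index] is not EndStatus.FREE:
        raise ContractError(
            f"recruitment on non-FREE end {end_index} of fragment {fragment_id} "
            f"({frag.ends[end_index].name})"
        )
    frag.ends[end_index] = EndStatus.BOUND
    state.event_counts["RECRUIT"] += 1
    return state


def _surviving_token(state: SystemState, fragment_id: int, end_index: int):
    """Find the residue token blocking (fragment_id, end_index), if any."""
    for token in state.residues.values():
        if token.fragment_id == fragment_id and end_index in token.blocked_ends:
            return token
    return None


def apply_join(
    state: SystemState,
    frag_a: int,
    end_a: int,
    frag_b: int,
    end_b: int,
    params: SimParams,
) -> SystemState:
    """Ligate two BOUND ends of distinct fragments (in place; returns ``state``).

    Residue rule, by the partners' capacities *before* the join:

    * both capacity 1 — the product starts fully BLOCKED by a single R
      token (the residue pair sits at the junction, within reach of every
      tracked end of the still-short or just-critical product);
    * exactly one capacity 1 — the product has capacity 2; its end on the
      short partner's side starts BLOCKED by an r token, while the long
      partner's non-joining end status (FREE / BOUND / BLOCKED, with any
      surviving r token) carries over;
    * both capacity 2 — no new residue; the two non-joining end statuses
      (and surviving r tokens) carry over.
    """
    if frag_a == frag_b:
        raise ValueError("cannot join a fragment to itself (no circularization)")
    fa = state.fragments.get(frag_a)
    fb = state.fragments.get(frag_b)
    if fa is None or fb is None:
        raise ContractError(f"join on unknown fragment(s) {frag_a}, {frag_b}")
    for frag, end in ((fa, end_a), (fb, end_b)):
        if not 0 <= end < frag.capacity:
            raise ContractError(f"fragment {frag.id} has no end {end}")
        if frag.ends[end] is not EndStatus.BOUND:
            raise ContractError(
                f"join on non-BOUND end {end} of fragment {frag.id} "
                f"({frag.ends[end].name})"
            )

    new_length = fa.length + fb.length
    new_capacity = site_capacity(new_length, params)

    cap_a, cap_b = fa.capacity, fb.capacity
    new_id = state.next_fragment_id

    if cap_a == 1 and cap_b == 1:
        ends = [EndStatus.BLOCKED] * new_capacity
        token = ResidueToken(
            state.next_residue_id, new_id, tuple(range(new_capacity)), "R"
        )
        state.residues[token.id] = token
        state.next_residue_id += 1
    elif cap_a == 2 and cap_b == 2:
        # end 0 inherits from partner a, end 1 from partner b
        ends = [fa.ends[1 - end_a], fb.ends[1 - end_b]]
        for new_end, (frag, end) in enumerate(((fa, 1 - end_a), (fb, 1 - end_b))):
            if frag.ends[end] is EndStatus.BLOCKED:
                token = _surviving_token(state, frag.id, end)
                if token is None:
                    raise ContractError(
                        f"BLOCKED end ({frag.id}, {end}) has no residue token"
                    )
                token.fragment_id = new_id
                token.blocked_ends = (new_end,)
    else:
        short, long_ = (fa, fb) if cap_a == 1 else (fb, fa)
        long_end = end_a if long_ is fa else end_b
        inherited = long_.ends[1 - long_end]
        # end 0 = short partner's side (junction residue), end 1 = long side
        ends = [EndStatus.BLOCKED, inherited]
        token = ResidueToken(state.next_residue_id, new_id, (0,), "r")
        state.residues[token.id] = token
        state.next_residue_id += 1
        if inherited is EndStatus.BLOCKED:
            surv = _surviving_token(state, long_.id, 1 - long_end)
            if surv is None:
                raise ContractError(
                    f"BLOCKED end ({long_.id}, {1 - long_end}) has no residue token"
                )
            surv.fragment_id = new_id
            surv.blocked_ends = (1,)

    del state.fragments[frag_a]
    del state.fragments[frag_b]
    state.add_fragment(new_length, ends)
    state.event_counts["JOIN"] += 1
    return state


def apply_release(state: SystemState, residue_id: int, params: SimParams) -> SystemState:
    """Remove a residue token; every end it blocked becomes FREE (in place)."""
    token = state.residues.pop(residue_id, None)
    if token is None:
        raise ContractError(f"release of unknown residue token {residue_id}")
    frag = state.fragments.get(token.fragment_id)
    if frag is None:
        raise ContractError(
            f"residue token {residue_id} owned by unknown fragment {token.fragment_id}"
        )
    for end in token.blocked_ends:
        if frag.ends[end] is not EndStatus.BLOCKED:
            raise ContractError(
                f"token {residue_id} blocks end ({frag.id}, {end}) "
                f"but its status is {frag.ends[end].name}"
            )
        frag.ends[end] = EndStatus.FREE
    state.event_counts["RELEASE"] += 1
    return state
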