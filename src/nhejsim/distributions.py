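"""Initial fragment-length distributions: generators, radiation presets, TSV I/O.

The initial condition of a rejoining simulation is a table of (length,
count) pairs. In default mode every length is at least ``L_min`` — only
fragments able to bind Ku are counted. In comparison mode (against foci
data) sub-``L_min`` fragments are kept as irreparable spectators; they
never react and set the plateau of the remaining-fragment kinetics.

Radiation-quality presets encode the two-class picture of fragment spectra:
high-LET Fe ions deposit energy in dense track cores and produce a large
short-fragment fraction (30%), while sparsely ionising gamma rays produce
almost exclusively long fragments (3% short). Class counts are apportioned
deterministically (half-up rounding, remainder to the long class) so preset
fractions are exact, not stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .state_model import SimParams, site_capacity

__all__ = [
    "PRESETS",
    "FragmentDistribution",
    "add_irreparable",
    "fixed_length",
    "fraction_pair",
    "preset",
    "read_distribution",
    "two_class",
    "uniform_random",
    "write_distribution",
]

#: Short-fragment and irreparable fractions for the two radiation-quality
#: presets. The short fractions are the two-class spectra for 1 Gy of each
#: quality; the irreparable fractions (used only in comparison mode) keep
#: the same ~10x high/low-LET ratio.
PRESETS = {
    "fe_ion": {"p_short": 0.30, "p_irr": 0.10},
    "gamma": {"p_short": 0.03, "p_irr": 0.01},
}

DEFAULT_LONG_MAX = 3000  # bp, upper bound of the long-fragment sampling range


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FragmentDistribution:
    """A (length, count) table; the simulation's initial condition.

    ``rows`` is sorted by length with unique positive-integer lengths and
    positive-integer counts.
    """

    rows: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("a fragment distribution needs at least one row")
        seen = set()
        for length, count in self.rows:
            if not isinstance(length, int) or isinstance(length, bool) or length < 1:
                raise ValueError(f"length must be a positive integer, got {length!r}")
            if not isinstance(count, int) or isinstance(count, bool) or count < 1:
                raise ValueError(f"count must be a positive integer, got {count!r}")
            if length in seen:
                raise ValueError(f"duplicate length {length}")
            seen.add(length)
        object.__setattr__(self, "rows", tuple(sorted(self.rows)))

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "FragmentDistribution":
        """Aggregate a flat sequence of fragment lengths into a table."""
        counts: dict = {}
        for n in lengths:
            n = int(n)
            counts[n] = counts.get(n, 0) + 1
        return cls(tuple(sorted(counts.items())))

    @property
    def m0(self) -> int:
        """Total number of fragments."""
        return sum(c for _, c in self.rows)

    @property
    def total_length(self) -> int:
        return sum(n * c for n, c in self.rows)

    @property
    def mean_length(self) -> float:
        return self.total_length / self.m0

    @property
    def min_length(self) -> int:
        return self.rows[0][0]

    def lengths(self) -> np.ndarray:
        """Expand to one entry per fragment."""
        return np.repeat(
            [n for n, _ in self.rows], [c for _, c in self.rows]
        ).astype(int)

    def countable_count(self, params: SimParams) -> int:
        return sum(c for n, c in self.rows if n >= params.L_min)

    def irreparable_count(self, params: SimParams) -> int:
        return sum(c for n, c in self.rows if n < params.L_min)

    def short_count(self, params: SimParams) -> int:
        """Fragments with one binding site: L_min <= length < L_c."""
        return sum(c for n, c in self.rows if params.L_min <= n < params.L_c)

    def validate(self, params: SimParams) -> None:
        """Check mode-dependent invariants against the given parameters."""
        if not params.include_irreparable and self.min_length < params.L_min:
            raise ValueError(
                f"length {self.min_length} < L_min={params.L_min}: such fragments "
                "cannot recruit Ku; enable include_irreparable for comparison mode"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["length", "count"])


def write_distribution(dist: FragmentDistribution, path) -> None:
    """Write the two-column tab-separated table (header ``length<TAB>count``)."""
    dist.to_frame().to_csv(path, sep="\t", index=False)


def read_distribution(path) -> FragmentDistribution:
    """Read a distribution written by :func:`write_distribution`."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    expected = ["length", "count"]
    if list(table.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(table.columns)}"
        )
    rows = tuple(
        (int(r.length), int(r.count)) for r in table.itertuples(index=False)
    )
    return FragmentDistribution(rows)


def fixed_length(
    m0: int, n: int, params: Optional[SimParams] = None
) -> FragmentDistribution:
    """``m0`` fragments all of length ``n`` bp (the mean-length experiments)."""
    params = params or SimParams()
    if m0 < 1:
        raise ValueError(f"m0 must be >= 1, got {m0}")
    dist = FragmentDistribution(((int(n), int(m0)),))
    dist.validate(params)
    return dist


def uniform_random(
    k_species: int,
    length_range: Tuple[int, int],
    count_range: Tuple[int, int],
    seed,
    params: Optional[SimParams] = None,
) -> FragmentDistribution:
    """``k_species`` distinct lengths and per-length counts, both uniform.

    Lengths are drawn without replacement from the inclusive integer
    ``length_range``; counts independently from the inclusive
    ``count_range``. Reproducible by seed.
    """
    params = params or SimParams()
    lo, hi = int(length_range[0]), int(length_range[1])
    clo, chi = int(count_range[0]), int(count_range[1])
    if k_species < 1:
        raise ValueError("k_species must be >= 1")
    width = hi - lo + 1
    if width < k_species:
        raise ValueError(
            f"length range [{lo}, {hi}] holds {width} integers < k_species={k_species}"
        )
    if clo < 1 or chi < clo:
        raise ValueError(f"invalid count range [{clo}, {chi}]")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(np.arange(lo, hi + 1), size=k_species, replace=False)
    counts = rng.integers(clo, chi + 1, size=k_species)
    dist = FragmentDistribution(
        tuple((int(n), int(c)) for n, c in zip(sorted(lengths), counts))
    )
    dist.validate(params)
    return dist


def _uniform_lengths(rng, n, lo, hi):
    if n == 0:
        return []
    if lo > hi:
        raise ValueError(f"empty length range [{lo}, {hi}]")
    return [int(x) for x in rng.integers(lo, hi + 1, size=n)]


def two_class(
    m0: int,
    p_short: float,
    seed,
    short_range: Optional[Tuple[int, int]] = None,
    long_range: Optional[Tuple[int, int]] = None,
    params: Optional[SimParams] = None,
) -> FragmentDistribution:
    """Two-class radiation spectrum: a short fraction and a long remainder.

    Exactly ``round(m0 * p_short)`` fragments are short (one binding site,
    lengths uniform in ``short_range`` ⊂ [L_min, L_c)); the rest are long
    (two sites, uniform in ``long_range`` ⊂ [L_c, ∞)). The class split is
    deterministic given ``m0`` and ``p_short``; only lengths are sampled.
    """
    params = params or SimParams()
    if not 0.0 <= p_short <= 1.0:
        raise ValueError(f"p_short must be in [0, 1], got {p_short}")
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    short_range = short_range or (params.L_min, params.L_c - 1)
    long_range = long_range or (params.L_c, DEFAULT_LONG_MAX)
    if not (params.L_min <= short_range[0] <= short_range[1] < params.L_c):
        raise ValueError(
            f"short_range {short_range} must lie within [L_min={params.L_min}, "
            f"L_c={params.L_c})"
        )
    if not (params.L_c <= long_range[0] <= long_range[1]):
        raise ValueError(f"long_range {long_range} must lie within [L_c={params.L_c}, inf)")
    n_short = _round_half_up(m0 * p_short)
    rng = np.random.default_rng(seed)
    lengths = _uniform_lengths(rng, n_short, *short_range)
    lengths += _uniform_lengths(rng, m0 - n_short, *long_range)
    dist = FragmentDistribution.from_lengths(lengths)
    dist.validate(params)
    return dist


def preset(
    name: str,
    m0: int,
    seed,
    params: Optional[SimParams] = None,
    include_irreparable: bool = False,
) -> FragmentDistribution:
    """Radiation-quality preset ('fe_ion' or 'gamma').

    With ``include_irreparable`` the preset's irreparable fraction of
    sub-``L_min`` fragments is appended for comparison-mode kinetics.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = params or SimParams()
    spec = PRESETS[name]
    dist = two_class(m0, spec["p_short"], seed, params=params)
    if include_irreparable:
        dist = add_irreparable(
            dist,
            spec["p_irr"],
            seed=np.random.SeedSequence((_seed_entropy(seed), 1)),
            params=params.with_(include_irreparable=True),
        )
    return dist


def _seed_entropy(seed) -> int:
    if isinstance(seed, (tuple, list)):
        seed = np.random.SeedSequence(tuple(seed))
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, dtype=np.uint64)[0] % (2**31))
    return int(seed)


def fraction_pair(
    m0: int,
    q1: float,
    q2: float,
    seed,
    params: Optional[SimParams] = None,
    long_max: int = DEFAULT_LONG_MAX,
) -> FragmentDistribution:
    """Distribution with prescribed fractions of the two short sub-classes.

    The short range [L_min, L_c) is split at ``ceil(L_c / 2)``: fragments
    below the split cannot reach ``L_c`` even pairwise among themselves,
    those above can. ``q1`` is the fraction in [L_min, ceil(L_c/2)), ``q2``
    in [ceil(L_c/2), L_c); the remainder is long, uniform in
    [L_c, long_max]. Class counts are deterministic (half-up rounding,
    remainder to the long class); lengths are seeded.
    """
    params = params or SimParams()
    if q1 < 0 or q2 < 0 or q1 + q2 > 1 + 1e-12:
        raise ValueError(f"need q1, q2 >= 0 and q1 + q2 <= 1, got ({q1}, {q2})")
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    split = math.ceil(params.L_c / 2)
    n1 = _round_half_up(m0 * q1)
    n2 = _round_half_up(m0 * q2)
    if n1 + n2 > m0:
        raise ValueError(f"fractions ({q1}, {q2}) infeasible at m0={m0}")
    n_long = m0 - n1 - n2
    rng = np.random.default_rng(seed)
    lengths = _uniform_lengths(rng, n1, params.L_min, split - 1)
    lengths += _uniform_lengths(rng, n2, split, params.L_c - 1)
    lengths += _uniform_lengths(rng, n_long, params.L_c, long_max)
    dist = FragmentDistribution.from_lengths(lengths)
    dist.validate(params)
    return dist


def add_irreparable(
    dist: FragmentDistribution,
    p_irr: float,
    seed,
    irr_range: Optional[Tuple[int, int]] = None,
    params: Optional[SimParams] = None,
) -> FragmentDistribution:
    """Append capacity-0 fragments so they make up fraction ``p_irr`` of the total.

    Comparison mode only: adds ``round(m0 * p_irr / (1 - p_irr))``
    fragments with lengths uniform in ``irr_range`` ⊂ [1, L_min). These
    never bind Ku and persist for the whole simulation.
    """
    params = params or SimParams(include_irreparable=True)
    if not params.include_irreparable:
        raise ValueError("add_irreparable requires comparison mode (include_irreparable)")
    if not 0.0 <= p_irr < 1.0:
        raise ValueError(f"p_irr must be in [0, 1), got {p_irr}")
    irr_range = irr_range or (max(1, params.L_min // 2), params.L_min - 1)
    if not (1 <= irr_range[0] <= irr_range[1] < params.L_min):
        raise ValueError(
            f"irr_range {irr_range} must lie within [1, L_min={params.L_min})"
        )
    n_irr = _round_half_up(dist.m0 * p_irr / (1.0 - p_irr))
    if n_irr == 0:
        return dist
    rng = np.random.default_rng(seed)
    lengths = list(dist.lengths()) + _uniform_lengths(rng, n_irr, *irr_range)
    return FragmentDistribution.from_lengths(lengths)
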