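"""The (s, n) fragmentation-strategy space and the group-partitioning sampler.

A fragmentation mode is a point in a triangular strategy space.  ``n`` in
(0, 1] is the expected fraction of the parent's cells transmitted to
offspring groups; ``s`` in (0, 0.5] is the expected size of each offspring
group, again as a fraction of the parent.  Valid modes satisfy
``s <= n <= 1 - s`` (the lower triangle is logically impossible; above the
upper diagonal one of the resulting parts is simply relabelled the parent).
The triangle's corners are the archetypal modes: single-cell reproduction
(s = n = 1/N), complete fragmentation (s = 1/N, n = 1 - 1/N) and binary
fission (s = n = 0.5).

When a group of ``N`` cells fissions:

1. ``N_offspring`` is drawn from a Poisson distribution with expectation
   ``n * N``, renormalised on support {1, ..., N};
2. ``S_offspring`` is drawn from a Poisson with expectation ``s * N``,
   renormalised on {1, ..., N_offspring};
3. ``G_offspring = ceil(N_offspring / S_offspring)`` groups are formed, the
   first ``G_offspring - 1`` of exactly ``S_offspring`` cells and the last of
   the remainder, each filled by sampling cells without replacement
   (multivariate hypergeometric over the (species, type[, trait-bin])
   census);
4. the transmitted cells are removed from the parent.  If every cell was
   transmitted, the last part is relabelled as the parent so that an empty
   group never survives the event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .model_core import GroupState

__all__ = [
    "FragmentationStrategy",
    "FragmentationDraw",
    "validate_strategy",
    "truncated_poisson_pmf_scipy",
    "truncated_poisson_sample",
    "sample_cells_without_replacement",
    "fragment_group",
]


@dataclass(frozen=True)
class FragmentationStrategy:
    """A point (s, n) of the fragmentation-mode triangle.

    The constructor does not reject invalid points (scans iterate over full
    rectangular grids and flag the inadmissible ones); use
    :func:`validate_strategy` or :meth:`is_valid`.
    """

    s: float
    n: float

    def is_valid(self) -> bool:
        return validate_strategy(self)

    def as_tuple(self) -> tuple[float, float]:
        return (self.s, self.n)


def validate_strategy(strategy: FragmentationStrategy) -> bool:
    """True iff 0 < s <= 0.5, 0 < n <= 1 and s <= n <= 1 - s.

    The triangle is treated as closed so the three archetypal corners are
    admissible strategies.
    """
    s, n = strategy.s, strategy.n
    return (0.0 < s <= 0.5) and (0.0 < n <= 1.0) and (s <= n <= 1.0 - s)


@dataclass(frozen=True)
class FragmentationDraw:
    """Outcome of the two truncated-Poisson draws of a fission event."""

    N_offspring: int
    S_offspring: int

    def __post_init__(self) -> None:
        if self.N_offspring < 1:
            raise ValueError("N_offspring must be >= 1")
        if not (1 <= self.S_offspring <= self.N_offspring):
            raise ValueError("S_offspring must be in {1, ..., N_offspring}")

    @property
    def G_offspring(self) -> int:
        return -(-self.N_offspring // self.S_offspring)  # ceil division

    @property
    def sizes(self) -> tuple[int, ...]:
        """Sizes of the emitted parts: G-1 full parts plus the remainder."""
        g = self.G_offspring
        last = self.N_offspring - (g - 1) * self.S_offspring
        return (self.S_offspring,) * (g - 1) + (last,)


@lru_cache(maxsize=4096)
def _tp_pmf_cached(lam: float, max_support: int) -> np.ndarray:
    k = np.arange(1, max_support + 1)
    logp = stats.poisson.logpmf(k, lam)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p.setflags(write=False)
    return p


def truncated_poisson_pmf_scipy(lam: float, max_support: int) -> np.ndarray:
    """Poisson pmf renormalised on {1, ..., max_support} (scipy route).

    An independently coded twin lives in :mod:`fragmodes.oracles`.
    Results are cached: fission events reuse a handful of (lam, support)
    pairs over and over.
    """
    if max_support < 1:
        raise ValueError("max_support must be >= 1")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    return _tp_pmf_cached(float(lam), int(max_support))


@lru_cache(maxsize=4096)
def _tp_cdf_cached(lam: float, max_support: int) -> np.ndarray:
    cdf = np.cumsum(_tp_pmf_cached(lam, max_support))
    cdf.setflags(write=False)
    return cdf


def truncated_poisson_sample(
    lam: float, max_support: int, rng: np.random.Generator, size: int | None = None
):
    """Draw from a Poisson(lam) renormalised on support {1, ..., max_support}."""
    if max_support < 1:
        raise ValueError("max_support must be >= 1")
    cdf = _tp_cdf_cached(float(lam), int(max_support))
    if size is None:
        idx = int(np.searchsorted(cdf, rng.random(), side="right"))
        return min(idx, max_support - 1) + 1
    idx = np.searchsorted(cdf, rng.random(size), side="right")
    return np.minimum(idx, max_support - 1).astype(np.int64) + 1


def sample_cells_without_replacement(
    census: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` cells without replacement from a per-category census.

    Returns an array of the same shape as ``census`` with the drawn counts;
    the draw follows the multivariate hypergeometric law, so
    ``drawn + (census - drawn)`` reproduces the original census exactly.
    """
    census = np.asarray(census, dtype=np.int64)
    total = int(census.sum())
    if not (0 <= k <= total):
        raise ValueError(f"cannot draw {k} cells from a census of {total}")
    flat = census.ravel()
    drawn = rng.multivariate_hypergeometric(flat, k)
    return np.asarray(drawn, dtype=np.int64).reshape(census.shape)


def _group_census(group: GroupState) -> np.ndarray:
    """(m, 2[, B]) census array (axis 1: 0 = wild-type, 1 = mutant)."""
    if group.bin_counts is not None:
        return group.bin_counts.copy()
    return np.stack([group.wt_counts, group.mut_counts], axis=1)


def _group_from_census(census: np.ndarray) -> GroupState:
    if census.ndim == 3:
        return GroupState(
            census[:, 0, :].sum(axis=1), census[:, 1, :].sum(axis=1), census
        )
    return GroupState(census[:, 0], census[:, 1])


def fragment_group(
    group: GroupState,
    strategy: FragmentationStrategy,
    rng: np.random.Generator,
    forced_draws: FragmentationDraw | None = None,
) -> tuple[GroupState, list[GroupState], FragmentationDraw]:
    """Partition a group according to its fragmentation mode.

    Returns ``(parent, offspring, draw)``.  Cells are conserved exactly per
    (species, type[, trait-bin]) category.  ``forced_draws`` bypasses the two
    truncated-Poisson draws (used by tests and oracles); the cell allocation
    itself is always stochastic.
    """
    N = group.N
    if N < 1:
        raise ValueError("cannot fragment an empty group")
    if forced_draws is None:
        if not validate_strategy(strategy):
            raise ValueError(f"invalid fragmentation strategy {strategy}")
        n_off = truncated_poisson_sample(strategy.n * N, N, rng)
        s_off = truncated_poisson_sample(strategy.s * N, n_off, rng)
        draw = FragmentationDraw(n_off, s_off)
    else:
        draw = forced_draws
        if draw.N_offspring > N:
            raise ValueError("forced N_offspring exceeds group size")

    remaining = _group_census(group)
    parts: list[np.ndarray] = []
    for size in draw.sizes:
        taken = sample_cells_without_replacement(remaining, size, rng)
        remaining = remaining - taken
        parts.append(taken)

    if remaining.sum() == 0:
        # all cells transmitted: relabel the last allocated part as the parent
        remaining = parts.pop()
    parent = _group_from_census(remaining)
    offspring = [_group_from_census(p) for p in parts]
    return parent, offspring, draw
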