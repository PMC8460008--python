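"""Domain types and rate functions of the two-level birth-death model.

The model describes a community of multicellular groups (e.g. biofilm
patches).  Each group hosts cells of ``m`` species; every cell is either a
wild-type cooperator, which pays a growth cost ``gamma`` to produce public
goods, or a mutant cheater, which consumes public goods without producing
them.  Cells are born and die inside their group, while whole groups fission
into offspring groups and go extinct.  This module is the single source of
truth for the per-capita / per-group rates of those five event channels:

* mutant birth: ``n_wt/N`` for one species, or a cross-feeding product
  ``m**(m-1) * prod_{k != j} n_wt_k / N`` across the other ``m - 1`` species;
* wild-type birth: ``(1 - gamma)`` times the mutant rate of the same species;
* cell death: ``N/K_cells`` (logistic) or a constant ``1/K_cells`` in the
  forced-fission variant;
* group fission: ``B0 + sigma * N/K_cells``;
* group extinction: ``N_total/K_total``, identical for every group;
* migration: per-capita rate ``nu`` (no destination exists when G == 1).

Time is measured in units of the shortest possible cell generation: the
``m**(m-1)`` normalisation makes the maximum per-capita birth rate exactly 1
for a symmetric all-cooperator group, for any ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DENSITY_DEPENDENT",
    "CONSTANT_FORCED_FISSION",
    "ModelParams",
    "GroupState",
    "CommunityState",
    "mutant_birth_rate",
    "wildtype_birth_rate",
    "death_rate",
    "fission_rate",
    "extinction_rate",
    "migration_rate",
]

DENSITY_DEPENDENT = "density_dependent"
CONSTANT_FORCED_FISSION = "constant_with_forced_fission"

_DEATH_VARIANTS = (DENSITY_DEPENDENT, CONSTANT_FORCED_FISSION)


@dataclass(frozen=True)
class ModelParams:
    """All rate constants and model switches.

    Parameters
    ----------
    m
        Number of cross-feeding species in a group (>= 1).  With ``m == 1``
        cooperation is within-species (public goods shared by conspecifics).
    gamma
        Cost of cooperation, ``0 <= gamma < 1``.  Wild-type cells reproduce at
        ``(1 - gamma)`` times the rate of mutants in the same state.  The
        default of 0.1 is a documented placeholder, not a literature value;
        set it explicitly for publication-grade runs.
    mu
        Probability that a wild-type birth produces a mutant offspring
        (no back-mutation).
    K_cells
        Within-group carrying capacity (cells).
    B0
        Baseline group fission rate (per group per time unit).
    sigma
        Slope of the size-dependence of the fission rate.
    K_total
        Community-level scaling constant: per-group extinction rate is
        ``N_total / K_total``.  Use ``np.inf`` to switch extinctions off.
    nu
        Per-capita migration rate between groups.
    mu_s, mu_n
        Per-birth probabilities of a small-effect mutation in the heritable
        fragmentation traits ``s`` and ``n`` (evolution mode only).
    death_variant
        ``"density_dependent"`` (d = N/K_cells) or
        ``"constant_with_forced_fission"`` (d = 1/K_cells, and a group is
        forced to fission the moment it reaches ``K_cells`` cells).
    evolution_enabled
        Whether cells carry heritable (s, n) traits on a discretised grid.
    """

    m: int = 1
    gamma: float = 0.1
    mu: float = 0.0
    K_cells: int = 100
    B0: float = 0.01
    sigma: float = 0.0
    K_total: float = 10_000.0
    nu: float = 0.0
    mu_s: float = 0.0
    mu_n: float = 0.0
    death_variant: str = DENSITY_DEPENDENT
    evolution_enabled: bool = False

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        object.__setattr__(self, "m", int(self.m))
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must satisfy 0 <= gamma < 1, got {self.gamma}")
        for name in ("mu", "mu_s", "mu_n"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if int(self.K_cells) != self.K_cells or self.K_cells < self.m:
            raise ValueError(
                f"K_cells must be an integer >= m (= {self.m}), got {self.K_cells}"
            )
        object.__setattr__(self, "K_cells", int(self.K_cells))
        for name in ("B0", "sigma", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not self.K_total > 0:
            raise ValueError(f"K_total must be positive, got {self.K_total}")
        if self.death_variant not in _DEATH_VARIANTS:
            raise ValueError(
                f"death_variant must be one of {_DEATH_VARIANTS}, got {self.death_variant!r}"
            )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced (validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "gamma": self.gamma,
            "mu": self.mu,
            "K_cells": self.K_cells,
            "B0": self.B0,
            "sigma": self.sigma,
            "K_total": self.K_total if np.isfinite(self.K_total) else "inf",
            "nu": self.nu,
            "mu_s": self.mu_s,
            "mu_n": self.mu_n,
            "death_variant": self.death_variant,
            "evolution_enabled": self.evolution_enabled,
        }


@dataclass
class GroupState:
    """Per-group census: wild-type and mutant cell counts per species.

    ``wt_counts[j]`` / ``mut_counts[j]`` hold the number of cooperator /
    cheater cells of species ``j``.  In evolution mode an optional
    trait-resolved census ``bin_counts`` of shape ``(m, 2, n_bins)`` (axis 1:
    0 = wild-type, 1 = mutant) refines the aggregates; its marginals must
    match ``wt_counts`` / ``mut_counts`` exactly.
    """

    wt_counts: np.ndarray
    mut_counts: np.ndarray
    bin_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wt_counts = np.asarray(self.wt_counts, dtype=np.int64).copy()
        self.mut_counts = np.asarray(self.mut_counts, dtype=np.int64).copy()
        if self.wt_counts.ndim != 1 or self.wt_counts.shape != self.mut_counts.shape:
            raise ValueError("wt_counts and mut_counts must be 1-D arrays of equal length")
        if (self.wt_counts < 0).any() or (self.mut_counts < 0).any():
            raise ValueError("cell counts must be non-negative")
        if self.bin_counts is not None:
            self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64).copy()
            m = self.wt_counts.shape[0]
            if self.bin_counts.ndim != 3 or self.bin_counts.shape[:2] != (m, 2):
                raise ValueError("bin_counts must have shape (m, 2, n_bins)")
            if (self.bin_counts < 0).any():
                raise ValueError("bin_counts must be non-negative")
            if not np.array_equal(self.bin_counts[:, 0, :].sum(axis=1), self.wt_counts):
                raise ValueError("bin_counts wild-type marginal disagrees with wt_counts")
            if not np.array_equal(self.bin_counts[:, 1, :].sum(axis=1), self.mut_counts):
                raise ValueError("bin_counts mutant marginal disagrees with mut_counts")

    @property
    def m(self) -> int:
        return self.wt_counts.shape[0]

    @property
    def species_counts(self) -> np.ndarray:
        """N_{i,j} = wild-type + mutant cells per species."""
        return self.wt_counts + self.mut_counts

    @property
    def N(self) -> int:
        """Total number of cells in the group."""
        return int(self.wt_counts.sum() + self.mut_counts.sum())

    def copy(self) -> "GroupState":
        return GroupState(
            self.wt_counts,
            self.mut_counts,
            None if self.bin_counts is None else self.bin_counts,
        )


@dataclass
class CommunityState:
    """The set of living groups plus the simulation clock.

    Invariant: a group with zero cells never belongs to ``groups``.
    """

    groups: list[GroupState] = field(default_factory=list)
    time: float = 0.0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.N == 0:
                raise ValueError("an empty group must not exist in the community")

    @property
    def G(self) -> int:
        return len(self.groups)

    @property
    def N_total(self) -> int:
        return int(sum(g.N for g in self.groups))

    def copy(self) -> "CommunityState":
        return CommunityState([g.copy() for g in self.groups], self.time)


# ---------------------------------------------------------------------------
# Rate functions (reference implementations; the Gillespie kernel in
# fragmodes.engine mirrors these and is tested against them).
# ---------------------------------------------------------------------------

def mutant_birth_rate(group: GroupState, j: int, params: ModelParams) -> float:
    """Per-capita birth rate of a mutant cell of species ``j`` (0-based).

    For ``m == 1`` this is the wild-type fraction ``n_wt / N``; for ``m > 1``
    it is ``m**(m-1) * prod_{k != j} n_wt_k / N``, so a cell can only divide
    when cooperating partners of all other species are present.
    """
    N = group.N
    if N == 0:
        raise ValueError("birth rate is undefined for an empty group")
    m = params.m
    if not (0 <= j < m):
        raise IndexError(f"species index {j} out of range for m={m}")
    if m == 1:
        return float(group.wt_counts[0]) / N
    prod = 1.0
    for k in range(m):
        if k == j:
            continue
        prod *= float(group.wt_counts[k]) / N
    return float(m ** (m - 1)) * prod


def wildtype_birth_rate(group: GroupState, j: int, params: ModelParams) -> float:
    """Per-capita birth rate of a wild-type cell: ``(1 - gamma)`` x mutant rate."""
    return (1.0 - params.gamma) * mutant_birth_rate(group, j, params)


def death_rate(group: GroupState, params: ModelParams) -> float:
    """Per-capita death rate, identical for all cells of the group."""
    N = group.N
    if N == 0:
        raise ValueError("death rate is undefined for an empty group")
    if params.death_variant == CONSTANT_FORCED_FISSION:
        return 1.0 / params.K_cells
    return float(N) / params.K_cells


def fission_rate(group: GroupState, params: ModelParams) -> float:
    """Per-group fission rate ``B0 + sigma * N / K_cells``."""
    return params.B0 + params.sigma * float(group.N) / params.K_cells


def extinction_rate(community: CommunityState, params: ModelParams) -> float:
    """Per-group extinction rate ``N_total / K_total`` (same for every group)."""
    if not np.isfinite(params.K_total):
        return 0.0
    return float(community.N_total) / params.K_total


def migration_rate(
    group: GroupState, params: ModelParams, n_groups: int | None = None
) -> float:
    """Total emigration rate of a group, ``N_i * nu``.

    A migrating cell must join a *different* group, so with ``n_groups == 1``
    the channel has rate zero.
    """
    if n_groups is not None and n_groups <= 1:
        return 0.0
    return float(group.N) * params.nu
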