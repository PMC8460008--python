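"""Heritable fragmentation traits on a discretised (s, n) grid.

In evolution mode every cell carries a phenotype vector (s, n) — think of it
as properties of the extracellular matrix the cell secretes.  The group's
fragmentation mode is an emergent property: the cell-count-weighted mean
trait of its members.  Offspring inherit the parental trait; with small
per-birth probabilities ``mu_s`` and ``mu_n`` the offspring moves to an
adjacent phenotype bin along the corresponding axis.  Mutants that would
leave the admissible triangle ``s <= n <= 1 - s`` are moved along the
n-direction and placed on the boundary of the allowed space.

The grid default is 20 s-bins over (0, 0.5] x 40 n-bins over (0, 1], giving
both axes the same bin width (0.025) so that every s-column — including the
one at the binary-fission corner — contains at least one admissible bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragmentation import FragmentationStrategy, validate_strategy
from .model_core import GroupState

__all__ = ["TraitGrid", "mutate_trait", "group_mean_strategy", "evolve_run"]


@dataclass
class TraitGrid:
    """Discretised phenotype space for the heritable (s, n) traits.

    Bins are indexed flat as ``b = i_s * nn + i_n``; bin centers are the
    phenotype values.  ``mask[i_s, i_n]`` marks admissible bins (centers
    inside the closed triangle).  ``proj[b, ds + 1, dn + 1]`` precomputes the
    destination bin of a mutation step ``(ds, dn)`` from bin ``b``, with
    out-of-bounds results projected along the n-direction onto the boundary
    (and the s-step cancelled if no admissible bin exists at the target s).
    """

    ns: int = 20
    nn: int = 40
    s_centers: np.ndarray = field(init=False, repr=False)
    n_centers: np.ndarray = field(init=False, repr=False)
    mask: np.ndarray = field(init=False, repr=False)
    proj: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.ns < 2 or self.nn < 2:
            raise ValueError("grid needs at least 2 bins per axis")
        self.s_centers = (np.arange(self.ns) + 0.5) * 0.5 / self.ns
        self.n_centers = (np.arange(self.nn) + 0.5) * 1.0 / self.nn
        sc = self.s_centers[:, None]
        nc = self.n_centers[None, :]
        self.mask = (sc <= nc) & (nc <= 1.0 - sc)
        if not all(self.mask[i].any() for i in range(self.ns)):
            raise ValueError(
                "some s-column contains no admissible bin; use a finer n-axis "
                "(e.g. nn = 2 * ns so both axes share one bin width)"
            )
        self.proj = self._build_projection()
        if not self._every_bin_has_neighbour():
            raise ValueError("an admissible bin has no admissible neighbour")

    # -- indexing ----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.ns * self.nn

    def flat(self, i_s: int, i_n: int) -> int:
        return i_s * self.nn + i_n

    def coords(self, b: int) -> tuple[int, int]:
        return divmod(b, self.nn)

    @property
    def bin_s(self) -> np.ndarray:
        """s center of every flat bin (length n_bins)."""
        return np.repeat(self.s_centers, self.nn)

    @property
    def bin_n(self) -> np.ndarray:
        """n center of every flat bin (length n_bins)."""
        return np.tile(self.n_centers, self.ns)

    def admissible_bins(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def bin_of(self, s: float, n: float) -> int:
        """Flat index of the admissible bin nearest to a phenotype (s, n)."""
        adm = self.admissible_bins()
        d2 = (self.bin_s[adm] - s) ** 2 + (self.bin_n[adm] - n) ** 2
        return int(adm[np.argmin(d2)])

    def strategy_of(self, b: int) -> FragmentationStrategy:
        i_s, i_n = self.coords(b)
        return FragmentationStrategy(self.s_centers[i_s], self.n_centers[i_n])

    # -- construction helpers ---------------------------------------------
    def _project_n(self, i_s: int, i_n: int) -> int:
        """Clamp an n-index into the admissible band of column ``i_s``."""
        col = np.flatnonzero(self.mask[i_s])
        return int(np.clip(i_n, col[0], col[-1]))

    def _build_projection(self) -> np.ndarray:
        proj = np.zeros((self.n_bins, 3, 3), dtype=np.int64)
        for i_s in range(self.ns):
            for i_n in range(self.nn):
                b = self.flat(i_s, i_n)
                for ds in (-1, 0, 1):
                    for dn in (-1, 0, 1):
                        ts = i_s + ds
                        if not (0 <= ts < self.ns):
                            ts = i_s  # s-step off the grid: cancel it
                        tn = i_n + dn
                        if 0 <= tn < self.nn and self.mask[ts, tn]:
                            proj[b, ds + 1, dn + 1] = self.flat(ts, tn)
                        else:
                            # move along the n-direction onto the boundary
                            tn2 = self._project_n(ts, tn)
                            proj[b, ds + 1, dn + 1] = self.flat(ts, tn2)
        return proj

    def _every_bin_has_neighbour(self) -> bool:
        for b in self.admissible_bins():
            for ds in (-1, 0, 1):
                for dn in (-1, 0, 1):
                    if (ds, dn) != (0, 0) and self.proj[b, ds + 1, dn + 1] != b:
                        break
                else:
                    continue
                break
            else:
                return False
        return True


def mutate_trait(
    parent_bin: int,
    mu_s: float,
    mu_n: float,
    grid: TraitGrid,
    rng: np.random.Generator,
) -> int:
    """Offspring trait bin after independent +/-1 steps in s and n.

    With probability ``mu_s`` the offspring moves one s-bin (direction
    uniform), independently with probability ``mu_n`` one n-bin; a double
    mutation is possible.  Inadmissible results are projected along n onto
    the boundary (the s-step is cancelled if its column has no admissible
    bin at the grid edge).
    """
    ds = 0
    if mu_s > 0 and rng.random() < mu_s:
        ds = 1 if rng.random() < 0.5 else -1
    dn = 0
    if mu_n > 0 and rng.random() < mu_n:
        dn = 1 if rng.random() < 0.5 else -1
    return int(grid.proj[parent_bin, ds + 1, dn + 1])


def group_mean_strategy(group: GroupState, grid: TraitGrid) -> FragmentationStrategy:
    """Emergent group strategy: count-weighted mean of member bin centers.

    The mean of admissible points can stray outside the closed triangle only
    past the corner arcs; for consistency with trait mutation any such point
    is projected along the n-direction onto the boundary.
    """
    if group.bin_counts is None:
        raise ValueError("group carries no trait-resolved census")
    weights = group.bin_counts.sum(axis=(0, 1)).astype(float)
    total = weights.sum()
    if total == 0:
        raise ValueError("cannot average traits of an empty group")
    s = float(weights @ grid.bin_s) / total
    n = float(weights @ grid.bin_n) / total
    n = min(max(n, s), 1.0 - s)
    strat = FragmentationStrategy(s, n)
    assert validate_strategy(strat)
    return strat


def evolve_run(
    params,
    grid: TraitGrid,
    initial_strategy: FragmentationStrategy,
    *,
    t_end: float = 1_000_000.0,
    snapshot_every: float = 1_000.0,
    n_groups: int = 100,
    seed: int = 0,
    **run_kwargs,
):
    """Multilevel evolutionary dynamics of the fragmentation mode.

    Starts a trait-homogeneous population (every cell in the admissible bin
    nearest ``initial_strategy``) and runs the full two-level dynamics with
    heritable (s, n) traits for ``t_end`` time units, without steady-state
    stopping.  Returns an :class:`~fragmodes.engine.RunResult` whose
    trajectory is thinned to one row per ``snapshot_every`` time units
    (columns ``mean_s`` / ``mean_n`` track the population mean trait) and
    whose ``final_community`` carries the full trait-resolved census.
    """
    from .engine import run  # imported here to avoid an import cycle

    if not params.evolution_enabled:
        raise ValueError("params.evolution_enabled must be True for evolve_run")
    initial_bin = grid.bin_of(initial_strategy.s, initial_strategy.n)
    res = run(params, strategy=None, grid=grid, initial_bin=initial_bin,
              n_groups=n_groups, seed=seed, t_max=t_end,
              stop_on_steady=False, **run_kwargs)
    traj = res.trajectory
    if len(traj):
        keep = (traj["time"] % snapshot_every < 1.0) | (traj.index == len(traj) - 1)
        res.trajectory = traj[keep].reset_index(drop=True)
    return res
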