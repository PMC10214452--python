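"""Model parameters and Monte Carlo schedules.

Defaults reproduce the reference simulation conditions: spin-spin coupling
J = 0.55 k_BT (well below the triangular-lattice critical coupling
ln(3)/4, so the quench demixes), anchor couplings J_sT = 0.136 k_BT and
J_dC = -0.057 k_BT, composition ratio n(-1)/n(+1) = 2/3 and tile coverage
sigma = 30%.  All energies are in units of k_BT (beta = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import ConfigurationError

__all__ = ["ModelParams", "Schedule"]


@dataclass(frozen=True)
class ModelParams:
    """Couplings and composition of one simulation condition."""

    j: float = 0.55           # spin-spin coupling, k_BT
    j_st: float = 0.136       # sT anchor coupling, k_BT (prefers s = +1)
    j_dc: float = -0.057      # dC anchor coupling, k_BT (prefers s = -1)
    ratio: float = 2.0 / 3.0  # composition n(-1)/n(+1)
    sigma: float = 0.30       # tile area coverage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j < 0:
            raise ConfigurationError(f"J must be >= 0, got {self.j}")
        if not (0.0 <= self.sigma < 1.0):
            raise ConfigurationError(f"sigma must be in [0, 1), got {self.sigma}")
        if self.ratio <= 0:
            raise ConfigurationError(f"ratio must be > 0, got {self.ratio}")

    def anchor_j(self, kind: int) -> float:
        from .tiles import ANCHOR_ST

        return self.j_st if kind == ANCHOR_ST else self.j_dc


@dataclass(frozen=True)
class Schedule:
    """Monte Carlo schedule.

    One cycle is ``n_sites`` attempted nearest-neighbour spin exchanges
    followed by one attempted rigid-body move per tile; this keeps MC time
    roughly comparable across lattice sizes.  Observables (and optional
    snapshots) are recorded every ``stride`` cycles, always including
    cycle 0 and the final cycle.
    """

    t_mc: int = 20_000_000
    stride: int = 1000
    deactivate_at: int | None = None  # cycle at which all tiles are removed
    n_replicates: int = 15
    record_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.t_mc < 0:
            raise ConfigurationError(f"t_mc must be >= 0, got {self.t_mc}")
        if self.stride < 1:
            raise ConfigurationError(f"stride must be >= 1, got {self.stride}")
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if self.deactivate_at is not None and not (
            0 <= self.deactivate_at <= self.t_mc
        ):
            raise ConfigurationError(
                f"deactivate_at must lie within [0, t_mc], got {self.deactivate_at}"
            )
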