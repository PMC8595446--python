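"""D3Q19 velocity set.

The solver uses the standard 19-velocity three-dimensional stencil: one rest
population, six face neighbours and twelve edge neighbours.  Weights are the
usual 1/3, 1/18 and 1/36 rationals and the lattice sound speed squared is
``c_s^2 = 1/3`` in lattice units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StencilD3Q19", "D3Q19"]


def _build_velocities() -> np.ndarray:
    vels = [(0, 0, 0)]
    # face neighbours
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            vels.append(tuple(v))
    # edge neighbours
    for a in range(3):
        b = (a + 1) % 3
        for sa in (1, -1):
            for sb in (1, -1):
                v = [0, 0, 0]
                v[a] = sa
                v[b] = sb
                vels.append(tuple(v))
    return np.array(vels, dtype=np.int64)


@dataclass(frozen=True)
class StencilD3Q19:
    """Immutable D3Q19 stencil: velocities, weights and opposite pairing.

    Derived arrays (weights, opposite pairing) are computed once at
    construction — they sit on the hot path of every collision call.
    """

    velocities: np.ndarray = field(default_factory=_build_velocities)
    sound_speed_sq: float = 1.0 / 3.0
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    opposite_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.empty(self.q)
        speed2 = (self.velocities**2).sum(axis=1)
        w[speed2 == 0] = 1.0 / 3.0
        w[speed2 == 1] = 1.0 / 18.0
        w[speed2 == 2] = 1.0 / 36.0
        opp = np.empty(self.q, dtype=np.int64)
        for i, c in enumerate(self.velocities):
            opp[i] = np.where((self.velocities == -c).all(axis=1))[0][0]
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "opposite_index", opp)

    @property
    def q(self) -> int:
        return len(self.velocities)

    @property
    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, opposite(i)) with i < opposite(i); excludes the rest direction."""
        opp = self.opposite_index
        i = np.array([k for k in range(self.q) if k < opp[k]], dtype=np.int64)
        return i, opp[i]


#: Shared module-level stencil instance.
D3Q19 = StencilD3Q19()
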