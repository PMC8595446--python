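"""Two-relaxation-time D3Q19 lattice Boltzmann kernel on sparse site lists.

Fluid sites are stored as a flat list (the geometries are sparse vessel
networks, so dense grids would waste most of their memory on solid voxels).
Populations live in a ``(n_sites, 19)`` array; connectivity between sites is
a precomputed pull-streaming index table.

The collision operator is the two-relaxation-time (TRT) kernel: the even and
odd parts of the non-equilibrium populations relax with separate rates
``1/tau_plus`` and ``1/tau_minus``, linked through the magic parameter
``Lambda = (tau_plus - 1/2)(tau_minus - 1/2)``.  ``Lambda = 1/12`` is the
default, optimising bulk advection accuracy; ``Lambda = 3/16`` places the
half-way bounce-back wall exactly in straight channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stencil import D3Q19, StencilD3Q19
from .units import CS2

__all__ = [
    "TRTParameters",
    "FluidState",
    "equilibrium",
    "update_macroscopics",
    "trt_collide",
    "stream",
    "guo_source",
    "periodic_connectivity",
]

MAGIC_DEFAULT = 1.0 / 12.0


@dataclass(frozen=True)
class TRTParameters:
    """TRT relaxation times; ``tau_minus`` is derived from the magic parameter."""

    tau_plus: float
    lambda_magic: float = MAGIC_DEFAULT
    tau_minus: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau_plus <= 0.5:
            raise ValueError(f"tau_plus must exceed 1/2, got {self.tau_plus}")
        if self.tau_minus is None:
            tm = 0.5 + self.lambda_magic / (self.tau_plus - 0.5)
            object.__setattr__(self, "tau_minus", tm)
        if self.tau_minus <= 0.5:
            raise ValueError(f"tau_minus must exceed 1/2, got {self.tau_minus}")
        gap = abs((self.tau_plus - 0.5) * (self.tau_minus - 0.5) - self.lambda_magic)
        if gap > 1e-12:
            raise ValueError(
                f"(tau+ - 1/2)(tau- - 1/2) = {gap + self.lambda_magic:g} "
                f"inconsistent with Lambda = {self.lambda_magic:g}"
            )

    @classmethod
    def bgk(cls, tau: float) -> "TRTParameters":
        """Degenerate single-relaxation-time (BGK) parameterisation."""
        lam = (tau - 0.5) ** 2
        return cls(tau_plus=tau, lambda_magic=lam, tau_minus=tau)


@dataclass
class FluidState:
    """Populations plus derived macroscopic fields on the sparse site list."""

    f: np.ndarray  # (n, 19) populations, lattice units
    rho: np.ndarray  # (n,) density
    u: np.ndarray  # (n, 3) velocity
    step: int = 0

    @classmethod
    def at_rest(cls, n_sites: int, rho: float = 1.0,
                stencil: StencilD3Q19 = D3Q19) -> "FluidState":
        f = np.tile(rho * stencil.weights, (n_sites, 1))
        return cls(f=f, rho=np.full(n_sites, rho),
                   u=np.zeros((n_sites, 3)), step=0)

    @property
    def n_sites(self) -> int:
        return self.f.shape[0]

    def copy(self) -> "FluidState":
        return FluidState(self.f.copy(), self.rho.copy(), self.u.copy(), self.step)


def equilibrium(rho, u, stencil: StencilD3Q19 = D3Q19) -> np.ndarray:
    """Second-order polynomial equilibrium populations.

    ``rho`` may be a scalar or ``(n,)``; ``u`` a 3-vector or ``(n, 3)``.
    Returns ``(n, 19)`` (or ``(19,)`` for scalar input).  The zeroth and first
    moments of the result are ``rho`` and ``rho*u`` to round-off.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 1
    if scalar:
        rho = rho.reshape(1)
        u = u.reshape(1, 3)
    if np.any(rho <= 0):
        raise ValueError("equilibrium requires rho > 0")
    c = stencil.velocities.astype(float)
    cu = u @ c.T  # (n, 19)
    usq = np.einsum("nd,nd->n", u, u)
    feq = stencil.weights * rho[:, None] * (
        1.0 + cu / CS2 + 0.5 * cu**2 / CS2**2 - 0.5 * usq[:, None] / CS2
    )
    return feq[0] if scalar else feq


def update_macroscopics(state: FluidState, force: np.ndarray | None = None,
                        stencil: StencilD3Q19 = D3Q19) -> FluidState:
    """Recompute rho and u from the populations (Guo half-force included)."""
    c = stencil.velocities.astype(float)
    state.rho = state.f.sum(axis=1)
    mom = state.f @ c
    if force is not None:
        mom = mom + 0.5 * force
    state.u = mom / state.rho[:, None]
    return state


def trt_collide(state: FluidState, params: TRTParameters,
                force: np.ndarray | None = None,
                stencil: StencilD3Q19 = D3Q19) -> FluidState:
    """In-place TRT collision (macroscopics must be current).

    Even/odd parts of ``f - f_eq`` relax with ``1/tau_plus`` and
    ``1/tau_minus``; the rest population relaxes with ``1/tau_plus``.  Mass
    and momentum at every site are conserved exactly (the optional Guo force
    adds exactly ``force`` of momentum per site per step).
    """
    feq = equilibrium(state.rho, state.u, stencil)
    i, j = stencil.pair_indices
    f = state.f
    fp = 0.5 * (f[:, i] + f[:, j])
    fm = 0.5 * (f[:, i] - f[:, j])
    ep = 0.5 * (feq[:, i] + feq[:, j])
    em = 0.5 * (feq[:, i] - feq[:, j])
    wp = 1.0 / params.tau_plus
    wm = 1.0 / params.tau_minus
    dp = fp - ep
    dm = fm - em
    f[:, i] -= wp * dp + wm * dm
    f[:, j] -= wp * dp - wm * dm
    f[:, 0] -= wp * (f[:, 0] - feq[:, 0])
    if force is not None:
        f += guo_source(state.u, force, params, stencil)
    return state


def guo_source(u: np.ndarray, force: np.ndarray, params: TRTParameters,
               stencil: StencilD3Q19 = D3Q19) -> np.ndarray:
    """Guo second-order forcing source term, ``(n, 19)``.

    The classic form w_i [ (c_i - u)/c_s^2 + (c_i.u) c_i/c_s^4 ] . F is split
    by parity for TRT: the odd part (c_i.F) carries the (1 - 1/(2 tau-))
    prefactor, the even part (1 - 1/(2 tau+)); this keeps the injected
    momentum exactly F per site per step and avoids a spurious force bias in
    resistive flows.
    """
    c = stencil.velocities.astype(float)
    cu = u @ c.T
    cF = force @ c.T
    uF = np.einsum("nd,nd->n", u, force)
    pref_odd = (1.0 - 0.5 / params.tau_minus) * stencil.weights
    pref_even = (1.0 - 0.5 / params.tau_plus) * stencil.weights
    return pref_odd * cF / CS2 + pref_even * (cu * cF / CS2**2 - uF[:, None] / CS2)


def stream(state: FluidState, src: np.ndarray) -> FluidState:
    """Pull-streaming over the sparse connectivity table, in place.

    ``src[n, i]`` is the site index from which population ``i`` at site ``n``
    is pulled (the neighbour at ``x_n - c_i``), or ``-1`` where that neighbour
    is not a fluid site.  Missing entries keep their pre-stream value and are
    resolved afterwards by the boundary module (Bouzidi walls, openings).
    """
    n, q = state.f.shape
    cols = np.arange(q)[None, :]
    pulled = state.f[np.where(src >= 0, src, np.arange(n)[:, None]), cols]
    state.f = pulled
    return state


def periodic_connectivity(shape: tuple[int, int, int],
                          wall_axis: int | None = None,
                          stencil: StencilD3Q19 = D3Q19) -> np.ndarray:
    """Pull-streaming table for a dense box, periodic in every axis except
    an optional ``wall_axis`` (whose out-of-range links are marked -1).

    Intended for benchmark geometries (periodic boxes, plane channels); the
    vessel domains build their tables from the voxel classification instead.
    """
    c = stencil.velocities
    dims = np.asarray(shape)
    idx = np.arange(int(np.prod(dims))).reshape(shape)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    src = np.empty((idx.size, stencil.q), dtype=np.int64)
    for i, ci in enumerate(c):
        coords = []
        missing = np.zeros(shape, dtype=bool)
        for a in range(3):
            pos = grids[a] - ci[a]
            if a == wall_axis:
                missing |= (pos < 0) | (pos >= dims[a])
                coords.append(np.clip(pos, 0, dims[a] - 1))
            else:
                coords.append(pos % dims[a])
        s = idx[tuple(coords)]
        src[:, i] = np.where(missing, -1, s).ravel()
    return src
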