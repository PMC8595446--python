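"""Sub-scale capillary-bed coupling between arterial and venous instances.

The capillaries that cannot be resolved at lattice scale are represented by
a 0D resistor-capacitor surrogate joining n arterial outlets to m venous
inlets.  Per exchange:

1. the flow-weighted velocity v_D over the feeding-side openings is
   aggregated (v_D = sum A_j v_j^2 / sum A_j v_j) and scaled by the total
   area to give the feeding flow rate Q;
2. the bed converts the feeding flow to the receiving flow through
   ``Q_out = Q_in + 1/2 Cbar R dQ_B/dt`` with the pressure drop over the bed
   ``dP = R Q_B`` (Q_B is identified with the flow currently entering the
   bed; dQ_B/dt is a backward difference over the coupling interval);
3. the receiving flow is distributed to the member openings in proportion to
   (transfer coefficient x area).

Exchanges fire every ``interval`` steps, alternating direction: the
artery-to-vein half sets venous inlet velocity targets; the vein-to-artery
half converts the per-outlet target velocity to a dynamic-pressure body
force applied at the arterial outlets.  A fistula pair bypasses the bed
entirely: the venous inlet copies the arterial partner's mean outlet
velocity scaled by a transfer coefficient (area ratio once the vein has
dilated, so volumetric flow is conserved across the junction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BedOpening",
    "CapillaryBed",
    "CouplingSchedule",
    "FistulaPairing",
    "ExchangeResult",
    "flow_weighted_velocity",
    "bed_pressure_drop",
    "bed_flow_update",
    "distribute_flow",
    "couple_exchange",
    "fistula_exchange",
    "coupling_map_to_yaml",
    "coupling_map_from_yaml",
]


@dataclass
class BedOpening:
    """One opening participating in a bed: id, area (m^2), transfer coefficient."""

    id: str
    area: float
    coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"opening {self.id!r}: area must be positive")


@dataclass
class CapillaryBed:
    """Resistor-capacitor bed state linking arterial outlets to venous inlets."""

    id: str
    arterial: list[BedOpening]
    venous: list[BedOpening]
    R: float  # bed resistance, Pa s / m^3
    C_bar: float = 0.0  # bed capacitance, m^3 / Pa
    Q_B: float = 0.0  # current bed flow, m^3/s
    Q_B_prev: float = 0.0
    last_update_time: float = 0.0

    def __post_init__(self) -> None:
        if len(self.arterial) < 1 or len(self.venous) < 1:
            raise ValueError("a bed needs at least one artery and one vein")
        if self.R < 0 or self.C_bar < 0:
            raise ValueError("R and C_bar must be non-negative")


@dataclass
class CouplingSchedule:
    """When exchanges fire and which direction runs next.

    The direction alternates at every exchange, starting artery-to-vein (the
    venous instance starts from rest, so it must be fed first).
    """

    interval: int = 500
    direction: str = "artery_to_vein"
    exchanges_done: int = 0

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("coupling interval must be >= 1 step")
        if self.direction not in ("artery_to_vein", "vein_to_artery"):
            raise ValueError(f"bad direction {self.direction!r}")

    def due(self, step: int) -> bool:
        return step > 0 and step % self.interval == 0

    def flip(self) -> None:
        self.direction = ("vein_to_artery" if self.direction == "artery_to_vein"
                          else "artery_to_vein")
        self.exchanges_done += 1


@dataclass
class FistulaPairing:
    """1:1 arterial-outlet to venous-inlet pairs with transfer coefficients."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        art = [a for a, _, _ in self.pairs]
        ven = [v for _, v, _ in self.pairs]
        if len(set(art)) != len(art) or len(set(ven)) != len(ven):
            raise ValueError("fistula pairing must be one-to-one")


# --------------------------------------------------------------------------
# the four model operations
# --------------------------------------------------------------------------

def flow_weighted_velocity(areas, velocities, form: str = "flow_weighted") -> float:
    """Aggregate velocity v_D over a bed's member openings (m/s).

    ``flow_weighted`` (default): v_D = sum_j A_j v_j^2 / sum_j A_j v_j.
    ``plain_sum``: the termwise-simplified alternative sum_j v_j, kept
    selectable for comparison (see docs/methods.md on this choice).

    Velocities are positive in the physiological flow direction out of the
    feeding geometry.  A vanishing denominator with non-zero velocities is a
    degenerate counterflow; 0 is returned with a logged warning.
    """
    A = np.asarray(areas, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if np.any(A <= 0):
        raise ValueError("areas must be positive")
    if form == "plain_sum":
        return float(np.sum(v))
    if form != "flow_weighted":
        raise ValueError(f"unknown v_D form {form!r}")
    denom = float(np.sum(A * v))
    if denom == 0.0:
        if np.any(v != 0.0):
            logger.warning("degenerate counterflow: sum A_j v_j = 0 with non-zero "
                           "velocities; returning v_D = 0")
        return 0.0
    return float(np.sum(A * v**2) / denom)


def bed_pressure_drop(bed: CapillaryBed) -> float:
    """Pressure drop over the bed, dP = R Q_B (Pa)."""
    return bed.R * bed.Q_B


def bed_flow_update(bed: CapillaryBed, Q_in: float, dt_couple: float,
                    Q_B: float | None = None) -> float:
    """Advance the bed and return the receiving-side flow rate (m^3/s).

    By default Q_B is identified with the flow currently entering the bed
    from the feeding side (``Q_in``); an explicit ``Q_B`` may be supplied
    when the bed flow is observed separately.  Its time derivative is the
    backward difference over the coupling interval.  Then
    ``Q_out = Q_in + 1/2 Cbar R dQ_B/dt``.
    """
    if dt_couple <= 0:
        raise ValueError("dt_couple must be positive")
    bed.Q_B_prev = bed.Q_B
    bed.Q_B = Q_in if Q_B is None else Q_B
    dQdt = (bed.Q_B - bed.Q_B_prev) / dt_couple
    bed.last_update_time += dt_couple
    return Q_in + 0.5 * bed.C_bar * bed.R * dQdt


def distribute_flow(Q: float, openings: list[BedOpening]) -> dict[str, float]:
    """Split a flow rate over openings by coefficient-weighted area.

    Opening j receives Q_j = Q (c_j A_j) / sum(c_k A_k); returned is the
    target mean velocity v_j = Q_j / A_j per opening id.  The Q_j sum to Q
    exactly.
    """
    wsum = sum(o.coefficient * o.area for o in openings)
    if wsum <= 0:
        raise ValueError("all-zero coefficient-area weights")
    return {o.id: Q * o.coefficient / wsum for o in openings}


# --------------------------------------------------------------------------
# exchange orchestration (pure flow arithmetic; the engine applies results)
# --------------------------------------------------------------------------

def coupling_map_to_yaml(beds: list[CapillaryBed],
                         fistula: FistulaPairing | None, path) -> None:
    """Persist bed membership, RC parameters and fistula pairs as YAML."""
    import yaml

    doc = {
        "beds": [
            {
                "id": b.id,
                "R_pa_s_per_m3": b.R,
                "C_bar_m3_per_pa": b.C_bar,
                "arterial": [{"id": o.id, "area_m2": o.area,
                              "coefficient": o.coefficient} for o in b.arterial],
                "venous": [{"id": o.id, "area_m2": o.area,
                            "coefficient": o.coefficient} for o in b.venous],
            }
            for b in beds
        ],
        "fistula_pairs": ([] if fistula is None else
                          [{"arterial": a, "venous": v, "coefficient": c}
                           for a, v, c in fistula.pairs]),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def coupling_map_from_yaml(path) -> tuple[list[CapillaryBed], FistulaPairing | None]:
    """Load and validate a coupling map; errors surface through the dataclass
    invariants (non-empty sides, non-negative R/C, one-to-one pairs)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    beds = [
        CapillaryBed(
            id=b["id"], R=float(b["R_pa_s_per_m3"]),
            C_bar=float(b.get("C_bar_m3_per_pa", 0.0)),
            arterial=[BedOpening(id=o["id"], area=float(o["area_m2"]),
                                 coefficient=float(o.get("coefficient", 1.0)))
                      for o in b["arterial"]],
            venous=[BedOpening(id=o["id"], area=float(o["area_m2"]),
                               coefficient=float(o.get("coefficient", 1.0)))
                    for o in b["venous"]],
        )
        for b in doc.get("beds", [])
    ]
    pairs = [(p["arterial"], p["venous"], float(p.get("coefficient", 1.0)))
             for p in doc.get("fistula_pairs", [])]
    return beds, (FistulaPairing(pairs=pairs) if pairs else None)


@dataclass
class ExchangeResult:
    """Instructions produced by one coupling exchange.

    ``venous_inlet_targets``: opening id -> target mean inflow velocity, m/s.
    ``arterial_outlet_targets``: opening id -> target mean outflow velocity,
    m/s, to be converted to a dynamic-pressure force at the outlet.
    """

    venous_inlet_targets: dict[str, float] = field(default_factory=dict)
    arterial_outlet_targets: dict[str, float] = field(default_factory=dict)
    direction: str = ""


def couple_exchange(bed: CapillaryBed, schedule: CouplingSchedule,
                    arterial_velocities: dict[str, float],
                    venous_velocities: dict[str, float],
                    dt_couple: float,
                    v_d_form: str = "flow_weighted") -> ExchangeResult:
    """Run one bed exchange in the scheduled direction and flip it.

    ``arterial_velocities``/``venous_velocities`` map member opening ids to
    measured mean velocities (m/s, positive out of the artery / into the
    vein).  Missing ids are a configuration error.
    """
    for o in bed.arterial:
        if o.id not in arterial_velocities:
            raise KeyError(f"bed {bed.id!r}: arterial opening {o.id!r} not measured")
    for o in bed.venous:
        if o.id not in venous_velocities:
            raise KeyError(f"bed {bed.id!r}: venous opening {o.id!r} not measured")

    result = ExchangeResult(direction=schedule.direction)
    if schedule.direction == "artery_to_vein":
        feed = bed.arterial
        v = [arterial_velocities[o.id] for o in feed]
        v_d = flow_weighted_velocity([o.area for o in feed], v, form=v_d_form)
        Q_in = v_d * sum(o.area for o in feed)
        Q_out = bed_flow_update(bed, Q_in, dt_couple)
        result.venous_inlet_targets = distribute_flow(Q_out, bed.venous)
    else:
        feed = bed.venous
        v = [venous_velocities[o.id] for o in feed]
        v_d = flow_weighted_velocity([o.area for o in feed], v, form=v_d_form)
        Q_in = v_d * sum(o.area for o in feed)
        Q_out = bed_flow_update(bed, Q_in, dt_couple)
        result.arterial_outlet_targets = distribute_flow(Q_out, bed.arterial)
    schedule.flip()
    return result


def fistula_exchange(arterial_velocities: dict[str, float],
                     pairing: FistulaPairing,
                     areas: dict[str, float] | None = None,
                     conserve_flow: bool = False) -> dict[str, float]:
    """Direct 1:1 exchange across fistula pairs.

    Each venous inlet target is the arterial partner's mean outlet velocity
    times the pair's transfer coefficient.  With ``conserve_flow`` the
    coefficient is replaced by the area ratio A_art/A_ven so volumetric flow
    is conserved across a dilated junction; a coefficient of 1 with
    mismatched areas then triggers a warning upstream of this call.
    """
    targets: dict[str, float] = {}
    for art_id, ven_id, coeff in pairing.pairs:
        if art_id not in arterial_velocities:
            raise KeyError(f"fistula pair references unmeasured opening {art_id!r}")
        c = coeff
        if conserve_flow:
            if areas is None:
                raise ValueError("conserve_flow needs opening areas")
            c = areas[art_id] / areas[ven_id]
        targets[ven_id] = arterial_velocities[art_id] * c
    return targets
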