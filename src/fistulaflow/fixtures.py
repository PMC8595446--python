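"""Synthetic vessel fixtures: cylinder, Y-junction and the forearm pair.

The forearm fixture emulates the structural features of a patient forearm
vasculature without any licensed geometry: a single brachial-like arterial
inlet of 2.2 mm diameter feeding a radial/ulnar-like bifurcation with two
terminal outlets; a denser venous tree with 12 capillary inlets at the
wrist end and two major superficial trunks (cephalic and basilic
analogues) plus two minor veins with their own outlets; and a
radial-artery/cephalic-vein junction that the end-to-side fistula modifier
can cut into.  Vessels are geometrically simplified straight tubes with
mild taper; endpoint coordinates are multiples of the recommended lattice
spacing so that opening caps land on voxel faces.

All lengths are desk-scale (a few centimetres) rather than anatomical: the
fixture reproduces topology, diameters and flow-split structure, not limb
anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (AnastomosisSpec, OpeningDecl, Segment, VesselSpec,
                       VesselTree)

__all__ = ["cylinder_tree", "yjunction_tree", "forearm_trees", "ForearmFixture"]

MM = 1e-3


def cylinder_tree(radius: float = 2.0 * MM, length: float = 4.0 * MM,
                  name: str = "cylinder") -> VesselTree:
    """A straight axis-aligned tube with an inlet cap at z=0 and an outlet
    cap at z=length (the Poiseuille benchmark geometry)."""
    seg = Segment(p0=np.array([0.0, 0.0, 0.0]),
                  p1=np.array([0.0, 0.0, length]), r0=radius, r1=radius)
    vessel = VesselSpec(name=name, segments=[seg], openings=[
        OpeningDecl(id="inlet", role="inlet", segment=0, end="start"),
        OpeningDecl(id="outlet", role="outlet", segment=0, end="end"),
    ])
    return VesselTree(name=name, vessels=[vessel])


def yjunction_tree(radius: float = 1.0 * MM, trunk_length: float = 6.0 * MM,
                   branch_offset: float = 3.0 * MM,
                   branch_length: float = 6.0 * MM) -> VesselTree:
    """A symmetric Y: one trunk inlet splitting into two mirrored branches."""
    z0 = trunk_length
    z1 = z0 + branch_offset
    z2 = z1 + branch_length
    trunk = VesselSpec(name="trunk", segments=[
        Segment(p0=np.array([0.0, 0.0, 0.0]), p1=np.array([0.0, 0.0, z0]),
                r0=radius, r1=radius)],
        openings=[OpeningDecl(id="inlet", role="inlet", segment=0, end="start")])
    branches = []
    for sign, label in ((1, "left"), (-1, "right")):
        segs = [
            Segment(p0=np.array([0.0, 0.0, z0]),
                    p1=np.array([sign * branch_offset, 0.0, z1]),
                    r0=radius, r1=radius),
            Segment(p0=np.array([sign * branch_offset, 0.0, z1]),
                    p1=np.array([sign * branch_offset, 0.0, z2]),
                    r0=radius, r1=radius),
        ]
        branches.append(VesselSpec(name=label, segments=segs, openings=[
            OpeningDecl(id=f"outlet_{label}", role="outlet", segment=1, end="end")]))
    return VesselTree(name="yjunction", vessels=[trunk, *branches])


@dataclass
class ForearmFixture:
    """The coupled arterial/venous forearm pair plus its coupling metadata."""

    arterial: VesselTree
    venous: VesselTree
    dx: float
    arterial_inlet: str = "brachial_in"
    arterial_outlets: tuple[str, ...] = ("radial_out", "ulnar_out")
    venous_inlets: tuple[str, ...] = ()
    venous_outlets: tuple[str, ...] = ("cephalic_out", "basilic_out",
                                       "minor_a_out", "minor_b_out")
    cephalic_inlets: tuple[str, ...] = ()
    anastomosis: AnastomosisSpec | None = None
    notes: dict = field(default_factory=dict)


def forearm_trees(dx: float = 0.2 * MM) -> ForearmFixture:
    """Build the healthy forearm fixture at the recommended spacing.

    Arterial side: a brachial inlet (2.2 mm diameter) splitting into
    mirror-symmetric radial/ulnar-like branches with 2.0 mm terminal
    outlets at the wrist plane.  Venous side: four parallel trunks
    (cephalic, basilic, two minor veins) drained by proximal outlets and
    fed by 12 lateral 1.6 mm capillary feeders near the wrist: 2 on the
    cephalic, 2 on the basilic and 4 on each minor vein.  This split keeps
    the major-vein share of the bed flow small enough that an anastomosis
    carrying ~a fifth of the arterial flow redistributes outflow the way
    an end-to-side fistula does (cephalic up, basilic down).
    """
    z_end = 16.0 * MM

    # --- arterial tree -------------------------------------------------
    # mirror-symmetric radial/ulnar branches: matched branch resistances keep
    # the healthy terminal velocities equal, so the flow-weighted bed
    # aggregation is exact for the healthy baseline.  Vessels are kept wide
    # and short relative to anatomy so the lattice pressure drop (and with it
    # the quasi-compressible density variation) stays well under a percent.
    brachial = VesselSpec(name="brachial", segments=[
        Segment(p0=np.array([0.0, 0.0, 0.0]), p1=np.array([0.0, 0.0, 6 * MM]),
                r0=1.1 * MM, r1=1.0 * MM),
    ], openings=[OpeningDecl(id="brachial_in", role="inlet", segment=0, end="start")])

    def arm_branch(name: str, side: int, outlet_id: str) -> VesselSpec:
        x = side * 4 * MM
        return VesselSpec(name=name, segments=[
            Segment(p0=np.array([0.0, 0.0, 6 * MM]), p1=np.array([x, 0.0, 12 * MM]),
                    r0=1.0 * MM, r1=1.0 * MM),
            Segment(p0=np.array([x, 0.0, 12 * MM]), p1=np.array([x, 0.0, z_end]),
                    r0=1.0 * MM, r1=1.0 * MM),
        ], openings=[OpeningDecl(id=outlet_id, role="outlet", segment=1, end="end")])

    radial = arm_branch("radial", -1, "radial_out")
    ulnar = arm_branch("ulnar", +1, "ulnar_out")
    arterial = VesselTree(name="arterial", vessels=[brachial, radial, ulnar])

    # --- venous tree ---------------------------------------------------
    trunk_x = {"cephalic": 0.0, "minor_a": 2.8 * MM,
               "minor_b": 5.6 * MM, "basilic": 8.4 * MM}
    feeder_plan = {"cephalic": 2, "minor_a": 4, "minor_b": 4, "basilic": 2}
    vessels: list[VesselSpec] = []
    venous_inlets: list[str] = []
    cephalic_inlets: list[str] = []
    for tname, x in trunk_x.items():
        out_id = f"{tname}_out"
        vessels.append(VesselSpec(name=tname, segments=[
            Segment(p0=np.array([x, 0.0, 0.0]), p1=np.array([x, 0.0, z_end]),
                    r0=1.2 * MM, r1=0.8 * MM)],
            openings=[OpeningDecl(id=out_id, role="outlet", segment=0, end="start")]))
        n_feed = feeder_plan[tname]
        slots = [(12.8 * MM, 1), (15.2 * MM, 1), (12.8 * MM, -1), (15.2 * MM, -1)]
        for k in range(n_feed):
            zf, side = slots[k]
            fid = f"{tname}_in_{k}"
            seg = Segment(p0=np.array([x, 0.0, zf]),
                          p1=np.array([x, side * 2.4 * MM, zf]),
                          r0=0.8 * MM, r1=0.8 * MM)
            vessels.append(VesselSpec(name=f"{tname}_feeder_{k}", segments=[seg],
                                      openings=[OpeningDecl(id=fid, role="inlet",
                                                            segment=0, end="end")]))
            venous_inlets.append(fid)
            if tname == "cephalic":
                cephalic_inlets.append(fid)
    venous = VesselTree(name="venous", vessels=vessels)

    # anastomosis diameter follows the local cephalic-vein diameter, as an
    # end-to-side fistula's junction is sized by the vein it uses
    anastomosis = AnastomosisSpec(
        artery="radial", vein="cephalic",
        artery_point=np.array([-4 * MM, 0.0, 14 * MM]),
        vein_point=np.array([0.0, 0.0, 10 * MM]),
        direction=np.array([-1.0, 0.0, 0.0]),
        diameter=1.9 * MM,
        seal_openings=tuple(cephalic_inlets),
        stub_length=1.2 * MM,
    )

    return ForearmFixture(
        arterial=arterial, venous=venous, dx=dx,
        venous_inlets=tuple(venous_inlets),
        cephalic_inlets=tuple(cephalic_inlets),
        anastomosis=anastomosis,
        notes={"inlet_diameter_mm": 2.2,
               "anastomosis_diameter_mm": 1.9,
               "n_venous_inlets": len(venous_inlets)},
    )
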