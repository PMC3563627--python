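"""Generic heart-to-hand vascular network: construction, discretization and
surgical modification.

The network is a graph of tapered vessel segments between named nodes, with
three-element windkessel terminals standing in for the omitted peripheral
circulation, a prescribed-pressure venous outlet, and optional lumped
elements: the anastomosis (the surgical artery-to-vein connection of a
vascular access) and stenosis inserts.

The generic geometry shipped here (segment lengths, default radii, wall
thickness, Young's moduli, and which protocol stations cover which segment
ends) is a set of packaged, versioned constants chosen to be anatomically
plausible for an adult arm — it is model input, not clinical truth. All
values can be overridden before personalization.

Units at this interface: radii/thickness mm, lengths cm, E kPa, pressures
mmHg, impedance/resistance mmHg·min/ml, compliance ml/mmHg.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import networkx as nx

GEOMETRY_VERSION = "1.0"

#: maximum 1D element length used when discretizing segments (cm)
MAX_ELEMENT_LENGTH_CM = 5.0

#: prescribed pressure at the venous outlet (subclavian vein end), mmHg
VENOUS_OUTLET_PRESSURE_MMHG = 10.0

#: default anastomosis angles per site, degrees
DEFAULT_ANASTOMOSIS_ANGLE = {"lower_arm": 45.0, "upper_arm": 60.0}

#: default wall thickness as a fraction of the local radius
WALL_THICKNESS_FRACTION = 0.10


class NetworkError(ValueError):
    """Raised for invalid network construction or modification requests."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """A tapered vessel between two nodes.

    Radii vary linearly with arc length from ``r_p`` at the proximal node to
    ``r_d`` at the distal node. Positions along the segment are arc length in
    cm from the proximal end (0-based).
    """

    name: str
    role: str                 # "artery" | "vein"
    proximal_node: str
    distal_node: str
    r_p: float                # mm
    r_d: float                # mm
    length: float             # cm
    youngs_modulus: float     # kPa
    h_p: float = 0.0          # mm; 0 -> default fraction of radius
    h_d: float = 0.0
    measured: bool = False    # covered by a protocol measurement

    def __post_init__(self) -> None:
        if self.role not in ("artery", "vein"):
            raise NetworkError(f"segment {self.name}: unknown role {self.role!r}")
        if min(self.r_p, self.r_d, self.length, self.youngs_modulus) <= 0:
            raise NetworkError(f"segment {self.name}: r, L, E must be positive")
        if self.h_p <= 0:
            self.h_p = WALL_THICKNESS_FRACTION * self.r_p
        if self.h_d <= 0:
            self.h_d = WALL_THICKNESS_FRACTION * self.r_d

    def radius_at(self, position_cm: float) -> float:
        """Local radius (mm) at arc length ``position_cm`` from the proximal end."""
        x = position_cm / self.length
        return self.r_p + (self.r_d - self.r_p) * x


@dataclass
class Element1D:
    """One discretized 1D element (length capped at MAX_ELEMENT_LENGTH_CM);
    interior properties are linear interpolants between the end values."""

    proximal_node: str
    distal_node: str
    r_p: float      # mm
    r_d: float      # mm
    h_p: float      # mm
    h_d: float      # mm
    youngs_modulus: float  # kPa
    length: float   # cm

    @property
    def area_p(self) -> float:
        """Proximal cross-sectional area, mm^2."""
        return math.pi * self.r_p ** 2

    @property
    def area_d(self) -> float:
        """Distal cross-sectional area, mm^2."""
        return math.pi * self.r_d ** 2


@dataclass
class WindkesselTerminal:
    """Three-element windkessel: characteristic impedance Z in series with a
    parallel peripheral resistance R and compliance C, draining to p_out."""

    node: str
    Z: float           # mmHg.min/ml
    R: float           # mmHg.min/ml
    C: float           # ml/mmHg
    p_out: float = VENOUS_OUTLET_PRESSURE_MMHG  # mmHg
    name: str = ""

    def __post_init__(self) -> None:
        if self.Z < 0 or self.R < 0 or self.C < 0:
            raise NetworkError(f"windkessel at {self.node}: Z, R, C must be >= 0")


@dataclass
class AnastomosisJunction:
    """Lumped artery-to-vein connection with a flow-dependent pressure loss."""

    feeding_artery_area: float   # mm^2
    draining_vein_area: float    # mm^2
    angle_deg: float

    def __post_init__(self) -> None:
        if self.feeding_artery_area <= 0 or self.draining_vein_area <= 0:
            raise NetworkError("anastomosis areas must be positive")
        if not (0.0 < self.angle_deg <= 90.0):
            raise NetworkError("anastomosis angle must be in (0, 90] degrees")


@dataclass
class StenosisInsert:
    """Localized narrowing: reference area A_0 narrowed to A_s over length L_s."""

    length: float            # cm
    reference_area: float    # mm^2
    diseased_area: float     # mm^2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError("stenosis length must be positive")
        if not (0.0 < self.diseased_area <= self.reference_area):
            raise NetworkError("stenosis requires 0 < A_s <= A_0")

    @property
    def severity(self) -> float:
        """Area reduction 1 - A_s/A_0 (0 = none, 0.75 = severe)."""
        return 1.0 - self.diseased_area / self.reference_area


def stenosis_from_severity(severity: float, reference_area: float,
                           length: float) -> StenosisInsert:
    """Build a StenosisInsert from an area-reduction severity in [0, 1)."""
    return StenosisInsert(length=length, reference_area=reference_area,
                          diseased_area=reference_area * (1.0 - severity))


@dataclass
class VAConfiguration:
    """Choice of vascular-access configuration.

    Supported pairings: lower_arm radial-cephalic (radiocephalic, 45 deg);
    upper_arm brachial-cephalic or brachial-basilic (60 deg).
    """

    site: str = "lower_arm"
    artery: str = "radial"
    vein: str = "cephalic"
    anastomosis_angle: Optional[float] = None

    def __post_init__(self) -> None:
        valid = {
            ("lower_arm", "radial", "cephalic"),
            ("upper_arm", "brachial", "cephalic"),
            ("upper_arm", "brachial", "basilic"),
        }
        if (self.site, self.artery, self.vein) not in valid:
            raise NetworkError(
                f"unsupported VA configuration: {self.site}/{self.artery}/{self.vein}")
        if self.anastomosis_angle is None:
            self.anastomosis_angle = DEFAULT_ANASTOMOSIS_ANGLE[self.site]


@dataclass
class PlacedStenosis:
    """A stenosis insert placed on a (split) vessel, occupying its own span
    between two nodes."""

    vessel: str
    position: float          # cm from the original segment's proximal end
    insert: StenosisInsert
    proximal_node: str = ""
    distal_node: str = ""


@dataclass
class VascularNetwork:
    """Graph of vessel segments, terminals and lumped elements between the
    heart (inflow node) and the hand."""

    segments: dict[str, VesselSegment] = field(default_factory=dict)
    terminals: dict[str, WindkesselTerminal] = field(default_factory=dict)
    inflow_node: str = "heart"
    venous_outlet_node: Optional[str] = None
    venous_outlet_pressure: float = VENOUS_OUTLET_PRESSURE_MMHG
    anastomosis: Optional[AnastomosisJunction] = None
    anastomosis_artery_node: Optional[str] = None
    anastomosis_vein_node: Optional[str] = None
    anastomosis_artery_segment: Optional[str] = None
    anastomosis_vein_segment: Optional[str] = None
    stenoses: list[PlacedStenosis] = field(default_factory=list)
    global_diameter_factor: float = 1.0
    # station label -> list of (segment name, "r_p"|"r_d") slots
    stations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # station labels whose diameters enter the uncertainty analysis
    uncertain_arterial_stations: list[str] = field(default_factory=list)
    uncertain_venous_stations: list[str] = field(default_factory=list)
    config: Optional[VAConfiguration] = None
    preoperative: bool = True

    # -- graph helpers ------------------------------------------------------

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for seg in self.segments.values():
            out.add(seg.proximal_node)
            out.add(seg.distal_node)
        for st in self.stenoses:
            out.add(st.proximal_node)
            out.add(st.distal_node)
        if self.anastomosis is not None:
            out.add(self.anastomosis_artery_node)
            out.add(self.anastomosis_vein_node)
        return out

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for seg in self.segments.values():
            g.add_edge(seg.proximal_node, seg.distal_node, key=seg.name)
        for i, st in enumerate(self.stenoses):
            g.add_edge(st.proximal_node, st.distal_node, key=f"stenosis{i}")
        if self.anastomosis is not None:
            g.add_edge(self.anastomosis_artery_node, self.anastomosis_vein_node,
                       key="anastomosis")
        return g

    def validate(self) -> None:
        g = self.graph()
        if self.inflow_node not in g:
            raise NetworkError("inflow node not part of the graph")
        if not nx.is_connected(g):
            raise NetworkError("network graph is not connected")
        if self.venous_outlet_node is not None and self.venous_outlet_node not in g:
            raise NetworkError("venous outlet node not part of the graph")
        # every arterial leaf must carry a terminal (or be the inflow)
        for node in g.nodes:
            if g.degree(node) == 1 and node not in (self.inflow_node,
                                                    self.venous_outlet_node):
                roles = {self.segments[k].role
                         for _, _, k in g.edges(node, keys=True)
                         if k in self.segments}
                if "artery" in roles and node not in self.terminals:
                    raise NetworkError(f"arterial leaf {node} has no terminal")

    def station_radius_slots(self, label: str) -> list[tuple[str, str]]:
        return self.stations[label]

    def set_station_radius(self, label: str, radius_mm: float,
                           mark_measured: bool = True) -> None:
        """Write a radius value to all (segment, end) slots of a station."""
        for seg_name, end in self.stations[label]:
            if seg_name not in self.segments:
                continue
            setattr(self.segments[seg_name], end, radius_mm)
            if mark_measured:
                self.segments[seg_name].measured = True

    def get_station_radius(self, label: str) -> float:
        seg_name, end = self.stations[label][0]
        return getattr(self.segments[seg_name], end)

    def refresh_anastomosis_areas(self) -> None:
        """Recompute the anastomosis areas from the adjacent segment radii
        (call after any radius update)."""
        if self.anastomosis is None:
            return
        art = self.segments[self.anastomosis_artery_segment]
        vein = self.segments[self.anastomosis_vein_segment]
        r_a = art.r_d if art.distal_node == self.anastomosis_artery_node else art.r_p
        r_v = vein.r_p if vein.proximal_node == self.anastomosis_vein_node else vein.r_d
        self.anastomosis.feeding_artery_area = math.pi * r_a ** 2
        self.anastomosis.draining_vein_area = math.pi * r_v ** 2

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "geometry_version": GEOMETRY_VERSION,
            "segments": [asdict(s) for s in self.segments.values()],
            "terminals": [asdict(t) for t in self.terminals.values()],
            "inflow_node": self.inflow_node,
            "venous_outlet_node": self.venous_outlet_node,
            "venous_outlet_pressure": self.venous_outlet_pressure,
            "global_diameter_factor": self.global_diameter_factor,
            "stations": {k: [list(slot) for slot in v]
                         for k, v in self.stations.items()},
            "uncertain_arterial_stations": self.uncertain_arterial_stations,
            "uncertain_venous_stations": self.uncertain_venous_stations,
            "preoperative": self.preoperative,
            "config": asdict(self.config) if self.config else None,
            "stenoses": [
                {"vessel": st.vessel, "position": st.position,
                 "proximal_node": st.proximal_node, "distal_node": st.distal_node,
                 "insert": asdict(st.insert)}
                for st in self.stenoses],
        }
        if self.anastomosis is not None:
            d["anastomosis"] = {
                **asdict(self.anastomosis),
                "artery_node": self.anastomosis_artery_node,
                "vein_node": self.anastomosis_vein_node,
                "artery_segment": self.anastomosis_artery_segment,
                "vein_segment": self.anastomosis_vein_segment,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VascularNetwork":
        net = cls(
            inflow_node=d["inflow_node"],
            venous_outlet_node=d.get("venous_outlet_node"),
            venous_outlet_pressure=d.get("venous_outlet_pressure",
                                         VENOUS_OUTLET_PRESSURE_MMHG),
            global_diameter_factor=d.get("global_diameter_factor", 1.0),
            preoperative=d.get("preoperative", True),
        )
        for s in d["segments"]:
            seg = VesselSegment(**s)
            net.segments[seg.name] = seg
        for t in d["terminals"]:
            wk = WindkesselTerminal(**t)
            net.terminals[wk.node] = wk
        net.stations = {k: [tuple(slot) for slot in v]
                        for k, v in d.get("stations", {}).items()}
        net.uncertain_arterial_stations = d.get("uncertain_arterial_stations", [])
        net.uncertain_venous_stations = d.get("uncertain_venous_stations", [])
        if d.get("config"):
            net.config = VAConfiguration(**d["config"])
        for st in d.get("stenoses", []):
            net.stenoses.append(PlacedStenosis(
                vessel=st["vessel"], position=st["position"],
                insert=StenosisInsert(**st["insert"]),
                proximal_node=st["proximal_node"], distal_node=st["distal_node"]))
        if d.get("anastomosis"):
            a = d["anastomosis"]
            net.anastomosis = AnastomosisJunction(
                feeding_artery_area=a["feeding_artery_area"],
                draining_vein_area=a["draining_vein_area"],
                angle_deg=a["angle_deg"])
            net.anastomosis_artery_node = a["artery_node"]
            net.anastomosis_vein_node = a["vein_node"]
            net.anastomosis_artery_segment = a["artery_segment"]
            net.anastomosis_vein_segment = a["vein_segment"]
        return net

    def save_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path: str) -> "VascularNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Generic geometry table (packaged constants, version GEOMETRY_VERSION)
# ---------------------------------------------------------------------------

# name, role, proximal node, distal node, r_p mm, r_d mm, L cm, E kPa
_ARTERIAL_SEGMENTS = [
    ("aortic_arch",    "artery", "heart",      "n_arch",      12.0, 11.5,  6.0, 400.0),
    ("subclavian_a",   "artery", "n_arch",     "n_subax",      4.5,  4.0, 10.0, 400.0),
    ("axillary_a",     "artery", "n_subax",    "n_axbr",       4.0,  3.5, 12.0, 400.0),
    ("brachial_prox",  "artery", "n_axbr",     "n_br_mid",     3.5,  2.9, 11.0, 500.0),
    ("brachial_dist",  "artery", "n_br_mid",   "n_elbow",      2.9,  2.4, 11.0, 500.0),
    ("radial_prox",    "artery", "n_elbow",    "n_ra_mid",     1.5,  1.3, 12.0, 800.0),
    ("radial_dist",    "artery", "n_ra_mid",   "n_wrist",      1.3,  1.1, 11.0, 800.0),
    ("ulnar_a",        "artery", "n_elbow",    "n_ulnar_end",  1.6,  1.35, 24.0, 800.0),
    ("palmar_arch",    "artery", "n_wrist",    "n_ulnar_end",  1.1,  1.1,  8.0, 800.0),
]

_VEIN_E_KPA = 150.0

# venous chains; proximal end is the peripheral (hand-side) end so that
# postoperative flow runs proximal -> distal toward the outlet
_VENOUS_SEGMENTS = {
    "cephalic": [
        ("cephalic_forearm_d", "vein", "v_wrist",   "v_cf_mid",  1.5, 1.8, 12.0, _VEIN_E_KPA),
        ("cephalic_forearm_p", "vein", "v_cf_mid",  "v_elbow",   1.8, 2.1, 12.0, _VEIN_E_KPA),
        ("cephalic_upper_d",   "vein", "v_elbow",   "v_cu_mid",  2.1, 2.4, 13.0, _VEIN_E_KPA),
        ("cephalic_upper_p",   "vein", "v_cu_mid",  "v_deltoid", 2.4, 2.7, 13.0, _VEIN_E_KPA),
        ("subclavian_v",       "vein", "v_deltoid", "v_out",     4.2, 4.5, 10.0, _VEIN_E_KPA),
    ],
    "basilic": [
        ("basilic_upper_d",    "vein", "v_elbow",   "v_bu_mid",  1.9, 2.3, 12.0, _VEIN_E_KPA),
        ("basilic_upper_p",    "vein", "v_bu_mid",  "v_axilla",  2.3, 2.7, 12.0, _VEIN_E_KPA),
        ("axillary_v",         "vein", "v_axilla",  "v_deltoid", 3.2, 3.8, 12.0, _VEIN_E_KPA),
        ("subclavian_v",       "vein", "v_deltoid", "v_out",     4.2, 4.5, 10.0, _VEIN_E_KPA),
    ],
}

# protocol station table: 10 arterial + 14 venous = 24 vessel-mapping
# locations; each maps to the (segment, end) radius slots it constrains
PROTOCOL_STATIONS: dict[str, list[tuple[str, str]]] = {
    # arterial
    "A_SUB0": [("subclavian_a", "r_p")],
    "A_SUB":  [("subclavian_a", "r_d"), ("axillary_a", "r_p")],
    "A_AX":   [("axillary_a", "r_d"), ("brachial_prox", "r_p")],
    "A_BR1":  [("brachial_prox", "r_d"), ("brachial_dist", "r_p")],
    "A_BR2":  [("brachial_dist", "r_d")],
    "A_RA1":  [("radial_prox", "r_p")],
    "A_RA2":  [("radial_prox", "r_d"), ("radial_dist", "r_p")],
    "A_RA3":  [("radial_dist", "r_d")],
    "A_UL1":  [("ulnar_a", "r_p")],
    "A_UL2":  [("ulnar_a", "r_d")],
    # venous
    "V_CF1":  [("cephalic_forearm_d", "r_p")],
    "V_CF2":  [("cephalic_forearm_d", "r_d"), ("cephalic_forearm_p", "r_p")],
    "V_CF3":  [("cephalic_forearm_p", "r_d")],
    "V_CU1":  [("cephalic_upper_d", "r_p")],
    "V_CU2":  [("cephalic_upper_d", "r_d"), ("cephalic_upper_p", "r_p")],
    "V_CU3":  [("cephalic_upper_p", "r_d")],
    "V_BU1":  [("basilic_upper_d", "r_p")],
    "V_BU2":  [("basilic_upper_d", "r_d"), ("basilic_upper_p", "r_p")],
    "V_BF1":  [("basilic_upper_p", "r_d")],
    "V_AXV1": [("axillary_v", "r_p")],
    "V_AXV2": [("axillary_v", "r_d")],
    "V_SCV1": [("subclavian_v", "r_p")],
    "V_SCV2": [("subclavian_v", "r_d")],
    "V_CF0":  [("cephalic_forearm_d", "r_p")],  # duplicate wrist reading slot
}

# stations whose diameters are varied in the geometric uncertainty analysis,
# per configuration (the VA in-/outflow tract)
UNCERTAIN_STATIONS = {
    ("lower_arm", "radial", "cephalic"): {
        "arterial": ["A_SUB", "A_AX", "A_BR1", "A_BR2", "A_RA1", "A_RA2", "A_RA3"],
        "venous": ["V_CF1", "V_CF2", "V_CF3", "V_CU1", "V_CU2", "V_CU3"],
    },
    ("upper_arm", "brachial", "cephalic"): {
        "arterial": ["A_SUB", "A_AX", "A_BR1", "A_BR2"],
        "venous": ["V_CU1", "V_CU2", "V_CU3", "V_SCV1"],
    },
    ("upper_arm", "brachial", "basilic"): {
        "arterial": ["A_SUB", "A_AX", "A_BR1", "A_BR2"],
        "venous": ["V_BU1", "V_BU2", "V_BF1", "V_AXV1", "V_AXV2"],
    },
}

# default windkessel terminals (node, name, Z, R, C) in clinical units;
# values are re-estimated during personalization from measured flows
_DEFAULT_TERMINALS = [
    ("n_arch",      "rest_of_body", 1.0e-4, 0.0167, 1.5),
    ("n_br_mid",    "arm_muscle",   0.02,   2.0,    0.01),
    ("n_wrist",     "hand_radial",  0.05,   2.4,    0.01),
    ("n_ulnar_end", "hand_ulnar",   0.05,   1.8,    0.01),
]

#: nodes whose adjacent segments are never protocol-measured (candidates for
#: the global diameter factor)
_ANASTOMOSIS_SITE = {
    ("lower_arm", "radial", "cephalic"): ("n_wrist", "radial_dist", "v_wrist",
                                          "cephalic_forearm_d"),
    ("upper_arm", "brachial", "cephalic"): ("n_elbow", "brachial_dist", "v_elbow",
                                            "cephalic_upper_d"),
    ("upper_arm", "brachial", "basilic"): ("n_elbow", "brachial_dist", "v_elbow",
                                           "basilic_upper_d"),
}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_generic_arm_network(config: VAConfiguration,
                              preoperative: bool = False) -> VascularNetwork:
    """Build the generic heart-to-hand network for a VA configuration.

    Preoperative networks contain the arterial tree and its windkessel
    terminals only (the veins carry no flow before surgery, as the terminals
    drain directly to the venous outlet pressure). Postoperative networks add
    the configured venous drainage chain and exactly one anastomosis between
    the configured artery and vein, with the venous outlet held at
    ``VENOUS_OUTLET_PRESSURE_MMHG``.
    """
    net = VascularNetwork(config=config, preoperative=preoperative)
    for row in _ARTERIAL_SEGMENTS:
        seg = VesselSegment(name=row[0], role=row[1], proximal_node=row[2],
                            distal_node=row[3], r_p=row[4], r_d=row[5],
                            length=row[6], youngs_modulus=row[7])
        net.segments[seg.name] = seg
    for node, name, z, r, c in _DEFAULT_TERMINALS:
        net.terminals[node] = WindkesselTerminal(node=node, Z=z, R=r, C=c,
                                                 name=name)
    if not preoperative:
        for row in _VENOUS_SEGMENTS[config.vein]:
            seg = VesselSegment(name=row[0], role=row[1], proximal_node=row[2],
                                distal_node=row[3], r_p=row[4], r_d=row[5],
                                length=row[6], youngs_modulus=row[7])
            net.segments[seg.name] = seg
        net.venous_outlet_node = "v_out"
        art_node, art_seg, vein_node, vein_seg = _ANASTOMOSIS_SITE[
            (config.site, config.artery, config.vein)]
        net.anastomosis_artery_node = art_node
        net.anastomosis_vein_node = vein_node
        net.anastomosis_artery_segment = art_seg
        net.anastomosis_vein_segment = vein_seg
        net.anastomosis = AnastomosisJunction(
            feeding_artery_area=1.0, draining_vein_area=1.0,
            angle_deg=config.anastomosis_angle)
        net.refresh_anastomosis_areas()

    key = (config.site, config.artery, config.vein)
    present = set(net.segments)
    net.stations = {label: slots for label, slots in PROTOCOL_STATIONS.items()
                    if all(seg in present for seg, _ in slots)}
    unc = UNCERTAIN_STATIONS[key]
    net.uncertain_arterial_stations = [s for s in unc["arterial"]
                                       if s in net.stations]
    net.uncertain_venous_stations = [s for s in unc["venous"]
                                     if s in net.stations]
    net.validate()
    return net


def discretize_segment(segment: VesselSegment,
                       max_len: float = MAX_ELEMENT_LENGTH_CM) -> list[Element1D]:
    """Split a segment into ``ceil(L/max_len)`` equal-length 1D elements.

    End radii of the chain equal the segment's, interior node radii and wall
    thicknesses are linear interpolants.
    """
    if max_len <= 0:
        raise NetworkError("max_len must be positive")
    if segment.length <= 0:
        raise NetworkError("segment length must be positive")
    n = max(1, math.ceil(segment.length / max_len - 1e-12))
    dl = segment.length / n
    elements = []
    for i in range(n):
        f0, f1 = i / n, (i + 1) / n
        node_p = segment.proximal_node if i == 0 else f"{segment.name}:{i}"
        node_d = segment.distal_node if i == n - 1 else f"{segment.name}:{i + 1}"
        elements.append(Element1D(
            proximal_node=node_p, distal_node=node_d,
            r_p=segment.r_p + (segment.r_d - segment.r_p) * f0,
            r_d=segment.r_p + (segment.r_d - segment.r_p) * f1,
            h_p=segment.h_p + (segment.h_d - segment.h_p) * f0,
            h_d=segment.h_p + (segment.h_d - segment.h_p) * f1,
            youngs_modulus=segment.youngs_modulus, length=dl))
    return elements


def apply_global_diameter_factor(network: VascularNetwork,
                                 f_D: float) -> VascularNetwork:
    """Scale the radii of all non-measured segments by ``f_D``; measured
    (protocol-covered) locations are left unchanged. Returns a new network."""
    if f_D <= 0:
        raise NetworkError("global diameter factor must be positive")
    out = copy.deepcopy(network)
    for seg in out.segments.values():
        if not seg.measured:
            seg.r_p *= f_D
            seg.r_d *= f_D
            seg.h_p *= f_D
            seg.h_d *= f_D
    out.global_diameter_factor = network.global_diameter_factor * f_D
    out.refresh_anastomosis_areas()
    return out


def insert_stenosis(network: VascularNetwork, vessel: str, position: float,
                    insert: StenosisInsert) -> VascularNetwork:
    """Insert a stenosis element occupying ``[position, position + L_s]`` cm
    of ``vessel``; the vessel is split around it, topology otherwise
    unchanged. Returns a new network."""
    if vessel not in network.segments:
        raise NetworkError(f"unknown vessel {vessel!r}")
    seg = network.segments[vessel]
    if position < 0 or position + insert.length > seg.length + 1e-9:
        raise NetworkError("stenosis does not fit within the vessel")
    for st in network.stenoses:
        if st.vessel.startswith(vessel) or vessel.startswith(st.vessel):
            raise NetworkError(f"vessel {vessel!r} already carries a stenosis")
    out = copy.deepcopy(network)
    seg = out.segments.pop(vessel)
    sten_p = f"{vessel}@sten_p"
    sten_d = f"{vessel}@sten_d"
    x0, x1 = position, position + insert.length
    if x0 > 1e-9:
        out.segments[f"{vessel}__pre"] = VesselSegment(
            name=f"{vessel}__pre", role=seg.role,
            proximal_node=seg.proximal_node, distal_node=sten_p,
            r_p=seg.r_p, r_d=seg.radius_at(x0), length=x0,
            youngs_modulus=seg.youngs_modulus, measured=seg.measured)
    else:
        sten_p = seg.proximal_node
    if seg.length - x1 > 1e-9:
        out.segments[f"{vessel}__post"] = VesselSegment(
            name=f"{vessel}__post", role=seg.role,
            proximal_node=sten_d, distal_node=seg.distal_node,
            r_p=seg.radius_at(x1), r_d=seg.r_d, length=seg.length - x1,
            youngs_modulus=seg.youngs_modulus, measured=seg.measured)
    else:
        sten_d = seg.distal_node
    if network.anastomosis_artery_segment == vessel or \
            network.anastomosis_vein_segment == vessel:
        # keep the anastomosis area lookup valid after the split
        repl = f"{vessel}__post" if f"{vessel}__post" in out.segments \
            else f"{vessel}__pre"
        if out.anastomosis_artery_segment == vessel:
            out.anastomosis_artery_segment = repl
        if out.anastomosis_vein_segment == vessel:
            out.anastomosis_vein_segment = repl
    out.stenoses.append(PlacedStenosis(
        vessel=vessel, position=position, insert=copy.deepcopy(insert),
        proximal_node=sten_p, distal_node=sten_d))
    # re-route station slots that referenced the split segment
    for label, slots in out.stations.items():
        new_slots = []
        for seg_name, end in slots:
            if seg_name == vessel:
                if end == "r_p" and f"{vessel}__pre" in out.segments:
                    seg_name = f"{vessel}__pre"
                elif end == "r_d" and f"{vessel}__post" in out.segments:
                    seg_name = f"{vessel}__post"
                else:
                    continue
            new_slots.append((seg_name, end))
        out.stations[label] = new_slots
    out.validate()
    return out
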