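"""Network builder: aorta with major branches, coronary tree, scenarios.

The arterial domain is a tree rooted at the aortic valve. The aorta and its
major side branches (22 segments, geometry after Stergiopulos et al.) carry
three-element windkessel terminals; the coronary tree -- left main splitting
into LAD and LCx, plus an RCA with the same geometry as the LAD -- carries
serial microvascular ladder terminals loaded by intramyocardial pressure.

Coronary radii: every terminal 1D vessel (14 in all) has a 1 mm radius;
parent radii follow Murray's law (cube-sum) up the tree; wall thickness is
10% of the radius throughout (kappa = 0.1). Side branches leave the LAD/LCx/
RCA main stems at 1.5 cm intervals.

Scenario overlays insert an epicardial stenosis in the mid (c) segment of the
LAD with microvascular hyperaemia, or reconfigure the heart and aortic valve
for left-ventricular hypertrophy with aortic valve stenosis (LVH-AVS), or
swap the coronary wall law for the stiff linear comparison law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

from .heart import HeartParams, lvh_params
from .lumped import (CoronaryBed, WindkesselElement, RCA_PIM_SCALE,
                     default_coronary_bed)
from .stenosis import StenosisSpec
from .valves import ValveParams, avs_params

RHO = 1050.0    # blood density, kg/m^3
ETA = 0.004     # dynamic viscosity, Pa s

#: Systemic arterial geometry: (nr, name, L mm, r_prox mm, r_dist mm, h mm,
#: parent nr or None, terminal (Z MPa s/m^3, R_w GPa s/m^3, C_w mm^3/Pa) or None)
SYSTEMIC_TABLE = [
    (1,  "ascending aorta A", 5.0,  14.7, 14.7, 1.63, None, None),
    (2,  "ascending aorta B", 35.0, 14.7, 14.4, 1.63, 1,    None),
    (3,  "innominate",        30.0, 6.20, 6.20, 0.80, 2,    (52.2, 0.36, 4.125)),
    (4,  "aortic arch A",     20.0, 11.2, 11.2, 1.26, 2,    None),
    (5,  "left carotid",      30.0, 3.70, 3.70, 0.63, 4,    (161.0, 1.80, 0.835)),
    (6,  "aortic arch B",     39.0, 10.7, 10.7, 1.15, 4,    None),
    (7,  "left subclavian",   30.0, 4.23, 4.23, 0.66, 6,    (118.0, 1.19, 1.259)),
    (8,  "thoracic aorta A",  52.0, 9.99, 9.99, 1.10, 6,    None),
    (9,  "intercostals",      30.0, 2.00, 2.00, 0.49, 8,    (659.0, 11.7, 0.128)),
    (10, "thoracic aorta B",  104.0, 6.75, 6.75, 1.00, 8,   None),
    (11, "celiac",            30.0, 3.00, 3.00, 0.64, 10,   (273.0, 3.40, 0.442)),
    (12, "abdominal aorta A", 53.0, 6.10, 6.10, 0.90, 10,   None),
    (13, "sup. mesenteric",   30.0, 4.35, 4.35, 0.69, 12,   (112.0, 1.09, 1.374)),
    (14, "abdominal aorta B", 10.0, 5.90, 5.90, 0.80, 12,   None),
    (15, "left renal",        30.0, 2.60, 2.60, 0.53, 14,   (356.0, 5.28, 0.284)),
    (16, "abdominal aorta C", 10.0, 5.90, 5.90, 0.80, 14,   None),
    (17, "right renal",       30.0, 2.60, 2.60, 0.53, 16,   (356.0, 5.28, 0.284)),
    (18, "abdominal aorta D", 106.0, 5.80, 5.48, 0.75, 16,  None),
    (19, "inf. mesenteric",   30.0, 1.60, 1.60, 0.43, 18,   (108.0, 23.1, 0.065)),
    (20, "abdominal aorta E", 10.0, 5.20, 5.20, 0.65, 18,   None),
    (21, "l. common iliac",   30.0, 3.68, 3.68, 0.60, 20,   (15.9, 1.83, 0.820)),
    (22, "r. common iliac",   30.0, 3.68, 3.68, 0.60, 20,   (15.9, 1.83, 0.820)),
]

CORONARY_KAPPA = 0.1
TERMINAL_RADIUS = 1.0e-3        # m, all 14 terminal coronary vessels
BRANCH_SPACING = 15e-3          # side branches every 1.5 cm
SIDE_BRANCH_LENGTH = 10e-3      # side-branch 1D vessel length (not printed; 1 cm)
LMCA_LENGTH = 5e-3
LAD_LENGTH = 75e-3              # four side branches -> five terminals
LCX_LENGTH = 60e-3              # three side branches -> four terminals


def murray_parent_radius(daughter_radii) -> float:
    """Murray's law: r_parent^3 = sum of daughter r^3."""
    radii = [r for r in daughter_radii]
    if not radii or min(radii) <= 0:
        raise ValueError("need at least one positive daughter radius")
    return sum(r ** 3 for r in radii) ** (1.0 / 3.0)


@dataclass
class SegmentDef:
    """One edge of the network tree.

    ``kind`` is 'vessel' for ordinary 1D segments and 'stenosis' for the
    rigid stenosis element (which then carries ``sten``). ``parent`` is the
    name of the upstream segment (None for the aortic root segment).
    """

    name: str
    parent: Optional[str]
    length: float
    r_prox: float
    r_dist: float
    h: float
    wall_kind: str = "linear"                  # 'linear'|'coronary'|'linear_stiff'
    terminal: WindkesselElement | CoronaryBed | None = None
    kind: str = "vessel"
    sten: StenosisSpec | None = None
    E: float | None = None                     # linear-wall Young's modulus override

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.r_prox + self.r_dist)


@dataclass
class NetworkSpec:
    """Tree of segments plus bookkeeping for scenario overlays."""

    segments: dict[str, SegmentDef] = field(default_factory=dict)
    scenario: str = "healthy"

    def add(self, seg: SegmentDef) -> None:
        if seg.name in self.segments:
            raise ValueError(f"duplicate segment {seg.name}")
        if seg.parent is not None and seg.parent not in self.segments:
            raise ValueError(f"segment {seg.name}: unknown parent {seg.parent}")
        self.segments[seg.name] = seg

    def children(self, name: str) -> list[str]:
        return [s.name for s in self.segments.values() if s.parent == name]

    @property
    def root(self) -> str:
        roots = [s.name for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {roots}")
        return roots[0]

    def terminals(self) -> list[str]:
        return [s.name for s in self.segments.values() if s.terminal is not None]

    def validate(self) -> None:
        """Tree consistency: one root, no orphans, terminals are leaves."""
        _ = self.root
        for seg in self.segments.values():
            kids = self.children(seg.name)
            if seg.terminal is not None and kids:
                raise ValueError(f"terminal segment {seg.name} has children {kids}")
            if seg.terminal is None and not kids:
                raise ValueError(f"leaf segment {seg.name} lacks a terminal element")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {"scenario": self.scenario, "segments": {}}
        for seg in self.segments.values():
            d = {k: v for k, v in asdict(seg).items()
                 if k not in ("terminal", "sten") and v is not None}
            d.pop("name", None)
            if seg.terminal is not None:
                d["terminal"] = {"type": type(seg.terminal).__name__,
                                 **asdict(seg.terminal)}
            if seg.sten is not None:
                d["stenosis"] = {"length": seg.sten.length, "a0": seg.sten.a0,
                                 "diameter_reduction": seg.sten.diameter_reduction}
            out["segments"][seg.name] = d
        return out

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        spec = cls(scenario=data.get("scenario", "healthy"))
        pending = dict(data["segments"])
        while pending:
            progressed = False
            for name in list(pending):
                d = dict(pending[name])
                d.setdefault("parent", None)
                parent = d.get("parent")
                if parent is not None and parent not in spec.segments:
                    continue
                term = d.pop("terminal", None)
                sten = d.pop("stenosis", None)
                d.pop("kind", None)
                seg = SegmentDef(name=name, kind="vessel", **d)
                if term is not None:
                    ttype = term.pop("type")
                    seg.terminal = (WindkesselElement(**term) if ttype == "WindkesselElement"
                                    else CoronaryBed(**term))
                if sten is not None:
                    seg.kind = "stenosis"
                    seg.sten = StenosisSpec(**sten)
                spec.segments[name] = seg
                del pending[name]
                progressed = True
            if not progressed:
                raise ValueError(f"unresolvable parents in {list(pending)}")
        return spec


def build_systemic_tree(spec: NetworkSpec) -> None:
    """Aorta and major branches per the printed geometry table."""
    for nr, name, L, rp, rd, h, parent, term in SYSTEMIC_TABLE:
        terminal = None
        if term is not None:
            Z, Rw, Cw = term
            terminal = WindkesselElement(Z=Z * 1e6, R_w=Rw * 1e9, C_w=Cw * 1e-9)
        spec.add(SegmentDef(
            name=f"sys{nr:02d} {name}", parent=None if parent is None else _sysname(parent),
            length=L * 1e-3, r_prox=rp * 1e-3, r_dist=rd * 1e-3, h=h * 1e-3,
            wall_kind="linear", terminal=terminal))


def _sysname(nr: int) -> str:
    for row in SYSTEMIC_TABLE:
        if row[0] == nr:
            return f"sys{nr:02d} {row[1]}"
    raise KeyError(nr)


def _coronary_seg(name, parent, length, radius, terminal=None) -> SegmentDef:
    return SegmentDef(name=name, parent=parent, length=length,
                      r_prox=radius, r_dist=radius, h=CORONARY_KAPPA * radius,
                      wall_kind="coronary", terminal=terminal)


def _main_stem(spec: NetworkSpec, prefix: str, parent: str, total_length: float,
               pim_scale: float, hyperemia: float) -> None:
    """A coronary main stem with 1 mm side branches at 1.5 cm intervals.

    The stem beyond the last branch point is itself the distal terminal; the
    inter-branch pieces are labelled b, c, d, ... proximal to distal and sized
    by Murray's law from the 1 mm leaves upward.
    """
    n_branch = int(round(total_length / BRANCH_SPACING)) - 1
    n_pieces = n_branch + 1  # inter-branch pieces incl. the terminal tip
    labels = [chr(ord("b") + i) for i in range(n_branch)]
    bed = lambda: default_coronary_bed(pim_scale=pim_scale, hyperemia=hyperemia)
    # radii from the leaves up: tip is a 1 mm terminal; each junction adds a 1 mm branch
    radii_up = [TERMINAL_RADIUS]
    for _ in range(n_branch):
        radii_up.append(murray_parent_radius([radii_up[-1], TERMINAL_RADIUS]))
    stem_radii = radii_up[::-1]  # proximal piece first
    prev = parent
    for i, label in enumerate(labels):
        name = f"{prefix}_{label}"
        spec.add(_coronary_seg(name, prev, BRANCH_SPACING, stem_radii[i]))
        spec.add(_coronary_seg(f"{prefix}_a{i + 1}", name, SIDE_BRANCH_LENGTH,
                               TERMINAL_RADIUS, terminal=bed()))
        prev = name
    tip_length = total_length - n_branch * BRANCH_SPACING
    spec.add(_coronary_seg(f"{prefix}_tip", prev, tip_length, TERMINAL_RADIUS,
                           terminal=bed()))


def build_coronary_tree(spec: NetworkSpec, hyperemia: float = 1.0) -> None:
    """LMCA -> LAD + LCx, and an RCA with LAD geometry, off the aortic root.

    Ostia sit 5 mm distal to the aortic valve, i.e. at the distal node of the
    first (5 mm) ascending aorta segment.
    """
    ostium = _sysname(1)
    lad_prox = _stem_proximal_radius(LAD_LENGTH)
    lcx_prox = _stem_proximal_radius(LCX_LENGTH)
    lmca_r = murray_parent_radius([lad_prox, lcx_prox])
    spec.add(_coronary_seg("LMCA", ostium, LMCA_LENGTH, lmca_r))
    _main_stem(spec, "LAD", "LMCA", LAD_LENGTH, pim_scale=1.0, hyperemia=hyperemia)
    _main_stem(spec, "LCx", "LMCA", LCX_LENGTH, pim_scale=1.0, hyperemia=hyperemia)
    _main_stem(spec, "RCA", ostium, LAD_LENGTH, pim_scale=RCA_PIM_SCALE,
               hyperemia=hyperemia)


def _stem_proximal_radius(total_length: float) -> float:
    n_branch = int(round(total_length / BRANCH_SPACING)) - 1
    r = TERMINAL_RADIUS
    for _ in range(n_branch):
        r = murray_parent_radius([r, TERMINAL_RADIUS])
    return r


@dataclass
class ScenarioConfig:
    """Everything a simulation run needs besides numerics."""

    name: str
    network: NetworkSpec
    heart: HeartParams
    valves: ValveParams
    coronary_wall: str = "langewouters"   # or 'linear' (E = 1.5 MPa comparison)


#: printed stenosis geometries: % diameter reduction, length
MILD_STENOSIS = (50.0, 2.65e-3)
SEVERE_STENOSIS = (70.0, 7.48e-3)
HYPEREMIA_FACTOR = 5.0


def build_network(hyperemia: float = 1.0) -> NetworkSpec:
    spec = NetworkSpec()
    build_systemic_tree(spec)
    build_coronary_tree(spec, hyperemia=hyperemia)
    spec.validate()
    return spec


def insert_stenosis(spec: NetworkSpec, segment: str, diameter_reduction: float,
                    length: float) -> None:
    """Split ``segment`` and replace its mid portion by the stenosis element."""
    host = spec.segments[segment]
    if host.kind != "vessel":
        raise ValueError(f"{segment} is not a plain vessel")
    if length >= host.length:
        raise ValueError("stenosis longer than its host segment")
    side = 0.5 * (host.length - length)
    a0 = host.mean_radius
    sten = StenosisSpec(length=length, a0=a0, diameter_reduction=diameter_reduction)
    prox_name, sten_name, dist_name = (f"{segment}~prox", f"{segment}~sten",
                                       f"{segment}~dist")
    children = spec.children(segment)
    del spec.segments[segment]
    spec.add(SegmentDef(name=prox_name, parent=host.parent, length=side,
                        r_prox=host.r_prox, r_dist=a0, h=host.h,
                        wall_kind=host.wall_kind))
    spec.add(SegmentDef(name=sten_name, parent=prox_name, length=length,
                        r_prox=a0, r_dist=a0, h=host.h, wall_kind=host.wall_kind,
                        kind="stenosis", sten=sten))
    spec.add(SegmentDef(name=dist_name, parent=sten_name, length=side,
                        r_prox=a0, r_dist=host.r_dist, h=host.h,
                        wall_kind=host.wall_kind, terminal=host.terminal))
    for child in children:
        spec.segments[child].parent = dist_name


def apply_scenario(name: str, coronary_wall: str = "langewouters") -> ScenarioConfig:
    """Assemble a named scenario.

    Names: 'healthy'; 'stenosis-mild'/'stenosis-severe' (LAD c-segment lesion
    plus microvascular hyperaemia); 'lvh-pre'/'lvh-post' (LVH-AVS before and
    after aortic valve replacement).
    """
    heart, valves = HeartParams(), ValveParams()
    if name == "healthy" or name == "lvh-post":
        spec = build_network()
    elif name in ("stenosis-mild", "stenosis-severe"):
        spec = build_network(hyperemia=HYPEREMIA_FACTOR)
        pct, length = MILD_STENOSIS if name == "stenosis-mild" else SEVERE_STENOSIS
        insert_stenosis(spec, "LAD_c", pct, length)
    elif name == "lvh-pre":
        spec = build_network()
        heart, valves = lvh_params(), avs_params()
    else:
        raise ValueError(f"unknown scenario {name!r}")
    spec.scenario = name
    spec.validate()
    return ScenarioConfig(name=name, network=spec, heart=heart, valves=valves,
                          coronary_wall=coronary_wall)
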