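"""Phantom scenario registry: simulated tanks, anomalies and layouts.

Three electrode configurations are used throughout:

* **Model 0** — 16 equidistant surface electrodes, no internal electrode;
* **Model 1** — equidistant surface electrodes plus an internal electrode;
* **Model 2** — internal electrode with surface electrodes clustered more
  densely on the sector facing the ROI.

The registry reproduces the study conditions: a normalized single-anomaly
tank (background 1 S/m, anomaly 2 S/m, diameter 0.1428, centre (0.8, 0)),
a four-anomaly simulation in a 14 cm tank (0.029 S/m objects of 1 cm
diameter in 0.0418 S/m saline, internal electrode at (0.035, 0) m), the
four-carrot experiment layout (0.04 S/m objects of 2 cm diameter in
0.06 S/m saline) and the radish/potato cases (radish 0.038 S/m inside the
ROI at (0.056, 0); potato 0.029 S/m outside at case-specific positions) in
0.042 S/m saline.

The third and fourth simulated anomaly coordinates are listed identically
in the source description; the registry restores the fourth to
(0.05, +0.015) by symmetry with the experimental four-carrot layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .forward import ConductivityField
from .geometry import (
    DiskDomain,
    ElectrodeLayout,
    ROIRegion,
    TriangleMesh,
    compute_roi,
    make_layout,
)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Anomaly:
    """Disk-shaped conductivity anomaly."""

    center: Tuple[float, float]
    diameter: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and self.conductivity > 0):
            raise ScenarioError("anomaly diameter and conductivity must be positive")


@dataclass(frozen=True)
class PhantomScenario:
    """Complete description of one simulated phantom configuration."""

    name: str
    units: str
    domain_radius: float
    background: float
    anomalies: Tuple[Anomaly, ...]
    electrode_count: int = 16
    layout_mode: str = "equidistant"
    internal_position: Optional[Tuple[float, float]] = None
    protocol_scheme: str = "boundary_adjacent"
    cluster_fraction: float = 0.5
    cluster_sector: float = 2.0 * math.pi / 3.0
    roi_anomalies_inside: bool = False  # validated against the 5/6-rule ROI

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ScenarioError("background conductivity must be positive")
        for a in self.anomalies:
            if math.hypot(*a.center) + a.diameter / 2 >= self.domain_radius:
                raise ScenarioError(
                    f"anomaly at {a.center} extends outside the domain"
                )

    def layout(self) -> ElectrodeLayout:
        return make_layout(
            self.electrode_count,
            mode=self.layout_mode,
            domain=DiskDomain(self.domain_radius),
            internal_position=self.internal_position,
            cluster_fraction=self.cluster_fraction,
            cluster_sector=self.cluster_sector,
        )

    def roi(self) -> ROIRegion:
        return compute_roi(self.layout())

    def anomalies_inside(self, region: ROIRegion) -> Tuple[Anomaly, ...]:
        return tuple(a for a in self.anomalies if region.contains([a.center])[0])

    def anomalies_outside(self, region: ROIRegion) -> Tuple[Anomaly, ...]:
        return tuple(a for a in self.anomalies if not region.contains([a.center])[0])


def conductivity_fields(
    scenario: PhantomScenario,
    mesh: TriangleMesh,
    anomalies: Optional[Sequence[Anomaly]] = None,
) -> Tuple[ConductivityField, ConductivityField]:
    """Reference and perturbed conductivity fields on a mesh.

    A triangle takes an anomaly's conductivity iff its centroid lies inside
    the anomaly disk; later anomalies in the list win on (non-physical)
    overlaps.  Passing ``anomalies`` restricts the perturbation to a subset
    (used to split difference data into in-ROI / out-of-ROI components).
    """
    cen = mesh.centroids()
    ref = np.full(mesh.n_triangles, scenario.background)
    per = ref.copy()
    for a in scenario.anomalies if anomalies is None else anomalies:
        d = np.hypot(cen[:, 0] - a.center[0], cen[:, 1] - a.center[1])
        inside = d < a.diameter / 2
        if not inside.any():
            raise ScenarioError(
                f"mesh too coarse: no triangle centroid inside anomaly at {a.center}"
            )
        per[inside] = a.conductivity
    return (
        ConductivityField(ref, is_reference=True),
        ConductivityField(per, is_reference=False),
    )


def percent_contrast(sigma_object: float, sigma_background: float) -> float:
    """Conductivity contrast of an object vs its background, in percent.

    ``100 * (background - object) / background`` — e.g. radish at
    0.038 S/m in 0.042 S/m saline is 9.5 % lower than saline.
    """
    if sigma_object <= 0 or sigma_background <= 0:
        raise ScenarioError("conductivities must be positive")
    return 100.0 * (sigma_background - sigma_object) / sigma_background


def _single(name: str, mode: str, internal: Optional[Tuple[float, float]], scheme: str):
    return PhantomScenario(
        name=name,
        units="normalized",
        domain_radius=1.0,
        background=1.0,
        anomalies=(Anomaly(center=(0.8, 0.0), diameter=0.1428, conductivity=2.0),),
        layout_mode=mode,
        internal_position=internal,
        protocol_scheme=scheme,
        roi_anomalies_inside=internal is not None,
    )


_POTATO_POSITIONS = {
    "case1": (-0.056, 0.0),
    "case2": (-0.035, -0.04),
    "case3": (0.0, -0.056),
}


def _radish_potato(case: int) -> PhantomScenario:
    anomalies = [Anomaly(center=(0.056, 0.0), diameter=0.012, conductivity=0.038)]
    if case > 0:
        anomalies.append(
            Anomaly(
                center=_POTATO_POSITIONS[f"case{case}"],
                diameter=0.012,
                conductivity=0.029,
            )
        )
    return PhantomScenario(
        name=f"model2_radish_potato_case{case}",
        units="m",
        domain_radius=0.07,
        background=0.042,
        anomalies=tuple(anomalies),
        layout_mode="clustered",
        internal_position=(0.035, 0.0),
        protocol_scheme="internal_augmented",
    )


def _registry() -> Dict[str, PhantomScenario]:
    reg: Dict[str, PhantomScenario] = {}
    reg["model0_single"] = _single("model0_single", "equidistant", None, "boundary_adjacent")
    reg["model1_single"] = _single(
        "model1_single", "equidistant", (0.5, 0.0), "internal_augmented"
    )
    reg["model2_single"] = _single(
        "model2_single", "clustered", (0.5, 0.0), "internal_augmented"
    )
    reg["model2_four_anomaly_sim"] = PhantomScenario(
        name="model2_four_anomaly_sim",
        units="m",
        domain_radius=0.07,
        background=0.0418,
        anomalies=tuple(
            Anomaly(center=c, diameter=0.01, conductivity=0.029)
            for c in [(0.02, 0.015), (0.02, -0.015), (0.05, -0.015), (0.05, 0.015)]
        ),
        layout_mode="clustered",
        internal_position=(0.035, 0.0),
        protocol_scheme="internal_augmented",
        roi_anomalies_inside=True,
    )
    reg["model2_four_carrot"] = PhantomScenario(
        name="model2_four_carrot",
        units="m",
        domain_radius=0.07,
        background=0.06,
        anomalies=tuple(
            Anomaly(center=c, diameter=0.02, conductivity=0.04)
            for c in [(0.015, 0.02), (0.055, 0.02), (0.055, -0.02), (0.015, -0.02)]
        ),
        layout_mode="clustered",
        internal_position=(0.035, 0.0),
        protocol_scheme="internal_augmented",
    )
    for case in range(4):
        sc = _radish_potato(case)
        reg[sc.name] = sc
    return reg


_REGISTRY = _registry()


def scenario_names() -> Tuple[str, ...]:
    return tuple(_REGISTRY)


def scenario(name: str) -> PhantomScenario:
    """Look up a registered phantom scenario by name.

    Geometric validity (anomalies inside the domain, ROI-targeted
    anomalies inside the computed 5/6-rule ROI) is checked on every load.
    """
    if name not in _REGISTRY:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(_REGISTRY)}"
        )
    sc = _REGISTRY[name]
    if sc.roi_anomalies_inside:
        region = sc.roi()
        for a in sc.anomalies:
            if not region.contains([a.center])[0]:
                raise ScenarioError(
                    f"scenario {name}: anomaly at {a.center} is outside the ROI"
                )
    return sc
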