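"""Shared simulation fixtures.

The heavier objects (meshes, factorized forward solvers, sensitivity
matrices) are session-scoped: the single-anomaly models share one pixel
grid whose ROI comes from the Model-1 geometry, so cross-model comparisons
(cross-correlation, thresholds) operate on matched grids.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import eitroi as e

UNIT_H = 0.06  # mesh edge length for the normalized unit-disk phantoms
TANK_H = 0.004  # mesh edge length (m) for the 7 cm-radius tank phantoms
PIX = 32


@pytest.fixture(scope="session")
def roi_unit():
    """ROI disk of the Model-1 geometry (internal electrode at (0.5, 0))."""
    return e.compute_roi(e.scenario("model1_single").layout())


@pytest.fixture(scope="session")
def grid_unit(roi_unit):
    return e.build_pixel_grid(e.DiskDomain(1.0), PIX, roi_unit)


def _single_case(name, grid, h=UNIT_H):
    sc = e.scenario(name)
    layout = sc.layout()
    mesh = e.build_mesh(layout, h)
    protocol = e.make_protocol(layout, sc.protocol_scheme)
    sigma_ref, sigma_per = e.conductivity_fields(sc, mesh)
    solver = e.ForwardSolver(mesh, sigma_ref)
    v_ref = e.collect_data(mesh, sigma_ref, protocol, solver=solver)
    dv = e.collect_data(mesh, sigma_per, protocol) - v_ref
    S = e.compute_sensitivity(mesh, sigma_ref, protocol, grid, solver=solver)
    return SimpleNamespace(
        scenario=sc,
        layout=layout,
        mesh=mesh,
        protocol=protocol,
        sigma_ref=sigma_ref,
        sigma_per=sigma_per,
        solver=solver,
        v_ref=v_ref,
        dv=dv,
        grid=grid,
        S=S,
    )


@pytest.fixture(scope="session")
def model0(grid_unit):
    return _single_case("model0_single", grid_unit)


@pytest.fixture(scope="session")
def model1(grid_unit):
    return _single_case("model1_single", grid_unit)


@pytest.fixture(scope="session")
def model2(grid_unit):
    return _single_case("model2_single", grid_unit)


@pytest.fixture(scope="session")
def four_anomaly():
    """Model-2 four-anomaly simulation in the 7 cm tank."""
    sc = e.scenario("model2_four_anomaly_sim")
    layout = sc.layout()
    mesh = e.build_mesh(layout, TANK_H)
    roi = e.compute_roi(layout)
    grid = e.build_pixel_grid(layout.domain, PIX, roi)
    protocol = e.make_protocol(layout, sc.protocol_scheme)
    sigma_ref, sigma_per = e.conductivity_fields(sc, mesh)
    solver = e.ForwardSolver(mesh, sigma_ref)
    v_ref = e.collect_data(mesh, sigma_ref, protocol, solver=solver)
    dv = e.collect_data(mesh, sigma_per, protocol) - v_ref
    S = e.compute_sensitivity(mesh, sigma_ref, protocol, grid, solver=solver)
    F = e.build_filter(S)
    return SimpleNamespace(
        scenario=sc, layout=layout, mesh=mesh, roi=roi, grid=grid,
        protocol=protocol, sigma_ref=sigma_ref, solver=solver,
        v_ref=v_ref, dv=dv, S=S, F=F,
    )


@pytest.fixture(scope="session")
def radish_potato():
    """In-silico radish/potato study: reference + three potato positions."""
    sc0 = e.scenario("model2_radish_potato_case0")
    layout = sc0.layout()
    mesh = e.build_mesh(layout, TANK_H)
    roi = e.compute_roi(layout)
    grid = e.build_pixel_grid(layout.domain, PIX, roi)
    protocol = e.make_protocol(layout, sc0.protocol_scheme)
    sigma_ref, _ = e.conductivity_fields(sc0, mesh)
    solver = e.ForwardSolver(mesh, sigma_ref)
    v_ref = e.collect_data(mesh, sigma_ref, protocol, solver=solver)
    S = e.compute_sensitivity(mesh, sigma_ref, protocol, grid, solver=solver)
    F = e.build_filter(S)
    dvs = {}
    for case in range(4):
        scc = e.scenario(f"model2_radish_potato_case{case}")
        _, per = e.conductivity_fields(scc, mesh)
        dvs[f"case{case}"] = e.collect_data(mesh, per, protocol) - v_ref
    return SimpleNamespace(
        scenario=sc0, mesh=mesh, roi=roi, grid=grid, protocol=protocol,
        sigma_ref=sigma_ref, S=S, F=F, dvs=dvs,
    )
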