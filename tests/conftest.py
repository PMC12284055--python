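"""Shared fixtures: meshes and forward contexts reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import eitpsoc as e

CURRENT_A = 0.98e-3  # bench drive current


@pytest.fixture(scope="session")
def layout8() -> e.ElectrodeLayout:
    return e.ElectrodeLayout.equispaced(8)


@pytest.fixture(scope="session")
def pattern8(layout8) -> e.InjectionPattern:
    return e.adjacent_pattern(layout8)


@pytest.fixture(scope="session")
def mesh_small(layout8) -> e.DiskMesh:
    """Coarse mesh (~240 elements) for finite-difference work."""
    return e.build_disk_mesh(0.07, 200, layout8)


@pytest.fixture(scope="session")
def mesh_mid(layout8) -> e.DiskMesh:
    """Desk-default mesh (~1800 elements) for reconstruction work."""
    return e.build_disk_mesh(0.07, 1800, layout8)


@pytest.fixture(scope="session")
def mesh_fine(layout8) -> e.DiskMesh:
    """Finer mesh (~2500 elements) for the analytic-oracle comparison."""
    return e.build_disk_mesh(0.07, 2500, layout8)


@dataclass(frozen=True)
class ReconContext:
    """Homogeneous-background difference-imaging context for one campaign."""

    mesh: e.DiskMesh
    pattern: e.InjectionPattern
    background: e.ConductivityField
    vh: np.ndarray
    jac: e.SensitivityMatrix
    op: e.ReconOperator

    def scenario_voltages(self, name: str, **kwargs) -> np.ndarray:
        field = e.apply_phantom(e.make_phantom(name, **kwargs), self.mesh)
        return e.protocol_voltages(self.mesh, field, self.pattern, CURRENT_A)

    def scenario_image(self, name: str, **kwargs) -> e.PixelImage:
        dv = e.normalized_difference(self.vh, self.scenario_voltages(name, **kwargs))
        return e.apply_recon(self.op, dv)


def _make_context(mesh, pattern, homog_name) -> ReconContext:
    background = e.apply_phantom(e.make_phantom(homog_name), mesh)
    vh = e.protocol_voltages(mesh, background, pattern, CURRENT_A)
    jac = e.jacobian(mesh, background, pattern, CURRENT_A)
    op = e.build_recon_operator(jac, mesh, v_ref=vh)
    return ReconContext(
        mesh=mesh, pattern=pattern, background=background, vh=vh, jac=jac, op=op
    )


@pytest.fixture(scope="session")
def saline_context(mesh_mid, pattern8) -> ReconContext:
    return _make_context(mesh_mid, pattern8, "saline-homog")


@pytest.fixture(scope="session")
def agar_context(mesh_mid, pattern8) -> ReconContext:
    return _make_context(mesh_mid, pattern8, "agar-homog")
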