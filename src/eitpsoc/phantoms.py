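"""Synthetic phantoms and noise profiles for the bench experiments.

The named scenarios mirror the two experimental campaigns: a 7 cm saline
tank (0.278 S/m) probed with an insulating PVC rod (r = 2.1 cm) and a
conductive copper rod (r = 2.15 cm), and agar phantoms (0.217 S/m,
emulating lower-pelvis tissue) with saline-filled cavities of radius
2.7/2.5/1.3 cm at cavity conductivities 1.227/1.890/2.07 S/m.  The copper
and PVC conductivities are clipped stand-ins (1e3 and 1e-6 S/m): only the
contrast sign matters for difference imaging, and extreme values hurt FEM
conditioning.

Noise profiles are named after the multiplexer switching times of the
bench characterization: short settling (1 ms) gives low-variance captures,
longer switching (10/100 ms) progressively larger scatter plus a slow
drift across the measurement slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import NoiseModel
from .forward import ConductivityField, DiskMesh, element_centroids

__all__ = [
    "PhantomSpec",
    "SCENARIOS",
    "NOISE_PROFILES",
    "make_phantom",
    "apply_phantom",
    "make_noise_model",
]

TANK_RADIUS_M = 0.07
SALINE_SIGMA = 0.278  # S/m
AGAR_SIGMA = 0.217  # S/m
PVC_SIGMA = 1e-6  # insulating stand-in
COPPER_SIGMA = 1e3  # conductive stand-in, clipped for conditioning
AGAR_CAVITY_RADII = {"large": 0.027, "medium": 0.025, "small": 0.013}
AGAR_CAVITY_SIGMAS = (1.227, 1.890, 2.07)


@dataclass(frozen=True)
class PhantomSpec:
    """Tank geometry plus circular inclusions."""

    name: str
    tank_radius_m: float
    background_sigma: float
    inclusions: tuple[tuple[float, float, float, float], ...]  # (x, y, r, sigma)

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ValueError("background conductivity must be positive")
        for x, y, r, s in self.inclusions:
            if s <= 0 or r <= 0:
                raise ValueError("inclusion radius and conductivity must be positive")
            if np.hypot(x, y) + r > self.tank_radius_m:
                raise ValueError("inclusion extends outside the tank")


SCENARIOS = (
    "saline-homog",
    "saline-pvc",
    "saline-copper",
    "saline-both",
    "agar-homog",
    "agar-large",
    "agar-medium",
    "agar-small",
)


def make_phantom(name: str, cavity_sigma: float = 1.227) -> PhantomSpec:
    """Named phantom scenario from the experimental campaigns.

    The rods in the saline scenarios sit at (+-3 cm, 0) so an off-center
    inclusion exercises localization; agar cavities are centered.
    ``cavity_sigma`` selects the saline conductivity filling an agar cavity.
    """
    pvc = (0.03, 0.0, 0.021, PVC_SIGMA)
    copper = (-0.03, 0.0, 0.0215, COPPER_SIGMA)
    if name == "saline-homog":
        inclusions: tuple = ()
        background = SALINE_SIGMA
    elif name == "saline-pvc":
        inclusions, background = (pvc,), SALINE_SIGMA
    elif name == "saline-copper":
        inclusions, background = (copper,), SALINE_SIGMA
    elif name == "saline-both":
        inclusions, background = (pvc, copper), SALINE_SIGMA
    elif name == "agar-homog":
        inclusions, background = (), AGAR_SIGMA
    elif name in ("agar-large", "agar-medium", "agar-small"):
        r = AGAR_CAVITY_RADII[name.split("-")[1]]
        inclusions, background = ((0.0, 0.0, r, float(cavity_sigma)),), AGAR_SIGMA
    else:
        raise ValueError(f"unknown scenario {name!r}; choose one of {SCENARIOS}")
    return PhantomSpec(
        name=name,
        tank_radius_m=TANK_RADIUS_M,
        background_sigma=background,
        inclusions=inclusions,
    )


def apply_phantom(spec: PhantomSpec, mesh: DiskMesh) -> ConductivityField:
    """Rasterize a phantom onto a mesh by element-centroid membership."""
    if not np.isclose(mesh.radius, spec.tank_radius_m, rtol=1e-9):
        raise ValueError("mesh radius does not match the phantom tank radius")
    for a in range(len(spec.inclusions)):
        for b in range(a + 1, len(spec.inclusions)):
            xa, ya, ra, _ = spec.inclusions[a]
            xb, yb, rb, _ = spec.inclusions[b]
            if np.hypot(xa - xb, ya - yb) < ra + rb:
                raise ValueError("overlapping inclusions")
    centroids = element_centroids(mesh)
    sigma = np.full(mesh.n_elements, spec.background_sigma)
    for x, y, r, s in spec.inclusions:
        inside = np.hypot(centroids[:, 0] - x, centroids[:, 1] - y) <= r
        sigma[inside] = s
    return ConductivityField(values=sigma)


#: (target SNR dB, drift per slot as a fraction of the additive sd)
NOISE_PROFILES = {
    "1ms": (60.0, 0.0),
    "10ms": (50.0, 0.05),
    "100ms": (10.0, 0.2),
}


def make_noise_model(
    profile: str, seed: int = 0, reference_voltage: float = 2e-4
) -> NoiseModel:
    """Noise model for a named multiplexer switching-time profile.

    The additive sd is set so a channel at ``reference_voltage`` (default
    0.2 mV, the median adjacent-protocol differential voltage at 0.98 mA in
    the 2D saline tank model) lands near the profile's target SNR; longer
    switching times add a per-slot drift.  Only the ordering across
    profiles is contractual.
    """
    if profile not in NOISE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {set(NOISE_PROFILES)}")
    snr_db, drift_frac = NOISE_PROFILES[profile]
    sd = reference_voltage * 10 ** (-snr_db / 20.0)
    return NoiseModel(additive_sd=sd, drift_rate=drift_frac * sd, seed=seed)
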