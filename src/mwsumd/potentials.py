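"""Analytic model potentials for the toy propagator.

Each potential exposes ``energy`` (kcal/mol) and ``gradient`` (kcal/mol/Å)
over full (N, 3) coordinate arrays, plus an optional ``frozen`` index list
of atoms the integrator must not move (marker/anchor particles). Gradients
are exact derivatives of the energy; ``check_gradient`` verifies this by
central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnalyticPotential",
    "HarmonicWell",
    "DoubleWell1D",
    "MuellerBrown",
    "BindingFunnel",
    "ZeroPotential",
]


class AnalyticPotential:
    """Base class: energy/gradient over all finite coordinates."""

    identifier: str = "potential"
    frozen: list[int] = []

    def energy(self, coordinates: np.ndarray) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, coordinates: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def check_gradient(
        self, coordinates: np.ndarray, h: float = 1e-5, tol: float = 1e-5
    ) -> float:
        """Max |numeric − analytic| gradient component (central differences).

        Raises AssertionError when the deviation exceeds ``tol``.
        """
        coordinates = np.asarray(coordinates, float)
        analytic = self.gradient(coordinates)
        numeric = np.zeros_like(analytic)
        for i in range(coordinates.shape[0]):
            for k in range(3):
                plus = coordinates.copy()
                minus = coordinates.copy()
                plus[i, k] += h
                minus[i, k] -= h
                numeric[i, k] = (self.energy(plus) - self.energy(minus)) / (2 * h)
        dev = float(np.abs(numeric - analytic).max())
        if dev > tol:
            raise AssertionError(f"gradient check failed: max deviation {dev:.2e}")
        return dev


@dataclass
class ZeroPotential(AnalyticPotential):
    """Free particles; useful for diffusion checks."""

    identifier: str = "zero"
    frozen: list[int] = field(default_factory=list)

    def energy(self, coordinates):
        return 0.0

    def gradient(self, coordinates):
        return np.zeros_like(np.asarray(coordinates, float))


@dataclass
class HarmonicWell(AnalyticPotential):
    """Isotropic harmonic well: E = ½ k Σ|x_i − x0_i|²  (k in kcal/mol/Å²)."""

    k: float = 1.0
    centers: np.ndarray | None = None  # (N, 3); origin when None
    identifier: str = "harmonic"
    frozen: list[int] = field(default_factory=list)

    def _disp(self, coordinates):
        coordinates = np.asarray(coordinates, float)
        if self.centers is None:
            return coordinates
        return coordinates - np.asarray(self.centers, float)

    def energy(self, coordinates):
        d = self._disp(coordinates)
        return float(0.5 * self.k * (d**2).sum())

    def gradient(self, coordinates):
        return self.k * self._disp(coordinates)


@dataclass
class DoubleWell1D(AnalyticPotential):
    """Symmetric quartic double well along x for atom 0.

    E = B ((x/a)² − 1)² + tilt·x + ½ k_conf (y² + z²), with minima near
    x = ±a and a barrier of height ~B (kcal/mol) at x ≈ 0; a nonzero
    ``tilt`` (kcal/mol/Å) biases one basin below the other. Other atoms
    (markers) are listed in ``frozen`` and feel no force.
    """

    barrier: float = 1.0  # kcal/mol
    a: float = 5.0  # Å; half the minimum separation
    k_conf: float = 2.0  # kcal/mol/Å² lateral confinement
    tilt: float = 0.0  # kcal/mol/Å linear bias along x
    identifier: str = "double_well"
    frozen: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be > 0")

    def energy(self, coordinates):
        x, y, z = np.asarray(coordinates, float)[0]
        u = (x / self.a) ** 2 - 1.0
        return float(
            self.barrier * u**2 + self.tilt * x + 0.5 * self.k_conf * (y**2 + z**2)
        )

    def gradient(self, coordinates):
        coordinates = np.asarray(coordinates, float)
        g = np.zeros_like(coordinates)
        x, y, z = coordinates[0]
        u = (x / self.a) ** 2 - 1.0
        g[0, 0] = self.barrier * 4.0 * u * x / self.a**2 + self.tilt
        g[0, 1] = self.k_conf * y
        g[0, 2] = self.k_conf * z
        return g


# canonical three-minimum surface constants from the adaptive-sampling literature
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


@dataclass
class MuellerBrown(AnalyticPotential):
    """The standard Müller–Brown three-minimum surface in the xy-plane.

    Atom 0 moves on the surface (scaled by ``scale`` into kcal/mol) with
    harmonic confinement along z. The canonical constants are bundled; the
    surface's deepest minimum lies near (−0.558, 1.442).
    """

    scale: float = 1.0
    k_z: float = 10.0
    identifier: str = "mueller_brown"
    frozen: list[int] = field(default_factory=list)

    def _terms(self, x: float, y: float) -> np.ndarray:
        dx = x - _MB_x0
        dy = y - _MB_y0
        return _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)

    def energy(self, coordinates):
        x, y, z = np.asarray(coordinates, float)[0]
        return float(self.scale * self._terms(x, y).sum() + 0.5 * self.k_z * z**2)

    def gradient(self, coordinates):
        coordinates = np.asarray(coordinates, float)
        g = np.zeros_like(coordinates)
        x, y, z = coordinates[0]
        dx = x - _MB_x0
        dy = y - _MB_y0
        terms = self._terms(x, y)
        g[0, 0] = self.scale * (terms * (2 * _MB_a * dx + _MB_b * dy)).sum()
        g[0, 1] = self.scale * (terms * (_MB_b * dx + 2 * _MB_c * dy)).sum()
        g[0, 2] = self.k_z * z
        return g

    def surface_energy(self, x: float, y: float) -> float:
        return float(self.scale * self._terms(x, y).sum())


@dataclass
class BindingFunnel(AnalyticPotential):
    """A mobile ligand bead and a harmonically restrained receptor pocket.

    Atom 0 is the ligand; atoms 1..n are receptor beads restrained to their
    home positions with stiffness ``k_restraint``. The ligand feels a
    short-range Gaussian attraction of depth ``well_depth`` to the pocket
    center, a weak long-range funnel bias ``bias`` (kcal/mol/Å, pulling
    toward the pocket at any distance), lateral confinement toward the
    approach axis, and repulsive cores against the receptor beads.
    """

    home: np.ndarray = None  # (n+1, 3) home/reference positions (row 0 unused)
    site_center: np.ndarray = None  # (3,)
    well_depth: float = 3.0  # kcal/mol
    well_width: float = 2.0  # Å
    bias: float = 0.02  # kcal/mol/Å
    k_restraint: float = 10.0  # kcal/mol/Å²
    k_lateral: float = 0.05  # kcal/mol/Å²
    core_sigma: float = 2.0  # Å
    core_eps: float = 0.5  # kcal/mol
    identifier: str = "binding_funnel"
    frozen: list[int] = field(default_factory=list)

    def energy(self, coordinates):
        c = np.asarray(coordinates, float)
        lig = c[0]
        rec = c[1:]
        e = 0.5 * self.k_restraint * ((rec - self.home[1:]) ** 2).sum()
        d = lig - self.site_center
        r2 = float(d @ d)
        r = np.sqrt(r2)
        e += -self.well_depth * np.exp(-r2 / (2 * self.well_width**2))
        e += self.bias * r
        e += 0.5 * self.k_lateral * (lig[1] ** 2 + lig[2] ** 2)
        rv = lig - rec
        rr = np.sqrt((rv**2).sum(axis=1))
        e += (self.core_eps * (self.core_sigma / rr) ** 12).sum()
        return float(e)

    def gradient(self, coordinates):
        c = np.asarray(coordinates, float)
        g = np.zeros_like(c)
        lig = c[0]
        rec = c[1:]
        g[1:] = self.k_restraint * (rec - self.home[1:])
        d = lig - self.site_center
        r2 = float(d @ d)
        r = max(np.sqrt(r2), 1e-12)
        gauss = -self.well_depth * np.exp(-r2 / (2 * self.well_width**2))
        g[0] += gauss * (-d / self.well_width**2)
        g[0] += self.bias * d / r
        g[0] += self.k_lateral * np.array([0.0, lig[1], lig[2]])
        rv = lig - rec
        rr2 = (rv**2).sum(axis=1)
        rr = np.sqrt(rr2)
        # d/dr (eps (sigma/r)^12) = -12 eps sigma^12 / r^13
        coef = -12.0 * self.core_eps * self.core_sigma**12 / rr**14
        core_g = coef[:, None] * rv
        g[0] += core_g.sum(axis=0)
        g[1:] -= core_g
        return g
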