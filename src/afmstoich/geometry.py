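"""Spherical-cap geometry of adsorbed globular particles.

A protein particle adsorbed on mica is modelled as a spherical cap: the
upper part of a sphere of radius ``R`` protruding a height ``h`` above the
surface, with ``0 < h <= 2R``.  The height profile at lateral distance
``rho`` from the particle centre is

    z(rho) = h - R + sqrt(R**2 - rho**2)        (clipped at zero)

Two derived quantities drive the whole analysis:

* the radius of the cross-section at half the apex height,
  ``r = sqrt(R*h - h**2/4)``, which is what an AFM grain analysis measures;
* the molecular-volume estimate ``Vm = (pi*h/6) * (3*r**2 + h**2)``,
  the spherical-segment formula evaluated at the half-height radius.

The shape of a cap is conveniently parameterised by its aspect ratio
``alpha = h / R`` in ``(0, 2]``: flat pancakes for small ``alpha``, a full
sphere sitting on the surface at ``alpha = 2``.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InvalidSpecError

ASPECT_MAX = 2.0


def half_height_radius(sphere_radius: float, height: float) -> float:
    """Radius of the cap cross-section at half the apex height.

    Solves ``z(r) = h/2`` for the profile above, giving
    ``r = sqrt(R*h - h**2/4)``.
    """
    return math.sqrt(sphere_radius * height - height * height / 4.0)


def base_radius(sphere_radius: float, height: float) -> float:
    """Radius of the cap's footprint on the surface.

    ``sqrt(2*R*h - h**2)`` while the cap is less than a hemisphere; for
    ``h > R`` the widest cross-section is the sphere's equator, radius R.
    """
    if height >= sphere_radius:
        return sphere_radius
    return math.sqrt(2.0 * sphere_radius * height - height * height)


def cap_profile(rho, sphere_radius: float, height: float):
    """Height of the cap surface at lateral distance(s) ``rho`` from centre.

    Vectorised over ``rho``; zero outside the footprint.
    """
    rho = np.asarray(rho, dtype=float)
    inside = rho < sphere_radius
    z = np.zeros_like(rho)
    z[inside] = height - sphere_radius + np.sqrt(
        sphere_radius**2 - rho[inside] ** 2
    )
    return np.clip(z, 0.0, None)


def cap_molecular_volume(sphere_radius: float, height: float) -> float:
    """Molecular volume of a cap via the half-height-radius formula."""
    r = half_height_radius(sphere_radius, height)
    return math.pi * height / 6.0 * (3.0 * r * r + height * height)


def solve_cap(volume: float, aspect: float) -> tuple[float, float, float]:
    """Cap dimensions ``(R, h, r)`` with the given molecular volume and aspect.

    At fixed aspect ``alpha = h/R`` the molecular volume is
    ``Vm = (pi * alpha**2 * R**3 / 6) * (3 + alpha/4)``, so the sphere
    radius follows in closed form.

    Raises
    ------
    InvalidSpecError
        If ``aspect`` is outside ``(0, 2]`` or ``volume`` is not positive.
    """
    if not (0.0 < aspect <= ASPECT_MAX):
        raise InvalidSpecError(f"cap aspect h/R must lie in (0, 2], got {aspect}")
    if volume <= 0.0:
        raise InvalidSpecError(f"cap volume must be positive, got {volume}")
    coeff = math.pi * aspect * aspect / 6.0 * (3.0 + aspect / 4.0)
    sphere_radius = (volume / coeff) ** (1.0 / 3.0)
    height = aspect * sphere_radius
    return sphere_radius, height, half_height_radius(sphere_radius, height)


def aspect_for_height(volume: float, height: float) -> float:
    """Aspect ratio of the cap with the given molecular volume and apex height.

    Inverts ``Vm = (pi*h/6)(3 r**2 + h**2)`` for ``r``, then recovers
    ``R = (r**2 + h**2/4) / h``.  Useful for building populations whose
    particles have a prescribed height (AFM heights of membrane proteins on
    mica are typically a few nm regardless of lateral size).
    """
    if volume <= 0.0 or height <= 0.0:
        raise InvalidSpecError("volume and height must be positive")
    r_sq = (6.0 * volume / (math.pi * height) - height * height) / 3.0
    if r_sq <= 0.0:
        raise InvalidSpecError(
            f"no cap of volume {volume} nm^3 has apex height {height} nm"
        )
    sphere_radius = (r_sq + height * height / 4.0) / height
    aspect = height / sphere_radius
    if aspect > ASPECT_MAX:
        raise InvalidSpecError(
            f"volume {volume} nm^3 at height {height} nm needs aspect > 2"
        )
    return aspect
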