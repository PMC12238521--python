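"""Flat-port refraction models and underwater -> equivalent-air conversion.

A camera sealed behind a plane-parallel glass window ("flat port") sees the
underwater world through two refractions: water -> glass at the outer face and
glass -> air at the inner face.  The bending magnifies off-axis image
coordinates (refractive pincushion distortion), so pixel positions measured
underwater disagree with the positions an in-air pinhole camera would record.

This module implements three 1-D coordinate maps between the underwater image
coordinate ``x_r`` and the equivalent-air coordinate ``x_a`` (both in mm on
the plane at distance ``d`` from the external focal point, which coincides
with the metric image plane when ``d`` equals the focal length — the default
configuration):

* ``SINGLE``  — one water/air interface; the glass slab is ignored.  The
  correction is closed-form:
  ``x_a = d * tan(arcsin(n_a * sin(arctan(x_r / d)) / n_r))``.
* ``PARALLEL`` — water/glass/air with the window parallel to the sensor.
  Both coordinates are parameterised by the water-side incidence angle α::

      x_r(α) = T tan(arcsin(n_r sin α / n_g)) + (d − T) tan(arcsin(n_r sin α / n_a))
      x_a(α) = T tan(arcsin(n_a sin α / n_g)) + (d − T) tan α

  and each direction of the map solves the matching equation for α by
  bracketed root finding (both are strictly increasing in α).
* ``TILTED`` — the window tilted by β relative to the sensor plane::

      x_r(α) = T [tan(arcsin(n_r sin α / n_g)) − tan β]
               + (d − T/cos β) tan(arcsin(n_r sin α / n_a) − β)
      x_a(α) = T [tan(arcsin(n_a sin α / n_g)) − tan β]
               + (d − T/cos β) tan(α − β)

  which reduces exactly to ``PARALLEL`` at β = 0.  Note that for β > 0 the
  tilted maps are *not* odd functions of x.

Limits tie the family together: TILTED(β=0) == PARALLEL, PARALLEL(T→0) ==
SINGLE, and SINGLE with n_water == n_air is the identity.  Total internal
reflection bounds the water-side angle at ``arcsin(n_air / n_water)``; inputs
beyond the corresponding coordinate raise
:class:`~fishstereo.errors.TotalInternalReflectionError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .camera import CameraIntrinsics, metric_to_pixel, pixel_to_metric
from .errors import (
    PortGeometryError,
    RefractionDomainError,
    TotalInternalReflectionError,
)
from .keypoints import FishKeypoints

__all__ = [
    "correction_grid",
    "FlatPort",
    "RefractionModel",
    "snell_refract",
    "correct_single",
    "observe_single",
    "correct_parallel",
    "observe_parallel",
    "correct_tilted",
    "observe_tilted",
    "correct",
    "observe",
    "magnification_ratio",
    "correct_keypoints",
    "observe_keypoints",
]

_TIR_MARGIN = 1e-9  # rad kept clear of the critical angle in brackets
_BRENTQ_XTOL = 1e-14
_BRENTQ_RTOL = 8.9e-16


@dataclass(frozen=True)
class FlatPort:
    """Geometry and optics of a flat-port waterproof housing.

    Parameters
    ----------
    d_mm
        Distance from the camera's external focal point to the outer face of
        the window (mm).  Defaults in this package set d equal to the focal
        length, which makes the underwater -> air mapping depth-independent.
    t_mm
        Window (glass) thickness (mm), 0 <= T <= d.
    n_air, n_glass, n_water
        Refractive indices (all >= 1; n_water < n_glass in the regime
        modelled here).
    tilt_rad
        Angle β between the sensor plane and the window plane (rad),
        0 <= β < π/2.  Used only by the TILTED model.
    """

    d_mm: float
    t_mm: float
    n_air: float = 1.0
    n_glass: float = 1.6
    n_water: float = 1.33
    tilt_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (self.d_mm >= self.t_mm >= 0.0):
            raise ValueError(f"need d >= T >= 0, got d={self.d_mm}, T={self.t_mm}")
        if min(self.n_air, self.n_glass, self.n_water) < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if not (self.n_water < self.n_glass):
            raise ValueError("flat-port model assumes n_water < n_glass")
        if not (0.0 <= self.tilt_rad < math.pi / 2):
            raise ValueError("tilt must lie in [0, pi/2)")

    @property
    def critical_angle(self) -> float:
        """Water-side TIR bound arcsin(n_air / n_water), rad."""
        return math.asin(self.n_air / self.n_water)


class RefractionModel(Enum):
    """Which flat-port conversion to apply."""

    SINGLE = "single"
    PARALLEL = "parallel"
    TILTED = "tilted"


def snell_refract(theta_in: float, n_from: float, n_to: float) -> float:
    """Snell's law: transmitted angle (rad) for incidence *theta_in* in [0, π/2).

    Raises :class:`TotalInternalReflectionError` when
    ``n_from * sin(theta_in) / n_to > 1``.
    """
    if not (0.0 <= theta_in < math.pi / 2):
        raise ValueError("incidence angle must lie in [0, pi/2)")
    s = n_from * math.sin(theta_in) / n_to
    if s > 1.0:
        raise TotalInternalReflectionError(
            f"n_from*sin(theta)/n_to = {s:.6f} > 1 (theta={theta_in:.6f} rad)"
        )
    return math.asin(s)


# ---------------------------------------------------------------------------
# SINGLE model (one water/air interface, closed form)
# ---------------------------------------------------------------------------


def correct_single(x_r: float, port: FlatPort) -> float:
    """Underwater coordinate -> equivalent-air coordinate, single interface.

    ``x_a = d tan(arcsin(n_a sin(arctan(x_r / d)) / n_r))``; odd in x_r and
    defined for all finite x_r (n_a/n_r < 1 keeps the arcsin in-domain).
    """
    x_r = float(x_r)
    alpha_r = math.atan2(abs(x_r), port.d_mm)
    x_a = port.d_mm * math.tan(math.asin(port.n_air * math.sin(alpha_r) / port.n_water))
    return math.copysign(x_a, x_r) if x_r != 0.0 else 0.0


def observe_single(x_a: float, port: FlatPort) -> float:
    """Equivalent-air coordinate -> underwater coordinate (inverse of
    :func:`correct_single`); raises on TIR."""
    x_a = float(x_a)
    alpha = math.atan2(abs(x_a), port.d_mm)
    s = port.n_water * math.sin(alpha) / port.n_air
    if s >= 1.0:
        raise TotalInternalReflectionError(
            f"air-side coordinate {x_a:.6g} mm lies beyond the TIR bound"
        )
    x_r = port.d_mm * math.tan(math.asin(s))
    return math.copysign(x_r, x_a) if x_a != 0.0 else 0.0


# ---------------------------------------------------------------------------
# PARALLEL model (secondary refraction, window parallel to sensor)
# ---------------------------------------------------------------------------


def _xr_parallel(alpha: float, port: FlatPort) -> float:
    """x_r(α): underwater coordinate at water-side incidence α."""
    sw = port.n_water * math.sin(alpha)
    return port.t_mm * math.tan(math.asin(sw / port.n_glass)) + (
        port.d_mm - port.t_mm
    ) * math.tan(math.asin(sw / port.n_air))


def _xa_parallel(alpha: float, port: FlatPort) -> float:
    """x_a(α): equivalent-air coordinate at incidence α (air target)."""
    sa = port.n_air * math.sin(alpha)
    return port.t_mm * math.tan(math.asin(sa / port.n_glass)) + (
        port.d_mm - port.t_mm
    ) * math.tan(alpha)


def correct_parallel(x_r: float, port: FlatPort) -> float:
    """Underwater -> equivalent-air coordinate with secondary refraction.

    Solves x_r(α) = |x_r| for α on [0, α_TIR) by Brent's method and evaluates
    x_a(α); odd in x_r.  Raises :class:`TotalInternalReflectionError` when
    |x_r| exceeds the attainable underwater range.
    """
    x_r = float(x_r)
    if x_r == 0.0:
        return 0.0
    hi = port.critical_angle - _TIR_MARGIN
    target = abs(x_r)
    if _xr_parallel(hi, port) < target:
        raise TotalInternalReflectionError(
            f"underwater coordinate {x_r:.6g} mm exceeds the TIR-attainable range"
        )
    alpha = brentq(
        lambda a: _xr_parallel(a, port) - target,
        0.0,
        hi,
        xtol=_BRENTQ_XTOL,
        rtol=_BRENTQ_RTOL,
    )
    return math.copysign(_xa_parallel(alpha, port), x_r)


def observe_parallel(x_a: float, port: FlatPort) -> float:
    """Equivalent-air -> underwater coordinate (inverse of
    :func:`correct_parallel`).

    Solves x_a(α) = |x_a| for α, then evaluates x_r(α); the implied
    water-side angle must stay below the TIR bound.
    """
    x_a = float(x_a)
    if x_a == 0.0:
        return 0.0
    hi = math.pi / 2 - 1e-6
    target = abs(x_a)
    if _xa_parallel(hi, port) < target:
        raise RefractionDomainError(
            f"no incidence angle reproduces air coordinate {x_a:.6g} mm"
        )
    alpha = brentq(
        lambda a: _xa_parallel(a, port) - target,
        0.0,
        hi,
        xtol=_BRENTQ_XTOL,
        rtol=_BRENTQ_RTOL,
    )
    if alpha >= port.critical_angle - _TIR_MARGIN:
        raise TotalInternalReflectionError(
            f"air coordinate {x_a:.6g} mm implies incidence beyond the TIR bound"
        )
    return math.copysign(_xr_parallel(alpha, port), x_a)


# ---------------------------------------------------------------------------
# TILTED model (window tilted by beta; not odd for beta > 0)
# ---------------------------------------------------------------------------


def _check_tilt_geometry(port: FlatPort) -> float:
    beta = port.tilt_rad
    if port.d_mm <= port.t_mm / math.cos(beta):
        raise PortGeometryError(
            f"tilted port needs d > T/cos(beta): d={port.d_mm}, "
            f"T/cos(beta)={port.t_mm / math.cos(beta):.6g}"
        )
    return beta


def _xr_tilted(alpha: float, port: FlatPort) -> float:
    beta = port.tilt_rad
    sw = port.n_water * math.sin(alpha)
    return port.t_mm * (
        math.tan(math.asin(sw / port.n_glass)) - math.tan(beta)
    ) + (port.d_mm - port.t_mm / math.cos(beta)) * math.tan(
        math.asin(sw / port.n_air) - beta
    )


def _xa_tilted(alpha: float, port: FlatPort) -> float:
    beta = port.tilt_rad
    sa = port.n_air * math.sin(alpha)
    return port.t_mm * (
        math.tan(math.asin(sa / port.n_glass)) - math.tan(beta)
    ) + (port.d_mm - port.t_mm / math.cos(beta)) * math.tan(alpha - beta)


def _tilted_alpha_bounds_water(port: FlatPort) -> tuple[float, float]:
    """Signed α bracket on which x_r(α) is defined for the tilted model."""
    beta = port.tilt_rad
    hi = port.critical_angle - _TIR_MARGIN
    # need arcsin(n_w sin α / n_a) - beta > -pi/2
    s_lo = -math.sin(math.pi / 2 - beta - 1e-6) * port.n_air / port.n_water
    lo = max(-hi, math.asin(s_lo))
    return lo, hi


def correct_tilted(x_r: float, port: FlatPort) -> float:
    """Underwater -> equivalent-air coordinate for a tilted window.

    Same bracketed root-finding contract as the parallel pair, on the signed
    incidence angle (the tilted maps are not odd); reduces exactly to
    :func:`correct_parallel` at β = 0.
    """
    beta = _check_tilt_geometry(port)
    if beta == 0.0:
        return correct_parallel(x_r, port)
    x_r = float(x_r)
    lo, hi = _tilted_alpha_bounds_water(port)
    f_lo, f_hi = _xr_tilted(lo, port) - x_r, _xr_tilted(hi, port) - x_r
    if f_lo > 0.0 or f_hi < 0.0:
        raise TotalInternalReflectionError(
            f"underwater coordinate {x_r:.6g} mm outside the tilted-model range"
        )
    alpha = brentq(
        lambda a: _xr_tilted(a, port) - x_r, lo, hi,
        xtol=_BRENTQ_XTOL, rtol=_BRENTQ_RTOL,
    )
    return _xa_tilted(alpha, port)


def observe_tilted(x_a: float, port: FlatPort) -> float:
    """Equivalent-air -> underwater coordinate for a tilted window
    (inverse of :func:`correct_tilted`)."""
    beta = _check_tilt_geometry(port)
    if beta == 0.0:
        return observe_parallel(x_a, port)
    x_a = float(x_a)
    lo = beta - math.pi / 2 + 1e-6
    hi = math.pi / 2 - 1e-6
    f_lo, f_hi = _xa_tilted(lo, port) - x_a, _xa_tilted(hi, port) - x_a
    if f_lo > 0.0 or f_hi < 0.0:
        raise RefractionDomainError(
            f"no incidence angle reproduces air coordinate {x_a:.6g} mm"
        )
    alpha = brentq(
        lambda a: _xa_tilted(a, port) - x_a, lo, hi,
        xtol=_BRENTQ_XTOL, rtol=_BRENTQ_RTOL,
    )
    w_lo, w_hi = _tilted_alpha_bounds_water(port)
    if not (w_lo < alpha < w_hi):
        raise TotalInternalReflectionError(
            f"air coordinate {x_a:.6g} mm implies incidence beyond the TIR bound"
        )
    return _xr_tilted(alpha, port)


_CORRECT = {
    RefractionModel.SINGLE: correct_single,
    RefractionModel.PARALLEL: correct_parallel,
    RefractionModel.TILTED: correct_tilted,
}
_OBSERVE = {
    RefractionModel.SINGLE: observe_single,
    RefractionModel.PARALLEL: observe_parallel,
    RefractionModel.TILTED: observe_tilted,
}


def correct(x_r: float, port: FlatPort, model: RefractionModel) -> float:
    """Dispatch underwater -> equivalent-air conversion to *model*."""
    return _CORRECT[model](x_r, port)


def observe(x_a: float, port: FlatPort, model: RefractionModel) -> float:
    """Dispatch equivalent-air -> underwater conversion to *model*."""
    return _OBSERVE[model](x_a, port)


def magnification_ratio(
    alpha: float, port: FlatPort, model: RefractionModel
) -> float:
    """Underwater magnification x_r(α)/x_a(α) at water-side incidence α.

    For SINGLE this is ``tan(arcsin(n_r sin α / n_a)) / tan α``; for
    PARALLEL (and TILTED) it is the ratio of the model's two coordinate
    equations.  Strictly increasing in α — the refractive pincushion.
    Requires 0 < α < arcsin(n_air/n_water).
    """
    if not (0.0 < alpha < port.critical_angle):
        raise TotalInternalReflectionError(
            f"alpha must lie in (0, {port.critical_angle:.6f}) rad, got {alpha}"
        )
    if model is RefractionModel.SINGLE:
        return math.tan(
            math.asin(port.n_water * math.sin(alpha) / port.n_air)
        ) / math.tan(alpha)
    if model is RefractionModel.PARALLEL:
        return _xr_parallel(alpha, port) / _xa_parallel(alpha, port)
    _check_tilt_geometry(port)
    return _xr_tilted(alpha, port) / _xa_tilted(alpha, port)


# ---------------------------------------------------------------------------
# Keypoint-level application
# ---------------------------------------------------------------------------


def _apply_to_keypoints(
    kps: FishKeypoints,
    k: CameraIntrinsics,
    port: FlatPort,
    model: RefractionModel,
    fn,
) -> FishKeypoints:
    """Apply a 1-D coordinate map to every visible keypoint.

    SINGLE/PARALLEL are rotationally symmetric about the principal axis, so
    the map acts on the radial metric coordinate with azimuth preserved.
    TILTED is derived along one direction only: it acts on the x axis (the
    tilt plane), with the orthogonal y axis treated as a parallel system.
    Keypoints whose coordinate leaves the valid domain (TIR) are marked
    invisible; invisible keypoints pass through unchanged.
    """
    xy = kps.xy.copy()
    vis = kps.visibility.copy()
    for i in range(len(xy)):
        if vis[i] == 0:
            continue
        m = pixel_to_metric(xy[i], k)
        try:
            if model is RefractionModel.TILTED:
                pp = replace(port, tilt_rad=0.0)
                mx = fn(float(m[0]), port, RefractionModel.TILTED)
                my = fn(float(m[1]), pp, RefractionModel.PARALLEL)
                out = np.array([mx, my])
            else:
                r = float(np.hypot(m[0], m[1]))
                if r == 0.0:
                    out = m
                else:
                    out = m * (fn(r, port, model) / r)
        except (TotalInternalReflectionError, RefractionDomainError):
            vis[i] = 0
            continue
        xy[i] = metric_to_pixel(out, k)
    return FishKeypoints(xy=xy, visibility=vis, bbox=kps.bbox)


def correct_keypoints(
    kps: FishKeypoints,
    k: CameraIntrinsics,
    port: FlatPort,
    model: RefractionModel = RefractionModel.PARALLEL,
) -> FishKeypoints:
    """Refraction-correct detected keypoints: underwater pixels -> the pixels
    of the equivalent air image.

    Each visible keypoint is lifted to metric image coordinates
    (:func:`~fishstereo.camera.pixel_to_metric`), converted by the chosen
    flat-port model, and mapped back to pixels.  Keypoints beyond the TIR
    bound are returned unchanged but marked invisible.
    """
    return _apply_to_keypoints(kps, k, port, model, correct)


def correction_grid(
    k: CameraIntrinsics,
    port: FlatPort,
    model: RefractionModel,
    image_size: tuple[int, int],
    step: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense underwater -> air remap grid, for visualization only.

    Samples the pixel lattice every *step* px and returns
    ``(source, corrected)``, two ``(ny, nx, 2)`` arrays of underwater pixel
    positions and their refraction-corrected counterparts.  Samples beyond
    the TIR bound are NaN.  Keypoint correction does not use this grid.
    """
    w, h = image_size
    us = np.arange(0, w + 1, step, dtype=float)
    vs = np.arange(0, h + 1, step, dtype=float)
    uu, vv = np.meshgrid(us, vs)
    source = np.stack([uu, vv], axis=-1)
    corrected = np.full_like(source, np.nan)
    pp = replace(port, tilt_rad=0.0)
    for iy in range(source.shape[0]):
        for ix in range(source.shape[1]):
            m = pixel_to_metric(source[iy, ix], k)
            try:
                if model is RefractionModel.TILTED:
                    out = np.array(
                        [
                            correct(float(m[0]), port, RefractionModel.TILTED),
                            correct(float(m[1]), pp, RefractionModel.PARALLEL),
                        ]
                    )
                else:
                    r = float(np.hypot(m[0], m[1]))
                    out = m if r == 0.0 else m * (correct(r, port, model) / r)
            except (TotalInternalReflectionError, RefractionDomainError):
                continue
            corrected[iy, ix] = metric_to_pixel(out, k)
    return source, corrected


def observe_keypoints(
    kps: FishKeypoints,
    k: CameraIntrinsics,
    port: FlatPort,
    model: RefractionModel = RefractionModel.PARALLEL,
) -> FishKeypoints:
    """Inverse of :func:`correct_keypoints`: turn air-equivalent keypoints
    into the pixels an underwater flat-port camera would record (used by the
    scene simulator)."""
    return _apply_to_keypoints(kps, k, port, model, observe)
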