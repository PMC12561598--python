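"""Synthetic pendulous-breast contour stacks with injectable artifacts.

The generator emulates the geometry a cylindrical-scanner contour
reconstruction would produce for a breast hanging into the coupling liquid:
per-height closed contours, widest near the chest wall and closing toward
the nipple, with controllable total volume in the 300–1800 mL range.

Two artifact families reproduce the phenomenology the partial-scan filters
target:

* ``proximity`` — the near-chest skin is pushed out to a prescribed
  clearance from the probe array (large-breast deformation under buoyancy);
* ``chest_widening`` — the top contours are inflated by a factor, abruptly
  or over a ramp, mimicking non-mammary tissue entering the scanner
  (small-breast insertion artifact).

Everything is deterministic for a fixed seed, and every phantom carries its
ground truth so filter recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ContourSlice, ContourStack, ScannerGeometry

__all__ = [
    "ChestWidening",
    "Proximity",
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
]

_N_VERTICES = 180  # 2 degree angular sampling
_R_STOP = 2.0  # mm; contours narrower than this are not emitted


@dataclass(frozen=True)
class ChestWidening:
    """Inflate the top ``extent`` mm of contours by ``widen_factor``.

    ``ramp_mm = 0`` gives an abrupt step (exercises the steep-decrease
    indicator); a positive ramp blends back to the base profile over that
    many mm (exercises the breakpoint indicator).
    """

    extent: float
    widen_factor: float
    ramp_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.widen_factor <= 1:
            raise ValueError("widen_factor must exceed 1")
        if self.extent <= 0 or self.ramp_mm < 0:
            raise ValueError("extent must be positive, ramp_mm non-negative")


@dataclass(frozen=True)
class Proximity:
    """Push the top ``extent`` mm of contours out to ``clearance`` mm from the array."""

    extent: float
    clearance: float

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.clearance < 0:
            raise ValueError("extent must be positive, clearance non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic breast.

    target_volume : mL — calibrated to within 1% on the generated stack.
    length : mm — nipple depth below the shallowest scan position; when
        omitted it defaults to ``1.6 · V^(1/3)`` (V in mm³), which keeps
        artifact-free skin at least ~15 mm clear of the array across the
        300–1800 mL range.
    profile : ``"teardrop"`` (default) or ``"hemicone"``.
    artifact : optional ChestWidening or Proximity.
    center_offset : (x, y) mm displacement of the breast axis.
    radial_noise_sd : mm — independent Gaussian radial noise per vertex.
    seed : RNG seed; fixed seed gives an identical stack.
    """

    target_volume: float
    length: float | None = None
    profile: str = "teardrop"
    artifact: ChestWidening | Proximity | None = None
    center_offset: tuple[float, float] = (0.0, 0.0)
    radial_noise_sd: float = 0.0
    seed: int = 0
    taper_power: float = 0.7

    def __post_init__(self) -> None:
        if self.target_volume <= 0:
            raise ValueError("target_volume must be positive")
        if self.profile not in ("teardrop", "hemicone"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.artifact is not None and self.length is not None:
            if self.artifact.extent >= self.length:
                raise ValueError("artifact extent must be smaller than breast length")

    @property
    def effective_length(self) -> float:
        if self.length is not None:
            return self.length
        return 1.6 * (self.target_volume * 1000.0) ** (1.0 / 3.0)


def _base_radius(zeta: np.ndarray, length: float, profile: str, p: float) -> np.ndarray:
    """Unit-amplitude radius profile; widest at the chest, closing at the nipple."""
    u = np.clip(zeta / length, 0.0, 1.0)
    if profile == "teardrop":
        return np.cos(0.5 * math.pi * u) ** p
    # hemisphere cap blended into a cone tip
    cone = math.sqrt(0.75) * (1.0 - u) / 0.5
    return np.where(u <= 0.5, np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0)), cone)


def _polygon_area_factor(n: int) -> float:
    """Area of a regular n-gon of unit circumradius, relative to the unit circle."""
    return 0.5 * n * math.sin(2 * math.pi / n) / math.pi


def _calibrated_r_max(spec: PhantomSpec, geometry: ScannerGeometry) -> float:
    """Chest-level radius that meets the target volume for this recipe."""
    L = spec.effective_length
    n_slices = int(math.floor(L / geometry.height_step)) + 1
    zeta = np.arange(n_slices) * geometry.height_step
    r_unit = _base_radius(zeta, L, spec.profile, spec.taper_power)
    unit_vol = math.pi * _polygon_area_factor(_N_VERTICES) * np.trapezoid(r_unit**2, zeta)
    return math.sqrt(spec.target_volume * 1000.0 / unit_vol)


def generate_phantom(
    spec: PhantomSpec, geometry: ScannerGeometry = ScannerGeometry()
) -> ContourStack:
    """Build one contour stack from a phantom recipe.

    The base radius profile is scaled so the stack's own trapezoidal volume
    matches ``target_volume`` before artifact injection; artifacts then
    modify the near-chest contours exactly as specified.

    Raises
    ------
    ValueError
        If the requested shape or artifact would place contours on or
        outside the probe-array circle.
    """
    rng = np.random.default_rng(spec.seed)
    g = geometry
    L = spec.effective_length
    step = g.height_step

    n_slices = int(math.floor(L / step)) + 1
    zeta = np.arange(n_slices) * step
    r_unit = _base_radius(zeta, L, spec.profile, spec.taper_power)

    # calibrate against the same trapezoid + polygon-area rule the volume
    # integrator uses, so the target is met by construction
    r_max = _calibrated_r_max(spec, geometry)

    radii = r_max * r_unit
    keep = radii >= _R_STOP
    zeta, radii = zeta[keep], radii[keep]

    if spec.artifact is not None and isinstance(spec.artifact, ChestWidening):
        a = spec.artifact
        factor = np.ones_like(radii)
        factor[zeta <= a.extent] = a.widen_factor
        if a.ramp_mm > 0:
            # linear blend keeps the per-step area drop below the abrupt case
            on_ramp = (zeta > a.extent) & (zeta < a.extent + a.ramp_mm)
            t = (zeta[on_ramp] - a.extent) / a.ramp_mm
            factor[on_ramp] = a.widen_factor + (1.0 - a.widen_factor) * t
        radii = radii * factor

    cx, cy = spec.center_offset
    offset = math.hypot(cx, cy)
    theta = np.linspace(0.0, 2 * math.pi, _N_VERTICES, endpoint=False)

    slices = []
    for z_rel, r in zip(zeta, radii):
        noise = rng.normal(0.0, spec.radial_noise_sd, _N_VERTICES) if spec.radial_noise_sd > 0 else 0.0
        rv = np.maximum(r + noise, 0.5)
        x = cx + rv * np.cos(theta)
        y = cy + rv * np.sin(theta)
        if isinstance(spec.artifact, Proximity) and z_rel <= spec.artifact.extent:
            # rescale about the scanner axis so the closest vertex sits at
            # exactly `clearance` from the array
            rho = np.hypot(x, y)
            scale = (g.array_radius - spec.artifact.clearance) / rho.max()
            x, y = x * scale, y * scale
        if np.hypot(x, y).max() >= g.array_radius:
            raise ValueError(
                f"phantom contour at depth {g.z_min + z_rel:.1f} mm reaches the array circle; "
                "reduce volume, widening or offset"
            )
        h = g.h_bed - (g.z_min + z_rel)
        slices.append(ContourSlice(h=h, points=np.column_stack([x, y])))
    return ContourStack(geometry=g, slices=tuple(slices))


_SIZE_RANGES = {"small": (300.0, 600.0), "medium": (600.0, 1200.0), "large": (1200.0, 1800.0)}

_DEFAULT_ARTIFACTS = {
    "none": None,
    "chest_widening": ChestWidening(extent=14.0, widen_factor=1.4, ramp_mm=0.0),
    "proximity": Proximity(extent=20.0, clearance=3.0),
}


def generate_cohort(
    n: int,
    size_mix: dict[str, float],
    artifact_mix: dict[str, float],
    seed: int = 0,
    geometry: ScannerGeometry = ScannerGeometry(),
    artifact_params: dict[str, ChestWidening | Proximity | None] | None = None,
    radial_noise_sd: float = 0.3,
) -> tuple[list[ContourStack], pd.DataFrame]:
    """Seeded cohort of phantoms plus its ground-truth table.

    ``size_mix`` and ``artifact_mix`` are proportions over the size classes
    (small/medium/large) and artifact kinds (none/chest_widening/proximity);
    each must sum to 1.  Returns the stacks and a DataFrame with one row per
    breast: id, size class, target volume, artifact kind and true extent.
    """
    for name, mix in (("size_mix", size_mix), ("artifact_mix", artifact_mix)):
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} proportions must sum to 1")
    params = dict(_DEFAULT_ARTIFACTS)
    if artifact_params:
        params.update(artifact_params)
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)

    sizes = rng.choice(list(size_mix), size=n, p=list(size_mix.values()))
    kinds = rng.choice(list(artifact_mix), size=n, p=list(artifact_mix.values()))

    stacks, rows = [], []
    for i in range(n):
        lo, hi = _SIZE_RANGES[sizes[i]]
        vol = float(rng.uniform(lo, hi))
        art = params[kinds[i]]
        if isinstance(art, ChestWidening):
            # cap the widening so the inflated contour stays clear of the array
            r0 = _calibrated_r_max(PhantomSpec(target_volume=vol), geometry)
            w_max = (geometry.array_radius - 4.0) / r0
            if art.widen_factor > w_max:
                art = ChestWidening(
                    extent=art.extent,
                    widen_factor=max(1.1, w_max),
                    ramp_mm=art.ramp_mm,
                )
        spec = PhantomSpec(
            target_volume=vol,
            artifact=art,
            radial_noise_sd=radial_noise_sd,
            seed=int(child_seeds[i]),
        )
        stacks.append(generate_phantom(spec, geometry))
        rows.append(
            {
                "breast_id": f"P{i:04d}",
                "size_class": sizes[i],
                "target_volume_ml": vol,
                "artifact": kinds[i],
                "true_extent_mm": getattr(art, "extent", 0.0) if art else 0.0,
                "seed": int(child_seeds[i]),
            }
        )
    return stacks, pd.DataFrame(rows)
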