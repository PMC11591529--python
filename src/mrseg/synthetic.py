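"""Synthetic color-Doppler echocardiogram generator.

The clinical frames this package targets cannot be redistributed, so the
generator renders apical-four-chamber-like stand-ins with exact ground
truth: a dark speckled ultrasound sector, an elliptical left-atrium cavity,
and an irregular star-convex regurgitant-jet blob nested inside it, colored
with a red/blue pseudo-velocity mosaic. The controllable quantity is the
regurgitant fraction RF = 100 * jet pixels / atrial pixels (the atrial area
counts jet pixels, matching the severity module's denominator).

The jet boundary is a radial profile r(theta) = s * (1 + irregularity *
f(theta)) around a seed point near the mitral-valve end of the atrium,
where f is a random low-order harmonic series. Scaling ``s`` grows the blob
monotonically, so the exact pixel-count threshold for a target RF is found
by rank-ordering pixels by their normalized radial distance — achieved RF
differs from the target by at most one pixel's worth of area.

Everything is driven by a single seeded generator: identical parameters and
seed give bit-identical images and masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .doppler_io import save_image, save_mask
from .severity import grade as grade_rf

__all__ = ["SyntheticParams", "SyntheticCase", "generate_case", "generate_dataset", "RF_RANGES"]

# Per-grade target-RF sampling ranges; offset from the 30/50 thresholds so a
# generated case can never sit on a grading boundary.
RF_RANGES = {"mild": (5.0, 29.0), "moderate": (31.0, 49.0), "severe": (51.0, 90.0)}


@dataclass(frozen=True)
class SyntheticParams:
    target_rf: float
    seed: int
    canvas: tuple[int, int] = (600, 800)  # (height, width)
    sector_apex: tuple[float, float] | None = None  # (row, col); default from canvas
    sector_angle: float = 70.0  # full opening angle, degrees
    la_center: tuple[float, float] | None = None
    la_axes: tuple[float, float] | None = None  # (row semi-axis, col semi-axis)
    jet_irregularity: float = 0.35  # 0..1 boundary roughness
    speckle_sigma: float = 0.15
    n_harmonics: int = 5

    def resolved(self) -> "SyntheticParams":
        h, w = self.canvas
        out = self
        if out.sector_apex is None:
            out = replace(out, sector_apex=(0.04 * h, 0.5 * w))
        if out.la_center is None:
            out = replace(out, la_center=(0.62 * h, 0.5 * w))
        if out.la_axes is None:
            out = replace(out, la_axes=(0.20 * h, 0.16 * w))
        return out

    def validate(self) -> None:
        if self.target_rf <= 0 or self.target_rf > 120:
            raise ValueError("target_rf must be in (0, 120]")
        if not (0 <= self.jet_irregularity <= 1):
            raise ValueError("jet_irregularity must be in [0, 1]")
        if min(self.canvas) < 32:
            raise ValueError("canvas must be at least 32 x 32")


@dataclass(frozen=True)
class SyntheticCase:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W labels {0,1,2}
    true_rf: float
    grade: str
    params: SyntheticParams


def _sector_mask(h: int, w: int, apex, angle_deg: float) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - apex[0] + 0.5
    dc = cols - apex[1] + 0.5
    radius = np.hypot(dr, dc)
    theta = np.abs(np.arctan2(dc, dr))  # angle from the downward vertical
    return (theta <= np.deg2rad(angle_deg / 2)) & (radius <= 0.93 * h) & (dr > 0)


def _ellipse_mask(h: int, w: int, center, axes, shrink: float = 1.0) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    return ((rows - center[0]) / (axes[0] * shrink)) ** 2 + (
        (cols - center[1]) / (axes[1] * shrink)
    ) ** 2 <= 1.0


def _jet_mask(params: SyntheticParams, la: np.ndarray, rng: np.random.Generator):
    """Jet support with exactly the pixel count matching target RF.

    Returns None when the target is geometrically unattainable with the
    drawn boundary profile (caller retries with fresh harmonics).
    """
    h, w = params.canvas
    n_la = int(la.sum())
    k = max(1, int(round(params.target_rf / 100.0 * n_la)))
    inner = la & _ellipse_mask(h, w, params.la_center, params.la_axes, shrink=0.985)
    if k > int(inner.sum()):
        return None
    jc = (params.la_center[0] - 0.45 * params.la_axes[0], params.la_center[1])
    rows, cols = np.nonzero(inner)
    dr = rows - jc[0]
    dc = cols - jc[1]
    theta = np.arctan2(dr, dc)
    coeffs = rng.normal(size=(2, params.n_harmonics)) / np.arange(1, params.n_harmonics + 1)
    f = np.zeros_like(theta)
    for m in range(params.n_harmonics):
        f += coeffs[0, m] * np.cos((m + 1) * theta) + coeffs[1, m] * np.sin((m + 1) * theta)
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    profile = np.clip(1.0 + params.jet_irregularity * f, 0.15, None)
    rel = np.hypot(dr, dc) / profile
    order = np.argsort(rel, kind="stable")[:k]
    jet = np.zeros((h, w), dtype=bool)
    jet[rows[order], cols[order]] = True
    return jet


def _render_image(params: SyntheticParams, sector, la, jet, rng) -> np.ndarray:
    h, w = params.canvas
    speckle = rng.gamma(2.0, params.speckle_sigma, size=(h, w))
    speckle = ndimage.gaussian_filter(speckle, 1.0)
    gray = np.where(sector, 0.16 + speckle, 0.02)
    gray = np.where(la, 0.05 + 0.25 * speckle, gray)
    img = np.repeat(np.clip(gray, 0, 1)[:, :, None], 3, axis=2)

    # pseudo-velocity field: smooth low-frequency noise in [-1, 1]
    coarse = rng.normal(size=(8, 8))
    field = ndimage.zoom(coarse, (h / 8, w / 8), order=3)[:h, :w]
    field /= max(np.abs(field).max(), 1e-9)
    v = field[jet]
    jet_rgb = np.empty((v.size, 3))
    pos = v >= 0
    jet_rgb[pos] = np.stack(
        [0.75 + 0.25 * v[pos], 0.15 + 0.35 * v[pos], 0.10 * np.ones(pos.sum())], axis=1
    )
    jet_rgb[~pos] = np.stack(
        [0.10 * np.ones((~pos).sum()), 0.20 - 0.15 * v[~pos], 0.70 - 0.30 * v[~pos]], axis=1
    )
    # mosaic flecks: scattered yellow/green aliasing-like speckles
    fleck = rng.random(v.size) < 0.15
    fleck_color = np.where(
        rng.random((v.size, 1)) < 0.5, [[0.90, 0.85, 0.20]], [[0.25, 0.80, 0.30]]
    )
    jet_rgb[fleck] = fleck_color[fleck]
    img[jet] = jet_rgb
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_case(params: SyntheticParams, max_retries: int = 3) -> SyntheticCase:
    """Render one image/mask pair hitting ``params.target_rf`` within the
    one-pixel quantization of the atrial area (well inside +-2 RF points)."""
    params = params.resolved()
    params.validate()
    h, w = params.canvas
    rng = np.random.default_rng(params.seed)
    sector = _sector_mask(h, w, params.sector_apex, params.sector_angle)
    la = _ellipse_mask(h, w, params.la_center, params.la_axes)
    if not la.any():
        raise ValueError("left-atrium ellipse rasterizes to zero pixels")
    if not (la <= sector).all():
        raise ValueError("left-atrium ellipse must lie inside the sector")
    jet = None
    for _ in range(max_retries):
        jet = _jet_mask(params, la, rng)
        if jet is not None:
            break
    if jet is None:
        raise ValueError(
            f"target RF {params.target_rf} is unattainable inside the atrium"
        )
    mask = np.zeros((h, w), dtype=np.int64)
    mask[la] = 2
    mask[jet] = 1  # jet overrides atrium
    true_rf = 100.0 * int(jet.sum()) / int(la.sum())
    if abs(true_rf - params.target_rf) > 2.0:
        raise ValueError(
            f"achieved RF {true_rf:.2f} misses target {params.target_rf:.2f} by > 2"
        )
    image = _render_image(params, sector, la, jet, rng)
    return SyntheticCase(image, mask, true_rf, grade_rf(true_rf), params)


def generate_dataset(
    n_per_grade: dict[str, int],
    out_dir,
    seed: int,
    canvas: tuple[int, int] = (600, 800),
    **param_overrides,
) -> dict:
    """Write ``n`` image/mask pairs per grade with target RF drawn uniformly
    from the per-grade ranges; returns (and writes) the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cases = []
    for grade_name in ("mild", "moderate", "severe"):
        n = n_per_grade.get(grade_name, 0)
        if n < 1:
            raise ValueError(f"need at least 1 case for grade {grade_name!r}")
        lo, hi = RF_RANGES[grade_name]
        for i in range(n):
            target = float(rng.uniform(lo, hi))
            case_seed = int(rng.integers(2**31))
            params = SyntheticParams(
                target_rf=target, seed=case_seed, canvas=canvas, **param_overrides
            )
            case = generate_case(params)
            cid = f"{grade_name}_{i:04d}"
            image_name = f"{cid}.png"
            mask_name = f"{cid}_mask.png"
            save_image(out_dir / image_name, case.image)
            save_mask(out_dir / mask_name, case.mask)
            cases.append(
                {
                    "id": cid,
                    "grade": case.grade,
                    "target_rf": round(target, 4),
                    "true_rf": round(case.true_rf, 4),
                    "seed": case_seed,
                    "image": image_name,
                    "mask": mask_name,
                }
            )
    manifest = {"seed": seed, "canvas": list(canvas), "cases": cases}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
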