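"""Synthetic dual bright-field ISH image generator with exact ground truth.

Renders region-of-interest tiles that emulate the assay's appearance: a
near-white tissue background, hematoxylin-blue elliptical nuclei, black
silver HER2 dots and red (Fast Red) CEP17 dots, all composed by Beer-Lambert
optical-density mixing.  Every image ships with a :class:`GroundTruthSidecar`
listing true nucleus geometry and per-nucleus signal counts, so segmentation
and counting can be validated without any external data.

:func:`apply_protocol` degrades a base render the way a scanning protocol
would: resampling to the protocol's pixel size, Gaussian optical blur, stain
fading (OD scaling), and spatially varying defocus driven by a smooth random
focal-depth field.  Extended-focus protocols composite the per-pixel least
defocused of several focal layers, which caps residual defocus at half the
layer step and thereby stabilises image quality.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._rng import child_rng
from .profiles import CaseProfile, ProtocolProfile, HETEROGENEITY_FACTOR
from .stains import HEMATOXYLIN_OD, FAST_RED_OD, _unit

SIDECAR_SCHEMA = "her2ish/sidecar-1"

HER2 = "HER2"
CEP17 = "CEP17"

#: Background (glass + faint tissue) intensity per channel.
BACKGROUND_INTENSITY = 245.0
#: Physical signal diameter prior: default and range, in micrometres.
SPOT_DIAMETER_UM = 0.9
SPOT_DIAMETER_RANGE_UM = (0.6, 1.2)
#: Minimum distance between two signals of one nucleus (rendered dots that
#: are closer than this fuse optically and are uncountable even by eye).
SPOT_MIN_SEPARATION_UM = 0.7
#: Peak OD amplitude (concentration) of rendered deposits.
SILVER_PEAK_OD = 1.3
FAST_RED_PEAK_OD = 1.1
#: Nucleus hematoxylin amplitude distribution (OD concentration units).
NUCLEUS_OD_MEAN = 0.72
NUCLEUS_OD_SD = 0.07
NUCLEUS_OD_CLIP = (0.50, 0.85)
#: Maximum pairwise overlap (lens area / smaller nucleus area).
MAX_NUCLEUS_OVERLAP = 0.15
#: Fractional radius within which signals are placed (keeps dots inside the
#: segmented nuclear mask even after mild blur).
SPOT_PLACEMENT_FRACTION = 0.75
#: Sensor noise (grey levels, 8-bit) added at render time.
SENSOR_NOISE_SD = 1.5

#: Peak focal-surface excursion, in um, at focus_instability = 1.
FOCUS_DEPTH_UM = 4.5
#: Gaussian blur sigma per um of defocus.
DEFOCUS_BLUR_COEFF = 1.0
#: Resolutions coarser than this cannot resolve individual signals.
MAX_USABLE_RESOLUTION_UM = 2.0

_V_H = _unit(HEMATOXYLIN_OD)
_V_R = _unit(FAST_RED_OD)
_V_S = np.ones(3) / math.sqrt(3.0)


@dataclass(frozen=True)
class TrueNucleus:
    label: int
    x: float
    y: float
    radius_px: float
    axes_px: tuple[float, float]
    theta: float
    her2_count: int
    cep17_count: int


@dataclass(frozen=True)
class TrueSpot:
    x: float
    y: float
    channel: str
    nucleus_label: int


@dataclass
class GroundTruthSidecar:
    """Exact per-image truth: nuclei, spots, and provenance."""

    nuclei: list[TrueNucleus]
    spots: list[TrueSpot]
    seed: int
    resolution_um_per_px: float
    shape: tuple[int, int]
    empty_warning: bool = False
    schema: str = SIDECAR_SCHEMA

    def counts(self) -> list[tuple[int, int]]:
        return [(n.her2_count, n.cep17_count) for n in self.nuclei]

    def validate(self) -> None:
        """Check internal consistency: every spot's parent exists and the
        per-nucleus tallies equal the stored counts."""
        labels = {n.label for n in self.nuclei}
        tallies: dict[tuple[int, str], int] = {}
        for s in self.spots:
            if s.nucleus_label not in labels:
                raise ValueError(f"spot parent {s.nucleus_label} not among nuclei")
            tallies[(s.nucleus_label, s.channel)] = tallies.get((s.nucleus_label, s.channel), 0) + 1
        for n in self.nuclei:
            if tallies.get((n.label, HER2), 0) != n.her2_count:
                raise ValueError(f"nucleus {n.label}: HER2 tally mismatch")
            if tallies.get((n.label, CEP17), 0) != n.cep17_count:
                raise ValueError(f"nucleus {n.label}: CEP17 tally mismatch")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": self.schema,
            "seed": self.seed,
            "resolution_um_per_px": self.resolution_um_per_px,
            "shape": list(self.shape),
            "empty_warning": self.empty_warning,
            "nuclei": [asdict(n) for n in self.nuclei],
            "spots": [asdict(s) for s in self.spots],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthSidecar":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        schema = data.get("schema", "")
        if not schema.startswith("her2ish/sidecar-"):
            raise ValueError(f"not a sidecar document: {schema!r}")
        if int(schema.rsplit("-", 1)[1]) > 1:
            raise ValueError(f"sidecar schema {schema!r} is newer than this reader")
        return cls(
            nuclei=[
                TrueNucleus(**{**n, "axes_px": tuple(n["axes_px"])}) for n in data["nuclei"]
            ],
            spots=[TrueSpot(**s) for s in data["spots"]],
            seed=data["seed"],
            resolution_um_per_px=data["resolution_um_per_px"],
            shape=tuple(data["shape"]),
            empty_warning=data.get("empty_warning", False),
            schema=schema,
        )


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def sample_counts(profile: CaseProfile, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-nucleus (HER2, CEP17) counts for ``n`` nuclei.

    Counts follow a negative binomial with the profile's means and
    overdispersion ``a`` (Var = mu + a mu^2); ``a = 0`` degenerates to
    Poisson.  With ``amplified_fraction`` > 0, that fraction of nuclei uses a
    HER2 mean ``HETEROGENEITY_FACTOR`` times the rest while preserving the
    overall mean.
    """
    af = profile.amplified_fraction
    mean_h = profile.mean_her2_per_nucleus
    if af > 0:
        low = mean_h / (1.0 - af + af * HETEROGENEITY_FACTOR)
        means_h = np.where(rng.random(n) < af, low * HETEROGENEITY_FACTOR, low)
    else:
        means_h = np.full(n, mean_h)

    def draw(mu: np.ndarray | float) -> np.ndarray:
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
        if profile.dispersion <= 1e-12:
            return rng.poisson(mu)
        r = 1.0 / profile.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    return draw(means_h), draw(profile.mean_cep17_per_nucleus)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _lens_overlap_fraction(d: float, r1: float, r2: float) -> float:
    """Circle-circle intersection area as a fraction of the smaller circle."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    d2, r12, r22 = d * d, r1 * r1, r2 * r2
    a1 = r12 * math.acos((d2 + r12 - r22) / (2 * d * r1))
    a2 = r22 * math.acos((d2 + r22 - r12) / (2 * d * r2))
    tri = 0.5 * math.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)))
    lens = a1 + a2 - tri
    return lens / (math.pi * min(r12, r22))


def _place_nuclei(rng, n_target, width, height, radii_px) -> list[tuple[float, float, float]]:
    """Rejection-sample non-to-mildly-overlapping circles fully inside the
    field.  Returns (x, y, r) triples; may place fewer than requested."""
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 60 * max(n_target, 1)
    i = 0
    while i < n_target and attempts < max_attempts:
        attempts += 1
        r = radii_px[i]
        margin = r + 3.0
        if 2 * margin >= min(width, height):
            i += 1
            continue
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        ok = True
        for (px, py, pr) in placed:
            d = math.hypot(x - px, y - py)
            if d < pr + r and _lens_overlap_fraction(d, pr, r) > MAX_NUCLEUS_OVERLAP:
                ok = False
                break
        if ok:
            placed.append((x, y, r))
            i += 1
    return placed


def _sample_point_in_ellipse(rng, cx, cy, a, b, theta, frac) -> tuple[float, float]:
    u = rng.uniform(0, 2 * math.pi)
    rad = math.sqrt(rng.uniform())
    ex = a * frac * rad * math.cos(u)
    ey = b * frac * rad * math.sin(u)
    ct, st = math.cos(theta), math.sin(theta)
    return cx + ex * ct - ey * st, cy + ex * st + ey * ct


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_ellipse(conc: np.ndarray, cx, cy, a, b, theta, amp, edge_w=0.05) -> None:
    """Accumulate a soft-edged ellipse into a concentration map."""
    h, w = conc.shape
    ext = max(a, b) * (1.0 + 6 * edge_w)
    x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 1)
    y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    ex = (dx * ct + dy * st) / a
    ey = (-dx * st + dy * ct) / b
    rho = np.sqrt(ex * ex + ey * ey)
    conc[y0:y1, x0:x1] += amp / (1.0 + np.exp(np.clip((rho - 1.0) / edge_w, -50, 50)))


def _add_gaussian(conc: np.ndarray, cx, cy, sigma, amp) -> None:
    h, w = conc.shape
    ext = 4 * sigma
    x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 1)
    y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    conc[y0:y1, x0:x1] += amp * np.exp(-d2 / (2 * sigma * sigma))


def render_roi(
    profile: CaseProfile,
    width_px: int,
    height_px: int,
    resolution_um_per_px: float,
    seed: int,
) -> tuple[np.ndarray, GroundTruthSidecar]:
    """Render one ROI tile and its exact ground truth.

    Returns an (H, W, 3) uint8 RGB image and the sidecar.  A density that
    yields zero nuclei in the field produces an empty sidecar with
    ``empty_warning`` set (and a Python warning), not an exception.
    """
    if width_px < 128 or height_px < 128:
        raise ValueError("ROI dimensions must be at least 128 px")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    res = resolution_um_per_px
    rng = child_rng(seed, "render")

    area_mm2 = (width_px * res) * (height_px * res) / 1e6
    n_target = int(rng.poisson(profile.nucleus_density_per_mm2 * area_mm2))

    radii_px = np.clip(
        rng.normal(profile.nucleus_radius_um, profile.nucleus_radius_sd_um, size=max(n_target, 1)),
        0.4 * profile.nucleus_radius_um,
        1.8 * profile.nucleus_radius_um,
    ) / res
    placed = _place_nuclei(rng, n_target, width_px, height_px, radii_px)

    hema = np.zeros((height_px, width_px))
    silver = np.zeros_like(hema)
    red = np.zeros_like(hema)

    # faint tissue haze so the background is near-white, not pure glass
    haze = ndimage.gaussian_filter(rng.standard_normal(hema.shape), 12.0)
    haze_sd = haze.std()
    if haze_sd > 0:
        haze /= haze_sd
    hema += 0.015 + 0.008 * np.abs(haze)

    nuclei: list[TrueNucleus] = []
    spots: list[TrueSpot] = []
    if placed:
        counts_h, counts_c = sample_counts(profile, len(placed), rng)
    for idx, (cx, cy, r) in enumerate(placed):
        label = idx + 1
        elong = rng.uniform(1.0, 1.25)
        a, b = r * elong, r / elong
        theta = rng.uniform(0, math.pi)
        amp = float(np.clip(rng.normal(NUCLEUS_OD_MEAN, NUCLEUS_OD_SD), *NUCLEUS_OD_CLIP))
        _add_ellipse(hema, cx, cy, a, b, theta, amp)

        ch, cc = int(counts_h[idx]), int(counts_c[idx])
        min_sep_px = SPOT_MIN_SEPARATION_UM / res
        pts: list[tuple[float, float]] = []

        def _place_spot() -> tuple[float, float]:
            for _ in range(60):
                px, py = _sample_point_in_ellipse(rng, cx, cy, a, b, theta, SPOT_PLACEMENT_FRACTION)
                if all(math.hypot(px - qx, py - qy) >= min_sep_px for qx, qy in pts):
                    pts.append((px, py))
                    return px, py
            px, py = _sample_point_in_ellipse(rng, cx, cy, a, b, theta, SPOT_PLACEMENT_FRACTION)
            pts.append((px, py))
            return px, py

        for _ in range(ch):
            px, py = _place_spot()
            d_um = rng.uniform(*SPOT_DIAMETER_RANGE_UM) * (SPOT_DIAMETER_UM / 0.9)
            _add_gaussian(silver, px, py, (d_um / 3.0) / res, SILVER_PEAK_OD * rng.uniform(0.85, 1.1))
            spots.append(TrueSpot(px, py, HER2, label))
        for _ in range(cc):
            px, py = _place_spot()
            d_um = rng.uniform(*SPOT_DIAMETER_RANGE_UM) * (SPOT_DIAMETER_UM / 0.9)
            _add_gaussian(red, px, py, (d_um / 3.0) / res, FAST_RED_PEAK_OD * rng.uniform(0.85, 1.1))
            spots.append(TrueSpot(px, py, CEP17, label))

        nuclei.append(TrueNucleus(label, cx, cy, math.sqrt(a * b), (a, b), theta, ch, cc))

    od = (
        hema[..., None] * _V_H[None, None, :]
        + red[..., None] * _V_R[None, None, :]
        + silver[..., None] * _V_S[None, None, :]
    )
    rgb = BACKGROUND_INTENSITY * np.power(10.0, -od)
    rgb = rgb + rng.normal(0.0, SENSOR_NOISE_SD, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    empty = len(nuclei) == 0
    if empty:
        warnings.warn("requested density yielded zero nuclei in the field", stacklevel=2)
    sidecar = GroundTruthSidecar(nuclei, spots, seed, res, (height_px, width_px), empty_warning=empty)
    return rgb, sidecar


# ---------------------------------------------------------------------------
# Protocol degradation
# ---------------------------------------------------------------------------

def _focal_depth_field(shape: tuple[int, int], rng: np.random.Generator, instability: float) -> np.ndarray:
    """Patchy focal-surface depth (um) over the field.

    A smooth unit-variance random field is soft-thresholded so that most of
    the field sits exactly in focus and isolated patches drift out, which is
    how single-layer scans actually fail ("out-of-focus areas", not a global
    softening).  ``focus_instability`` raises both the patch coverage (lower
    threshold) and the depth excursion inside patches.
    """
    h, w = shape
    ch, cw = max(h // 24, 4), max(w // 24, 4)
    coarse = ndimage.gaussian_filter(rng.standard_normal((ch, cw)), 1.5)
    sd = coarse.std()
    if sd > 0:
        coarse /= sd
    f = ndimage.zoom(coarse, (h / ch, w / cw), order=1)[:h, :w]
    f0 = max(0.8, 1.8 - instability)
    excess = np.maximum(np.abs(f) - f0, 0.0) * np.sign(f)
    return FOCUS_DEPTH_UM * instability * excess


def _variable_blur(img: np.ndarray, sigma_map_px: np.ndarray) -> np.ndarray:
    """Approximate spatially varying Gaussian blur by interpolating between
    copies blurred on a fixed geometric sigma ladder.

    The ladder is absolute (0, 0.35, 0.7, 1.4, ... px), not scaled to the
    map's range, so two degradations whose sigma maps agree pointwise produce
    identical output regardless of their respective maxima -- paired
    protocol comparisons then differ only where their defocus truly differs.
    """
    hi = float(sigma_map_px.max())
    if hi < 0.05:
        return img
    ladder = [0.0]
    s = 0.35
    while True:
        ladder.append(s)
        if s >= hi:
            break
        s *= 2.0
    rungs = np.asarray(ladder)
    stack = [img if r < 0.05 else ndimage.gaussian_filter(img, (r, r, 0)) for r in rungs]
    sig = np.clip(sigma_map_px, 0.0, rungs[-1])
    j = np.clip(np.searchsorted(rungs, sig), 1, len(rungs) - 1)
    lo_r, hi_r = rungs[j - 1], rungs[j]
    t = ((sig - lo_r) / (hi_r - lo_r))[..., None]
    out = np.zeros_like(img)
    for k in range(len(rungs)):
        w_lo = np.where(j - 1 == k, 1.0 - t[..., 0], 0.0)
        w_hi = np.where(j == k, t[..., 0], 0.0)
        w = (w_lo + w_hi)[..., None]
        if w.any():
            out += w * stack[k]
    return out


def apply_protocol(
    image: np.ndarray,
    base_resolution_um_per_px: float,
    protocol: ProtocolProfile,
    seed: int,
) -> np.ndarray:
    """Degrade a base render according to a scanning protocol.

    Resamples to the protocol resolution, fades stain OD by ``fade_factor``,
    applies the protocol's optical blur, and adds spatially varying defocus
    from a smooth focal-depth field whose amplitude scales with
    ``focus_instability``.  With ``n_focus_layers`` > 1 the per-pixel least
    defocused of the layers is composited (extended focus), capping residual
    defocus at half the layer step.
    """
    res = protocol.resolution_um_per_px
    if res > MAX_USABLE_RESOLUTION_UM:
        raise ValueError(
            f"protocol resolution {res} um/px is too coarse to resolve ISH signals"
        )
    if res + 1e-9 < base_resolution_um_per_px:
        raise ValueError(
            "base image must be rendered at a resolution at least as fine as the protocol's"
        )
    identity = (
        abs(res - base_resolution_um_per_px) < 1e-9
        and protocol.blur_sigma_um == 0
        and protocol.fade_factor == 1.0
        and protocol.focus_instability == 0
    )
    if identity:
        return image.copy()

    # keyed by seed only: the focal surface belongs to the mounted slide and
    # scan pass, so two protocols degrading the same base render see the
    # same focal-depth field (paired comparisons isolate the protocol)
    rng = child_rng(seed, "protocol")
    t = np.clip(np.asarray(image, dtype=float) / 255.0, 1e-4, 1.0)

    if protocol.fade_factor < 1.0:
        # OD' = fade * OD  <=>  t' = t ** fade
        t = np.power(t, protocol.fade_factor)

    scale = base_resolution_um_per_px / res
    if abs(scale - 1.0) > 1e-9:
        new_h = max(1, int(round(t.shape[0] * scale)))
        new_w = max(1, int(round(t.shape[1] * scale)))
        zoom = (new_h / t.shape[0], new_w / t.shape[1], 1.0)
        if scale < 1.0:
            # mild pre-smoothing to avoid aliasing when downsampling
            aa = 0.5 * (1.0 / scale - 1.0)
            t = ndimage.gaussian_filter(t, (aa, aa, 0))
        t = np.clip(ndimage.zoom(t, zoom, order=1), 1e-4, 1.0)

    sigma_base_px = protocol.blur_sigma_um / res
    if protocol.focus_instability > 0:
        z_um = _focal_depth_field(t.shape[:2], rng, protocol.focus_instability)
        if protocol.n_focus_layers > 1:
            offsets = (
                np.arange(protocol.n_focus_layers) - (protocol.n_focus_layers - 1) / 2.0
            ) * protocol.layer_step_um
            defocus_um = np.min(np.abs(z_um[..., None] - offsets[None, None, :]), axis=-1)
        else:
            defocus_um = np.abs(z_um)
        sigma_px = np.sqrt(sigma_base_px**2 + (DEFOCUS_BLUR_COEFF * defocus_um / res) ** 2)
        t = _variable_blur(t, sigma_px)
    elif sigma_base_px > 0.05:
        t = ndimage.gaussian_filter(t, (sigma_base_px, sigma_base_px, 0))

    return np.clip(np.rint(t * 255.0), 0, 255).astype(np.uint8)


def laplacian_sharpness(image: np.ndarray) -> float:
    """Variance-of-Laplacian sharpness of an RGB or grey image."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return float(ndimage.laplace(img).var())
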