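"""Case and scanning-protocol profiles.

A :class:`CaseProfile` captures the biology of one simulated tumour region:
mean HER2 and CEP17 signals per nucleus (so its expected HER2/CEP17 ratio is
available in closed form), count overdispersion, nucleus density and size,
and an optional amplified sub-population fraction for heterogeneous tumours.

A :class:`ProtocolProfile` captures one scanner/protocol combination: pixel
resolution, numerical aperture (may be unknown), extended-focus layering, and
the degradation strengths (blur, stain fading, focus instability) that the
simulator applies.  The shipped defaults mirror six protocols across three
scanners: A1/A2 at 0.12 um/px (dry vs water-immersion lens), B1 at 0.08,
B2/B3 at 0.17 (single layer vs 3-layer extended focus at 1.4 um steps), and
C1 at 0.26 um/px with unknown NA.  Resolutions, NA values and the extended
focus geometry are instrument facts; blur/fade/instability strengths are
calibrated qualitatively to each protocol's reported image character (A2 and
C1 pale, B1 focus-unstable at 40x, C1 additionally blurred and coarse) and
are flagged as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from ._rng import child_rng
from .scoring import classify_ish_group

PROTOCOL_SCHEMA = "her2ish/protocols-1"

#: Factor between the HER2 mean of the amplified sub-population and the bulk
#: mean when ``amplified_fraction`` > 0.
HETEROGENEITY_FACTOR = 4.0


@dataclass(frozen=True)
class CaseProfile:
    """Generative description of one tumour region.

    ``dispersion`` is the negative-binomial overdispersion ``a`` in
    ``Var[X] = mu + a * mu**2`` (0 = Poisson).  ``amplified_fraction`` draws
    that fraction of nuclei from a sub-population whose HER2 mean is
    ``HETEROGENEITY_FACTOR`` times the rest, while keeping the overall mean at
    ``mean_her2_per_nucleus``.
    """

    mean_her2_per_nucleus: float
    mean_cep17_per_nucleus: float
    dispersion: float = 0.3
    nucleus_density_per_mm2: float = 3000.0
    nucleus_radius_um: float = 4.0
    nucleus_radius_sd_um: float = 0.5
    amplified_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_her2_per_nucleus <= 0 or self.mean_cep17_per_nucleus <= 0:
            raise ValueError("signal means must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.amplified_fraction <= 1.0:
            raise ValueError("amplified_fraction must lie in [0, 1]")
        if self.nucleus_density_per_mm2 < 0:
            raise ValueError("nucleus density must be >= 0")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus radius must be positive")

    @property
    def expected_ratio(self) -> float:
        """Closed-form expected HER2/CEP17 ratio of the generator."""
        return self.mean_her2_per_nucleus / self.mean_cep17_per_nucleus


@dataclass(frozen=True)
class ProtocolProfile:
    """Imaging parameters of one scanning protocol.

    ``numerical_aperture`` may be ``None`` (unknown for scanner C).
    ``calibrated`` is False when the degradation strengths were set from
    qualitative image descriptions rather than stated instrument parameters.
    """

    name: str
    resolution_um_per_px: float
    numerical_aperture: float | None = None
    n_focus_layers: int = 1
    layer_step_um: float = 0.0
    blur_sigma_um: float = 0.0
    fade_factor: float = 1.0
    focus_instability: float = 0.0
    calibrated: bool = True

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if self.n_focus_layers < 1:
            raise ValueError("n_focus_layers must be >= 1")
        if not 0.0 < self.fade_factor <= 1.0:
            raise ValueError("fade_factor must lie in (0, 1]")
        if not 0.0 <= self.focus_instability <= 1.0:
            raise ValueError("focus_instability must lie in [0, 1]")
        if self.blur_sigma_um < 0 or self.layer_step_um < 0:
            raise ValueError("blur and layer step must be >= 0")


def clean_protocol(resolution_um_per_px: float, name: str = "clean") -> ProtocolProfile:
    """An identity protocol at the given resolution (no degradation)."""
    return ProtocolProfile(name=name, resolution_um_per_px=resolution_um_per_px)


DEFAULT_PROTOCOLS: dict[str, ProtocolProfile] = {
    "A1": ProtocolProfile("A1", 0.12, 0.95, blur_sigma_um=0.10, fade_factor=1.00, focus_instability=0.05),
    "A2": ProtocolProfile("A2", 0.12, 1.20, blur_sigma_um=0.15, fade_factor=0.60, focus_instability=0.05),
    "B1": ProtocolProfile("B1", 0.08, 0.95, blur_sigma_um=0.12, fade_factor=1.00, focus_instability=0.50),
    "B2": ProtocolProfile("B2", 0.17, 0.80, blur_sigma_um=0.15, fade_factor=1.00, focus_instability=0.35),
    "B3": ProtocolProfile(
        "B3", 0.17, 0.80, n_focus_layers=3, layer_step_um=1.4,
        blur_sigma_um=0.15, fade_factor=1.00, focus_instability=0.35,
    ),
    "C1": ProtocolProfile(
        "C1", 0.26, None, blur_sigma_um=1.20, fade_factor=0.28,
        focus_instability=0.65, calibrated=False,
    ),
}


def dump_protocols(protocols: dict[str, ProtocolProfile], path: str | Path | None = None) -> str:
    payload = {
        "schema": PROTOCOL_SCHEMA,
        "protocols": {
            name: {
                "resolution_um_per_px": p.resolution_um_per_px,
                "numerical_aperture": p.numerical_aperture,
                "n_focus_layers": p.n_focus_layers,
                "layer_step_um": p.layer_step_um,
                "blur_sigma_um": p.blur_sigma_um,
                "fade_factor": p.fade_factor,
                "focus_instability": p.focus_instability,
                "calibrated": p.calibrated,
            }
            for name, p in protocols.items()
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_protocols(source: str | Path) -> dict[str, ProtocolProfile]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    data = json.loads(text)
    schema = data.get("schema", "")
    if not schema.startswith("her2ish/protocols-"):
        raise ValueError(f"not a protocol document: {schema!r}")
    if int(schema.rsplit("-", 1)[1]) > 1:
        raise ValueError(f"protocol schema {schema!r} is newer than this reader")
    return {
        name: ProtocolProfile(name=name, **fields)
        for name, fields in data["protocols"].items()
    }


# ---------------------------------------------------------------------------
# Truncated count expectations
# ---------------------------------------------------------------------------

def _count_dist(mean: float, dispersion: float):
    if dispersion <= 1e-12:
        return stats.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom(r, p)


def truncated_count_mean(mean: float, dispersion: float, min_count: int) -> float:
    """``E[X | X >= min_count]`` for the generator's count distribution.

    Used to reason about the systematic inflation the nucleus-inclusion rule
    introduces: conditioning on at least two signals of a probe pushes the
    reported mean above the population mean, strongly so for small means.
    """
    if min_count <= 0:
        return mean
    d = _count_dist(mean, dispersion)
    k = np.arange(0, min_count)
    below_mass = d.pmf(k).sum()
    below_weighted = (k * d.pmf(k)).sum()
    denom = 1.0 - below_mass
    if denom <= 0:
        return float("nan")
    return (mean - below_weighted) / denom


def expected_reported_means(profile: CaseProfile, min_her2: int = 2, min_cep17: int = 2) -> tuple[float, float]:
    """Expected per-nucleus means *after* the inclusion filter."""
    th = truncated_count_mean(profile.mean_her2_per_nucleus, profile.dispersion, min_her2)
    tc = truncated_count_mean(profile.mean_cep17_per_nucleus, profile.dispersion, min_cep17)
    return th, tc


# ---------------------------------------------------------------------------
# Group-targeted case sampling
# ---------------------------------------------------------------------------

#: Sampling boxes per target group.  Each entry gives the uniform ranges the
#: sampler draws from; parameterisation differs per group so that both the
#: closed-form expectations and the filter-inflated (truncated) expectations
#: land inside the target region.  All boxes keep >= 0.2 margin from every
#: group boundary in closed form.
_GROUP_DESIGNS: dict[int, dict] = {
    # (ratio, cep17) boxes
    1: {"ratio": (3.4, 4.4), "cep17": (2.6, 3.2)},
    5: {"her2": (2.2, 2.6), "cep17": (2.0, 2.4)},
    # (her2, cep17) boxes -- monosomy-like low CEP17; the box is narrow
    # because the filter-inflated expectations must clear ratio 2 and stay
    # under 4 copies simultaneously at 20-40-nucleus counting noise
    2: {"her2": (2.3, 2.5), "cep17": (0.55, 0.65)},
    # (her2, ratio) boxes
    3: {"her2": (7.2, 8.8), "ratio": (1.4, 1.7)},
    4: {"her2": (4.5, 5.0), "ratio": (1.3, 1.6)},
}

#: Overdispersion used for sampled study cases: a fairly homogeneous tumour
#: region; the CaseProfile default (0.3) models more heterogeneous material.
SAMPLED_CASE_DISPERSION = 0.1


def sample_case_profile(target_group: int, seed: int) -> CaseProfile:
    """Draw a :class:`CaseProfile` whose expectations sit strictly inside the
    target ASCO/CAP group region (margin >= 0.2 from every boundary).

    Group 2 profiles are monosomy-like (CEP17 mean < 1): with roughly two
    chromosomes 17 per nucleus, a ratio >= 2 forces >= 4 HER2 copies, so the
    open part of the group-2 region is only reachable at low CEP17 counts.
    """
    if target_group not in (1, 2, 3, 4, 5):
        raise ValueError(f"target_group must be 1..5, got {target_group}")
    rng = child_rng(seed, "case-profile", target_group)
    d = _GROUP_DESIGNS[target_group]
    if "her2" in d and "cep17" in d:
        h = rng.uniform(*d["her2"])
        c = rng.uniform(*d["cep17"])
    elif "ratio" in d and "cep17" in d:
        r = rng.uniform(*d["ratio"])
        c = rng.uniform(*d["cep17"])
        h = r * c
    else:
        h = rng.uniform(*d["her2"])
        r = rng.uniform(*d["ratio"])
        c = h / r
    profile = CaseProfile(
        mean_her2_per_nucleus=float(h),
        mean_cep17_per_nucleus=float(c),
        dispersion=SAMPLED_CASE_DISPERSION,
    )
    assert classify_ish_group(profile.expected_ratio, profile.mean_her2_per_nucleus) == target_group
    return profile
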