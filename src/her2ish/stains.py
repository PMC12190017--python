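"""Stain separation for dual bright-field ISH tiles.

The chromogens of the assay behave differently in RGB optical-density (OD)
space.  Hematoxylin (nuclear counterstain) and Fast Red (CEP17) are dyes with
stable chromatic OD directions and mix linearly under Beer-Lambert, so they
are unmixed by least-squares projection onto two unit OD vectors.  The HER2
chromogen is a silver precipitate: a grey/black, achromatic absorber with no
chromatic direction of its own.  It is therefore scored separately as a
*darkness* channel -- mean OD weighted towards pixels of low colour
saturation -- rather than by adding a third deconvolution vector.

All maps are in OD units (``-log10`` transmittance) and non-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

STAIN_MODEL_SCHEMA = "her2ish/stain-model-1"

#: Hematoxylin OD direction (classical published H&E unmixing vector).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
#: Fast Red OD direction: a red dye transmits red and absorbs green/blue.
FAST_RED_OD = (0.090, 0.790, 0.602)

#: Grey-level offset guarding the logarithm.
OD_EPS = 1.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainModel:
    """Two chromatic OD vectors plus the achromatic-silver scoring cutoff.

    ``darkness_saturation_cutoff`` separates achromatic pixels (silver over
    counterstain) from strongly chromatic ones (Fast Red); the transition is
    softened over ``saturation_softness`` to avoid hard mask edges.
    """

    od_vectors: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        HEMATOXYLIN_OD,
        FAST_RED_OD,
    )
    background_intensity: tuple[float, float, float] | None = None
    darkness_saturation_cutoff: float = 0.65
    saturation_softness: float = 0.07

    def __post_init__(self) -> None:
        m = np.asarray(self.od_vectors, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("od_vectors must be two RGB-OD direction vectors")
        if (m < -1e-9).any():
            raise ValueError("OD vector components must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=5e-3):
            raise ValueError("OD vectors must be unit length")
        if np.linalg.matrix_rank(m, tol=1e-6) < 2:
            raise ValueError("OD vectors must be linearly independent")
        m = m / norms[:, None]  # store exactly unit-norm
        object.__setattr__(self, "od_vectors", (tuple(m[0]), tuple(m[1])))

    @classmethod
    def default(cls) -> "StainModel":
        return cls(
            od_vectors=(tuple(_unit(HEMATOXYLIN_OD)), tuple(_unit(FAST_RED_OD)))
        )

    @property
    def matrix(self) -> np.ndarray:
        """(2, 3) stain matrix, rows = (hematoxylin, fast_red)."""
        return np.asarray(self.od_vectors, dtype=float)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": STAIN_MODEL_SCHEMA,
            "od_vectors": {
                "hematoxylin": list(self.od_vectors[0]),
                "fast_red": list(self.od_vectors[1]),
            },
            "background_intensity": (
                list(self.background_intensity) if self.background_intensity else None
            ),
            "darkness_saturation_cutoff": self.darkness_saturation_cutoff,
            "saturation_softness": self.saturation_softness,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StainModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        schema = data.get("schema", "")
        if not schema.startswith("her2ish/stain-model-"):
            raise ValueError(f"not a stain model document: {schema!r}")
        major = int(schema.rsplit("-", 1)[1])
        if major > 1:
            raise ValueError(f"stain model schema {schema!r} is newer than this reader")
        vecs = data["od_vectors"]
        bg = data.get("background_intensity")
        return cls(
            od_vectors=(tuple(vecs["hematoxylin"]), tuple(vecs["fast_red"])),
            background_intensity=tuple(bg) if bg else None,
            darkness_saturation_cutoff=float(data["darkness_saturation_cutoff"]),
            saturation_softness=float(data["saturation_softness"]),
        )


def estimate_background(image: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background intensity I0 as a high percentile of the tile.

    Robust when the tile lacks pure background; floored at 10 grey levels so
    a pathologically dark tile cannot produce a degenerate I0.
    """
    img = np.asarray(image, dtype=float)
    i0 = np.percentile(img.reshape(-1, img.shape[-1]), percentile, axis=0)
    return np.maximum(i0, 10.0)


def rgb_to_od(image: np.ndarray, background_intensity) -> np.ndarray:
    """Optical density ``-log10((value + eps) / I0)``, clipped at 0.

    Monotone decreasing in pixel brightness; a pixel at background intensity
    maps to (0, 0, 0).
    """
    i0 = np.asarray(background_intensity, dtype=float)
    if (i0 <= 0).any():
        raise ValueError("background intensity must be positive in every channel")
    img = np.asarray(image, dtype=float)
    od = -np.log10((img + OD_EPS) / i0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, background_intensity) -> np.ndarray:
    """Exact float inverse of :func:`rgb_to_od` (no quantisation)."""
    i0 = np.asarray(background_intensity, dtype=float)
    return i0 * np.power(10.0, -np.asarray(od, dtype=float)) - OD_EPS


@dataclass(frozen=True)
class StainMaps:
    hematoxylin: np.ndarray
    fast_red: np.ndarray
    residual: np.ndarray


def separate_stains(od: np.ndarray, model: StainModel, cond_limit: float = 1e4) -> StainMaps:
    """Least-squares unmixing of an OD image onto the two stain vectors.

    Concentrations are clipped at zero; the residual map is the Euclidean norm
    of the OD left unexplained by the (clipped) reconstruction.
    """
    m = model.matrix  # (2, 3)
    gram = m @ m.T
    if np.linalg.cond(gram) > cond_limit:
        raise ValueError("stain vectors are near-collinear; cannot unmix")
    od = np.asarray(od, dtype=float)
    flat = od.reshape(-1, 3)
    coef = np.linalg.solve(gram, m @ flat.T).T  # (N, 2)
    coef = np.clip(coef, 0.0, None)
    resid = np.linalg.norm(flat - coef @ m, axis=1)
    shape = od.shape[:-1]
    return StainMaps(
        hematoxylin=coef[:, 0].reshape(shape),
        fast_red=coef[:, 1].reshape(shape),
        residual=resid.reshape(shape),
    )


def saturation(image: np.ndarray) -> np.ndarray:
    """HSV-style colour saturation, (max - min) / max per pixel."""
    img = np.asarray(image, dtype=float)
    mx = img.max(axis=-1)
    mn = img.min(axis=-1)
    return (mx - mn) / np.maximum(mx, 1e-6)


def achromatic_weight(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Soft weight ~1 on achromatic (grey) pixels, ~0 on chromatic ones."""
    sat = saturation(image)
    z = (model.darkness_saturation_cutoff - sat) / model.saturation_softness
    return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))


def silver_channel(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Darkness score for the silver (HER2) chromogen.

    Mean OD per pixel, weighted towards achromatic pixels: silver is a grey
    precipitate, so its footprint is dark *and* unsaturated, whereas Fast Red
    deposits are dark but strongly chromatic and are suppressed.
    """
    i0 = (
        np.asarray(model.background_intensity, dtype=float)
        if model.background_intensity is not None
        else estimate_background(image)
    )
    od = rgb_to_od(image, i0)
    return od.mean(axis=-1) * achromatic_weight(image, model)


def redness_channel(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Red-chromogen contrast: ``max((OD_G + OD_B)/2 - OD_R, 0)``.

    A linear OD contrast that is positive exactly for red dyes (which absorb
    green/blue but transmit red), identically zero for achromatic silver
    (equal OD in all channels), and clipped to zero for hematoxylin (whose
    red absorption exceeds its blue).  Being linear in OD it scales with
    stain fading instead of vanishing below a fixed colour-saturation cutoff,
    which makes CEP17 detection robust on pale scans.
    """
    i0 = (
        np.asarray(model.background_intensity, dtype=float)
        if model.background_intensity is not None
        else estimate_background(image)
    )
    od = rgb_to_od(image, i0)
    return np.clip(0.5 * (od[..., 1] + od[..., 2]) - od[..., 0], 0.0, None)


#: Redness above this level marks a pixel as red-chromogen territory when
#: suppressing Fast Red leakage from the silver (darkness) map.
REDNESS_GATE = 0.10
REDNESS_GATE_SOFTNESS = 0.03


def chromatic_red_channel(image: np.ndarray, model: StainModel) -> np.ndarray:
    """CEP17 detection map: the redness contrast (see
    :func:`redness_channel`)."""
    return redness_channel(image, model)


def gated_silver_channel(image: np.ndarray, model: StainModel) -> np.ndarray:
    """HER2 detection map: the achromatic darkness score with red-chromogen
    pixels suppressed, so faded Fast Red deposits are never mistaken for
    silver."""
    red = redness_channel(image, model)
    z = (REDNESS_GATE - red) / REDNESS_GATE_SOFTNESS
    gate = 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))
    return silver_channel(image, model) * gate
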