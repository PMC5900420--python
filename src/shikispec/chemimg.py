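"""Pixel-wise chemical mapping: apply a calibration model to a hypercube.

Each foreground pixel of a reflectance cube has a spectral fingerprint; a
wavelength-subset PLSR calibration transfers to every pixel, yielding a
concentration image (the shikimate "prediction map").  Background pixels
carry NaN, never a concentration.  Maps render as PNGs with a linear
blue-to-red colormap and an embedded colorbar strip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from matplotlib import colors as mcolors
from PIL import Image

from .chemo import PLSModel, predict
from .hsio import BandLookupError, HyperCube, Spectrum, band_index

__all__ = ["PredictionMap", "predict_map", "render_map", "BLUE_RED"]

#: linear blue -> red map used for concentration rendering
BLUE_RED = mcolors.LinearSegmentedColormap.from_list(
    "blue_red", ["#2166ac", "#67a9cf", "#f7f7f7", "#ef8a62", "#b2182b"]
)


@dataclass
class PredictionMap:
    """2-D concentration image; background pixels are NaN."""

    values: np.ndarray
    mask: np.ndarray
    model_id: str = ""
    clip_range: tuple[float, float] = field(default=(0.0, 1.0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share one shape")
        if self.mask.any() and not np.isfinite(self.values[self.mask]).all():
            raise ValueError("foreground values must be finite")

    @property
    def foreground_mean(self) -> float:
        return float(np.nanmean(self.values[self.mask])) if self.mask.any() else np.nan


def _resolve_model_bands(model: PLSModel, wavelengths: np.ndarray) -> np.ndarray:
    if model.feature_names is None:
        raise ValueError("model has no wavelength feature names to resolve")
    idx = []
    for name in model.feature_names:
        nm = float(name)
        try:
            idx.append(band_index(wavelengths, nm))
        except BandLookupError as e:
            raise BandLookupError(f"model wavelength {nm} nm not on cube axis: {e}") from e
    return np.asarray(idx, dtype=int)


def predict_map(
    cube: HyperCube,
    model: PLSModel,
    mask: np.ndarray | None = None,
    preprocess: Callable[[Spectrum], Spectrum] | None = None,
) -> PredictionMap:
    """Concentration image from per-pixel application of ``model``.

    The model's wavelengths are resolved on the cube axis (nearest band
    within 1.5 nm; unresolvable wavelengths raise, naming the offender).
    ``preprocess``, when given, is applied to every full-axis pixel spectrum
    before the model's bands are extracted -- the same treatment the
    calibration spectra received.  An empty mask yields an all-NaN map.
    """
    if mask is None:
        mask = cube.mask
    if mask is None:
        raise ValueError("no mask given and the cube carries none")
    mask = np.asarray(mask, dtype=bool)
    bands = _resolve_model_bands(model, cube.wavelengths)
    values = np.full(mask.shape, np.nan)
    if mask.any():
        pix = cube.data[mask].astype(float)  # (n_fg, n_bands)
        if preprocess is not None:
            pix = np.stack(
                [preprocess(Spectrum(cube.wavelengths, row)).values for row in pix]
            )
        values[mask] = predict(model, pix[:, bands])
        lo, hi = np.percentile(values[mask], [1, 99])
    else:
        lo, hi = 0.0, 1.0
    return PredictionMap(
        values=values,
        mask=mask,
        model_id=model.metadata.get("model_id", ""),
        clip_range=(float(lo), float(hi)),
    )


def render_map(
    pmap: PredictionMap,
    out_path: str | Path,
    colormap=BLUE_RED,
    clip_range: tuple[float, float] | None = None,
    colorbar: bool = True,
) -> Path:
    """Write a PNG of the map: blue -> red over ``clip_range``.

    Background renders neutral grey; a vertical colorbar strip is appended
    at the right edge.  Rendering is deterministic: identical map and range
    yield byte-identical files.
    """
    lo, hi = clip_range if clip_range is not None else pmap.clip_range
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("clip range must be finite")
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((pmap.values - lo) / span, 0.0, 1.0)
    rgb = (np.asarray(colormap(norm))[:, :, :3] * 255).astype(np.uint8)
    rgb[~pmap.mask] = 217  # neutral grey background
    if colorbar:
        h, w = rgb.shape[:2]
        gap = np.full((h, 2, 3), 255, dtype=np.uint8)
        grad = np.linspace(1.0, 0.0, h)[:, None]
        bar = (np.asarray(colormap(np.repeat(grad, 10, axis=1)))[:, :, :3] * 255).astype(
            np.uint8
        )
        rgb = np.concatenate([rgb, gap, bar], axis=1)
    out_path = Path(out_path)
    Image.fromarray(rgb).save(out_path, format="PNG")
    return out_path
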