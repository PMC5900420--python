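"""Hyperspectral I/O, calibration, segmentation and spectral preprocessing.

The unit records of the package live here: :class:`Spectrum` (one wavelength
axis plus a reflectance vector) and :class:`HyperCube` (rows x cols x bands
reflectance with a wavelength axis and optional foreground mask).  On top of
them the module provides reflectance calibration against white/dark
references, NIR/red band-ratio plant segmentation, ROI averaging, spectral
cropping, and the standard chemometric preprocessing repertoire (wavelet
detrending, SNV, MSC, Savitzky-Golay).

Cubes are persisted in the plain ENVI layout: an ASCII ``.hdr`` carrying the
wavelength list next to a flat little-endian float32 binary in BIL
interleave.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from scipy import ndimage
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "HyperCube",
    "CalibrationError",
    "EmptyMaskError",
    "BandLookupError",
    "band_index",
    "reflectance_calibrate",
    "segment_plant",
    "mean_roi_spectrum",
    "crop_spectrum",
    "wavelet_detrend",
    "snv",
    "msc",
    "savgol",
    "write_envi",
    "read_envi",
]

#: half the nominal 2.8 nm instrument resolution; nearest-band lookups
#: farther than this from any sampled wavelength raise.
BAND_LOOKUP_TOL_NM = 1.5


class CalibrationError(ValueError):
    """White minus dark reference is zero somewhere."""


class EmptyMaskError(ValueError):
    """A segmentation or ROI operation produced/received no foreground."""


class BandLookupError(KeyError):
    """Requested wavelength is too far from every sampled band."""


@dataclass
class Spectrum:
    """A single reflectance spectrum on a strictly increasing nm axis."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "Spectrum":
        """New spectrum on the same axis (preprocessing never moves the axis)."""
        return Spectrum(self.wavelengths, np.asarray(values, dtype=float))


@dataclass
class HyperCube:
    """Reflectance cube, ``data[row, col, band]`` over ``wavelengths`` (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count must equal wavelength count")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must equal the spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def band_index(wavelengths: np.ndarray, nm: float, tol: float = BAND_LOOKUP_TOL_NM) -> int:
    """Index of the band nearest ``nm``; error beyond ``tol`` nanometres."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    i = int(np.argmin(np.abs(wavelengths - nm)))
    if abs(wavelengths[i] - nm) > tol:
        raise BandLookupError(
            f"no band within {tol} nm of {nm} nm (nearest: {wavelengths[i]:.2f} nm)"
        )
    return i


# ---------------------------------------------------------------------------
# calibration / segmentation / ROI
# ---------------------------------------------------------------------------

def reflectance_calibrate(raw: HyperCube, white: HyperCube, dark: HyperCube) -> HyperCube:
    """Relative reflectance ``R = (raw - dark) / (white - dark)``, element-wise."""
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white and dark cubes must share one shape")
    denom = white.data.astype(float) - dark.data.astype(float)
    n_zero = int(np.count_nonzero(denom == 0))
    if n_zero:
        raise CalibrationError(
            f"white minus dark reference is zero at {n_zero} voxel(s)"
        )
    refl = (raw.data.astype(float) - dark.data.astype(float)) / denom
    return HyperCube(refl, raw.wavelengths.copy())


def segment_plant(
    cube: HyperCube,
    red_band: float = 670.0,
    nir_band: float = 800.0,
    ratio_threshold: float = 2.0,
) -> np.ndarray:
    """Foreground = pixels with NIR/red reflectance ratio above threshold.

    Vegetation is bright in the NIR plateau and dark at the red chlorophyll
    absorption, so the simple band ratio separates canopy from soil and
    belt backgrounds.  Of the pixels passing the ratio test only the largest
    8-connected component is kept (one plant per scene).
    """
    i_red = band_index(cube.wavelengths, red_band)
    i_nir = band_index(cube.wavelengths, nir_band)
    red = cube.data[:, :, i_red].astype(float)
    nir = cube.data[:, :, i_nir].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(red > 0, nir / red, np.inf * np.sign(nir + 1e-300))
        ratio = np.where((red == 0) & (nir == 0), 0.0, ratio)
    candidate = ratio > ratio_threshold
    if not candidate.any():
        raise EmptyMaskError("no pixel exceeds the NIR/red ratio threshold")
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return candidate
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def mean_roi_spectrum(cube: HyperCube, mask: np.ndarray) -> Spectrum:
    """Per-band arithmetic mean of all pixels inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must equal the cube's spatial shape")
    if not mask.any():
        raise EmptyMaskError("ROI mask is empty")
    return Spectrum(cube.wavelengths.copy(), cube.data[mask].mean(axis=0))


def crop_spectrum(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep wavelengths in the closed interval [lo, hi]."""
    if not lo < hi:
        raise ValueError("crop requires lo < hi")
    keep = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no wavelengths inside [{lo}, {hi}] nm")
    return Spectrum(s.wavelengths[keep], s.values[keep])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def wavelet_detrend(
    s: Spectrum,
    wavelet_name: str = "db6",
    level: int = 3,
    mode: str = "denoise",
) -> Spectrum:
    """Daubechies wavelet detrending of a spectrum.

    ``mode="denoise"`` soft-thresholds every detail level with the universal
    threshold sigma * sqrt(2 ln n), sigma estimated from the median absolute
    deviation of the finest-level details, then reconstructs.
    ``mode="debaseline"`` subtracts the reconstruction of the level-``level``
    approximation (the smooth background) from the signal.

    Symmetric signal extension is used throughout; output length equals
    input length.
    """
    if mode not in ("denoise", "debaseline"):
        raise ValueError("mode must be 'denoise' or 'debaseline'")
    v = s.values
    n = v.size
    wavelet = pywt.Wavelet(wavelet_name)
    if pywt.dwt_max_level(n, wavelet.dec_len) < level:
        raise ValueError(
            f"spectrum of length {n} too short for {wavelet_name} at level {level}"
        )
    coeffs = pywt.wavedec(v, wavelet, mode="symmetric", level=level)
    if mode == "denoise":
        detail_fine = coeffs[-1]
        sigma = np.median(np.abs(detail_fine - np.median(detail_fine))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        new_coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
        ]
        out = pywt.waverec(new_coeffs, wavelet, mode="symmetric")[:n]
    else:
        approx_only = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
        baseline = pywt.waverec(approx_only, wavelet, mode="symmetric")[:n]
        out = v - baseline
    return s.with_values(out)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre and scale by the sample sd (n-1)."""
    sd = float(np.std(s.values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("SNV undefined for a constant spectrum")
    return s.with_values((s.values - s.values.mean()) / sd)


def msc(s: Spectrum, reference: Spectrum) -> Spectrum:
    """Multiplicative scatter correction against a reference spectrum.

    Regress the spectrum on the reference (ordinary least squares) and
    return ``(v - intercept) / slope``.
    """
    if s.wavelengths.shape != reference.wavelengths.shape or not np.allclose(
        s.wavelengths, reference.wavelengths
    ):
        raise ValueError("MSC reference must share the spectrum's axis")
    slope, intercept = np.polyfit(reference.values, s.values, 1)
    if slope == 0.0:
        raise ValueError("MSC slope is zero; correction undefined")
    return s.with_values((s.values - intercept) / slope)


def savgol(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay least-squares local polynomial smoothing."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    return s.with_values(savgol_filter(s.values, window, polyorder))


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def write_envi(path: str | Path, cube: HyperCube) -> tuple[Path, Path]:
    """Write ``cube`` as ENVI: ASCII ``.hdr`` + flat ``.bil`` binary.

    Layout is BIL interleave, little-endian IEEE float32 (ENVI data type 4,
    byte order 0).  Returns the (hdr, bil) paths.
    """
    base = Path(path)
    if base.suffix in (".hdr", ".bil"):
        base = base.with_suffix("")
    hdr_path = base.with_suffix(".hdr")
    bil_path = base.with_suffix(".bil")
    lines, samples, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {shikispec hyperspectral cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(hdr)
    # BIL: for each line, bands x samples
    arr = np.ascontiguousarray(
        cube.data.astype("<f4").transpose(0, 2, 1)
    )  # (lines, bands, samples)
    arr.tofile(bil_path)
    return hdr_path, bil_path


def _parse_envi_header(text: str) -> dict:
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read a cube written by :func:`write_envi` (BIL float32, byte order 0)."""
    base = Path(path)
    if base.suffix in (".hdr", ".bil"):
        base = base.with_suffix("")
    hdr = _parse_envi_header(base.with_suffix(".hdr").read_text())
    samples = int(hdr["samples"])
    lines = int(hdr["lines"])
    bands = int(hdr["bands"])
    if int(hdr.get("data type", "4")) != 4 or hdr.get("interleave", "bil") != "bil":
        raise ValueError("only BIL float32 ENVI cubes are supported")
    wl_text = hdr["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    raw = np.fromfile(base.with_suffix(".bil"), dtype="<f4")
    if raw.size != lines * bands * samples:
        raise ValueError("binary size does not match header dimensions")
    data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    return HyperCube(data, wavelengths)
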