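"""Synthetic glyphosate-stress study generator.

Everything downstream of the instrument is testable without any real data
through this module.  It emulates a two-genotype maize trial: a wild type
(WT) whose shikimic acid rises with days after glyphosate, and a
glyphosate-tolerant transgenic line (TG) that, like all water controls,
keeps a low constant level.  Shikimate drives two latent optical variables
-- canopy pigment (chlorophyll a+b) and the effective 950-nm O-H absorption
path -- which shape reflectance through a Beer-Lambert-style model:

    r(lambda) = m * baseline(lambda) * exp(-sum_k c_k g_k(lambda)) + a + eps

with a smooth healthy-leaf baseline (low visible reflectance, red edge near
700-750 nm, NIR plateau), Gaussian absorber bands g_k, multiplicative and
additive scatter (m, a) and white noise eps.  Losing pigment raises visible
reflectance; a growing 950-nm optical depth pulls the upper-NIR shoulder
down, reproducing the stressed-canopy signature (visible up, NIR down).

A parallel chlorophyll-fluorescence table carries ~60 parameters of which a
small informative subset (Fv/Fm, NPQ, qL, qP, quantum yields, ...) is affine
in shikimate plus noise; the rest are pure noise.  Cubes for the chemical
maps add per-pixel concentration heterogeneity over a canopy mask on a soil
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsio import HyperCube, Spectrum

__all__ = [
    "DesignSpec",
    "SpectralLibrary",
    "GroundTruth",
    "LinkParams",
    "NoiseModel",
    "WAVELENGTH_MIN_NM",
    "WAVELENGTH_MAX_NM",
    "N_BANDS",
    "INFORMATIVE_CHLF",
    "make_spectral_library",
    "make_narrowband_library",
    "simulate_spectrum",
    "simulate_experiment",
    "simulate_independent_bands",
    "simulate_cube",
    "soil_spectrum",
]

WAVELENGTH_MIN_NM = 427.75
WAVELENGTH_MAX_NM = 948.49
N_BANDS = 412

#: informative fluorescence parameters: slope per shikimate unit and noise sd.
#: Slope signs follow stress physiology (photochemical efficiency down,
#: non-photochemical quenching up); noise is sized so a multi-parameter PLSR
#: recovers shikimate with R2 near the mid-0.8s, mirroring the precision an
#: imaging fluorometer achieves on canopy means.
INFORMATIVE_CHLF: dict[str, tuple[float, float, float]] = {
    # name: (intercept, slope per shikimate unit, noise sd)
    "Fv/Fm": (0.80, -0.0015, 0.068),
    "NPQ": (0.50, 0.0040, 0.180),
    "qL": (0.60, -0.0020, 0.090),
    "qP": (0.70, -0.0020, 0.090),
    "QY_max": (0.75, -0.0014, 0.063),
    "QY_Lss": (0.55, -0.0018, 0.081),
    "NPQ_Lss": (0.60, 0.0035, 0.158),
    "Fm_Lss": (2.20, -0.0060, 0.270),
    "Rfd": (1.80, -0.0050, 0.225),
    "qN": (0.45, 0.0030, 0.135),
    "Fv/F0": (3.80, -0.0080, 0.360),
}

_NOISE_CHLF_PREFIXES = (
    "F0", "Fm", "Fp", "Ft_Lss", "F0_Lss",
    "Fm_L1", "Fm_L2", "Fm_L3", "Fm_L4", "Fm_L5",
    "Fm_D1", "Fm_D2", "Fm_D3",
    "QY_L1", "QY_L2", "QY_L3", "QY_L4", "QY_L5",
    "NPQ_L1", "NPQ_L2", "NPQ_L3", "NPQ_L4", "NPQ_L5",
    "NPQ_D1", "NPQ_D2", "NPQ_D3",
    "qP_L1", "qP_L2", "qP_L3", "qP_L4", "qP_L5",
    "qL_L1", "qL_L2", "qL_L3", "qL_L4", "qL_L5",
    "Rfd_L1", "Rfd_L2", "Rfd_L3",
    "qN_L1", "qN_L2", "qN_L3", "qN_L4", "qN_L5",
    "Fv_L1", "Fv_L2", "Fv_L3", "Fv_L4", "Fv_L5",
)


@dataclass
class DesignSpec:
    """Sampling design: genotypes x assessment days x replicate pots.

    The default mirrors a 10-water / 20-glyphosate pots per genotype-day
    trial assessed at 2, 4, 6 and 8 days, i.e. 120 plants per genotype and
    240 in total.
    """

    genotypes: tuple[str, ...] = ("WT", "TG")
    days: tuple[int, ...] = (2, 4, 6, 8)
    n_water: int = 10
    n_glyphosate: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.n_glyphosate < 0:
            raise ValueError("replicate counts must be non-negative")
        if not self.genotypes or not self.days:
            raise ValueError("design needs at least one genotype and one day")

    @property
    def n_plants(self) -> int:
        return len(self.genotypes) * len(self.days) * (self.n_water + self.n_glyphosate)


@dataclass
class SpectralLibrary:
    """Wavelength axis, absorber band profiles and healthy-leaf baseline."""

    wavelengths: np.ndarray
    baseline: np.ndarray
    absorbers: dict[str, np.ndarray]        # name -> unit-peak absorbance profile
    absorber_bands: dict[str, list[tuple[float, float, float]]]  # (center, width, strength)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.baseline.min() < 0 or self.baseline.max() > 1:
            raise ValueError("baseline reflectance must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-plant latent state behind a simulated experiment."""

    shikimate: np.ndarray
    latent_pigment: np.ndarray
    latent_water: np.ndarray
    informative_bands: np.ndarray
    informative_chlf: list[str]
    meta: pd.DataFrame = field(default=None, repr=False)


@dataclass
class LinkParams:
    """Effect sizes tying shikimate to the optical/fluorescence latents.

    ``water_per_shikimate`` is positive: as stress (shikimate) grows the
    effective O-H absorption path at the 950 nm band rises, which lowers
    upper-NIR reflectance the way a wilting canopy does.
    """

    healthy_mean: float = 30.0
    healthy_sd: float = 10.0
    stress_slope_per_day: float = 12.0
    stress_noise_sd: float = 20.0
    pigment_base: float = 1.60
    pigment_per_shikimate: float = -0.010
    pigment_noise_sd: float = 0.12
    pigment_b_noise_sd: float = 0.20
    water_base: float = 0.30
    water_per_shikimate: float = 0.004
    water_noise_sd: float = 0.07

    def null(self) -> "LinkParams":
        """Copy with every shikimate link zeroed (null experiment)."""
        from dataclasses import replace

        return replace(
            self,
            stress_slope_per_day=0.0,
            pigment_per_shikimate=0.0,
            water_per_shikimate=0.0,
        )


@dataclass
class NoiseModel:
    """Instrument-level noise for simulated spectra."""

    noise_sd: float = 0.004
    scatter_mult_sd: float = 0.04
    scatter_add_sd: float = 0.008


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_spectral_library(seed: int = 0, randomize_strengths: bool = False) -> SpectralLibrary:
    """Default 412-band library over 427.75-948.49 nm.

    The baseline is a healthy-leaf template (green bump near 550 nm, red
    edge near 715 nm, NIR plateau ~0.5).  Absorbers: chlorophyll a (430,
    670 nm), chlorophyll b (460, 645 nm) and liquid water (950 nm).  The
    axis and band positions are fixed; ``randomize_strengths`` jitters band
    strengths +/-10% under ``seed``.
    """
    wl = np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_BANDS)
    baseline = (
        0.05
        + 0.45 * _sigmoid((wl - 715.0) / 16.0)
        + 0.05 * _gauss(wl, 550.0, 35.0)
    )
    bands = {
        "chlorophyll_a": [(430.0, 22.0, 1.0), (670.0, 28.0, 1.0)],
        "chlorophyll_b": [(460.0, 26.0, 0.8), (645.0, 24.0, 0.7)],
        "water": [(950.0, 38.0, 1.0)],
    }
    if randomize_strengths:
        rng = np.random.default_rng(seed)
        bands = {
            k: [(c, w, s * rng.uniform(0.9, 1.1)) for c, w, s in v]
            for k, v in bands.items()
        }
    absorbers = {
        name: sum(s * _gauss(wl, c, w) for c, w, s in blist)
        for name, blist in bands.items()
    }
    return SpectralLibrary(wl, baseline, absorbers, bands)


def make_narrowband_library(
    centers: tuple[float, ...] = (470.0, 550.0, 640.0, 710.0, 860.0),
    width: float = 4.0,
    seed: int = 0,
) -> SpectralLibrary:
    """Library variant with narrow, spectrally separated absorber bands.

    Used to build selection-power benchmarks where each informative band is
    localized to a few wavelengths instead of a broad pigment feature.
    """
    lib = make_spectral_library(seed)
    wl = lib.wavelengths
    bands = {f"band_{int(c)}": [(float(c), width, 1.0)] for c in centers}
    absorbers = {
        name: sum(s * _gauss(wl, c, w) for c, w, s in blist)
        for name, blist in bands.items()
    }
    return SpectralLibrary(wl, lib.baseline, absorbers, bands)


#: chlorophyll-b concentration relative to chlorophyll a
CHL_B_RATIO = 0.55


def _pigment_water_absorbance(
    lib: SpectralLibrary, pigment: np.ndarray, water: np.ndarray
) -> np.ndarray:
    """Total absorbance for pigment/water latents (broadcasts over samples)."""
    pigment = np.asarray(pigment, dtype=float)[..., None]
    water = np.asarray(water, dtype=float)[..., None]
    chl = lib.absorbers["chlorophyll_a"] + CHL_B_RATIO * lib.absorbers["chlorophyll_b"]
    return pigment * chl + water * lib.absorbers["water"]


def simulate_spectrum(
    lib: SpectralLibrary,
    pigment: float,
    water: float,
    scatter_mult: float = 1.0,
    scatter_add: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """One canopy reflectance spectrum from the Beer-Lambert generator.

    ``pigment`` and ``water`` are non-negative absorber concentrations;
    with both zero, unit multiplicative scatter, zero additive offset and
    zero noise the output equals the library baseline exactly.  Values are
    clipped to [0, 1.2].
    """
    if pigment < 0 or water < 0:
        raise ValueError("absorber concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    chl = lib.absorbers["chlorophyll_a"] + CHL_B_RATIO * lib.absorbers["chlorophyll_b"]
    absorb = pigment * chl + water * lib.absorbers["water"]
    r = scatter_mult * lib.baseline * np.exp(-absorb) + scatter_add
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, r.size)
    return Spectrum(lib.wavelengths.copy(), np.clip(r, 0.0, 1.2))


def _default_informative_bands(lib: SpectralLibrary) -> np.ndarray:
    centers = [c for blist in lib.absorber_bands.values() for c, _, _ in blist]
    idx = [int(np.argmin(np.abs(lib.wavelengths - c))) for c in centers]
    return np.unique(idx)


def simulate_experiment(
    design: DesignSpec,
    lib: SpectralLibrary | None = None,
    link: LinkParams | None = None,
    noise: NoiseModel | None = None,
    chlf_effect_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a full glyphosate trial.

    Returns ``(spectra, chlf, truth)``: two sample tables sharing the design
    metadata columns (plant_id, genotype, treatment, day) followed by
    features (reflectance per wavelength; fluorescence parameters), and the
    latent ground truth.  WT plants under glyphosate receive day-increasing
    shikimate; TG plants and all water controls sit at the low healthy
    level.  Row order is randomized under the design seed.
    """
    lib = lib if lib is not None else make_spectral_library(design.seed)
    link = link if link is not None else LinkParams()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(design.seed)

    rows = []
    for genotype in design.genotypes:
        for day in design.days:
            for treatment, n_rep in (("water", design.n_water),
                                     ("glyphosate", design.n_glyphosate)):
                for _ in range(n_rep):
                    rows.append((genotype, treatment, day))
    meta = pd.DataFrame(rows, columns=["genotype", "treatment", "day"])
    n = len(meta)
    meta.insert(0, "plant_id", [f"P{i:04d}" for i in range(n)])

    stressed = (meta["genotype"] == "WT") & (meta["treatment"] == "glyphosate")
    shik = rng.normal(link.healthy_mean, link.healthy_sd, n)
    shik = np.where(
        stressed,
        link.healthy_mean
        + link.stress_slope_per_day * meta["day"].to_numpy()
        + rng.normal(0.0, link.stress_noise_sd, n),
        shik,
    )
    shik = np.clip(shik, 1.0, None)

    # chlorophyll a and b track the same pigment latent but with
    # independent biological noise (their ratio drifts plant to plant)
    pigment = link.pigment_base + link.pigment_per_shikimate * shik
    chl_a = np.clip(pigment + rng.normal(0.0, link.pigment_noise_sd, n), 0.02, None)
    chl_b = CHL_B_RATIO * np.clip(
        pigment + rng.normal(0.0, link.pigment_b_noise_sd, n), 0.02, None
    )
    water = np.clip(
        link.water_base
        + link.water_per_shikimate * shik
        + rng.normal(0.0, link.water_noise_sd, n),
        0.0,
        None,
    )

    absorb = (
        chl_a[:, None] * lib.absorbers["chlorophyll_a"]
        + chl_b[:, None] * lib.absorbers["chlorophyll_b"]
        + water[:, None] * lib.absorbers["water"]
    )
    mult = 1.0 + rng.normal(0.0, noise.scatter_mult_sd, n)[:, None]
    add = rng.normal(0.0, noise.scatter_add_sd, n)[:, None]
    eps = rng.normal(0.0, noise.noise_sd, (n, lib.wavelengths.size)) if noise.noise_sd > 0 else 0.0
    spectra = np.clip(mult * lib.baseline * np.exp(-absorb) + add + eps, 0.0, 1.2)

    chlf_cols = {}
    for name, (a, b, sd) in INFORMATIVE_CHLF.items():
        chlf_cols[name] = a + chlf_effect_scale * b * shik + rng.normal(0.0, sd, n)
    n_noise = 60 - len(INFORMATIVE_CHLF)
    noise_names = list(_NOISE_CHLF_PREFIXES[:n_noise])
    for name in noise_names:
        center = rng.uniform(0.2, 3.0)
        sd = rng.uniform(0.05, 0.3) * max(center, 0.5)
        chlf_cols[name] = center + rng.normal(0.0, sd, n)

    order = rng.permutation(n)
    meta = meta.iloc[order].reset_index(drop=True)
    wl_names = [f"{w:.2f}" for w in lib.wavelengths]
    spectra_df = pd.concat(
        [meta, pd.DataFrame(spectra[order], columns=wl_names)], axis=1
    )
    chlf_df = pd.concat(
        [meta, pd.DataFrame({k: v[order] for k, v in chlf_cols.items()})], axis=1
    )
    truth = GroundTruth(
        shikimate=shik[order],
        latent_pigment=pigment[order],
        latent_water=water[order],
        informative_bands=_default_informative_bands(lib),
        informative_chlf=list(INFORMATIVE_CHLF),
        meta=meta,
    )
    return spectra_df, chlf_df, truth


def simulate_independent_bands(
    n_samples: int = 120,
    centers: tuple[float, ...] = (470.0, 550.0, 640.0, 710.0, 860.0),
    width: float = 4.0,
    latent_sd: float = 1.0,
    noise_sd: float = 0.004,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spectra whose response depends on independent narrow bands.

    Each centre carries its own latent factor; the response is the sum of
    the factors, so a selector must find (essentially) every band to predict
    it.  Returns ``(wavelengths, X, y, informative_indices)`` -- the
    ground-truth benchmark for wavelength-selection power.
    """
    lib = make_narrowband_library(centers, width, seed)
    rng = np.random.default_rng(seed)
    k = len(centers)
    latents = rng.normal(1.0, latent_sd, (n_samples, k)).clip(0.0, None)
    profiles = np.stack([lib.absorbers[f"band_{int(c)}"] for c in centers])
    absorb = latents @ profiles
    X = lib.baseline * np.exp(-absorb)
    X = X + rng.normal(0.0, noise_sd, X.shape)
    y = latents.sum(axis=1)
    idx = np.array([int(np.argmin(np.abs(lib.wavelengths - c))) for c in centers])
    return lib.wavelengths, X, y, idx


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Flat-ish soil/belt background template (NIR/red ratio ~1)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    return 0.22 + 0.00012 * (wavelengths - WAVELENGTH_MIN_NM)


def _canopy_mask(shape: tuple[int, int]) -> np.ndarray:
    """Default canopy silhouette: central disc plus two leaf-like lobes."""
    r, c = shape
    yy, xx = np.mgrid[0:r, 0:c]
    cy, cx = (r - 1) / 2.0, (c - 1) / 2.0
    disc = ((yy - cy) / (0.30 * r)) ** 2 + ((xx - cx) / (0.22 * c)) ** 2 <= 1.0
    lobe1 = ((yy - cy + 0.18 * r) / (0.12 * r)) ** 2 + ((xx - cx - 0.25 * c) / (0.28 * c)) ** 2 <= 1.0
    lobe2 = ((yy - cy - 0.10 * r) / (0.12 * r)) ** 2 + ((xx - cx + 0.25 * c) / (0.28 * c)) ** 2 <= 1.0
    return disc | lobe1 | lobe2


def simulate_cube(
    lib: SpectralLibrary,
    plant_shikimate: float,
    canopy_shape: tuple[int, int] | np.ndarray = (48, 48),
    pixel_heterogeneity_sd: float = 0.0,
    noise_sd: float = 0.002,
    link: LinkParams | None = None,
    seed: int = 0,
) -> tuple[HyperCube, np.ndarray]:
    """Hypercube of one plant over soil, plus the true concentration map.

    Foreground pixels carry per-pixel concentrations ``plant_shikimate +
    N(0, pixel_heterogeneity_sd)`` mapped through the deterministic
    shikimate->pigment/water link; background pixels carry the soil
    template.  The truth map holds NaN over background.
    """
    if isinstance(canopy_shape, np.ndarray):
        mask = canopy_shape.astype(bool)
    else:
        mask = _canopy_mask(tuple(canopy_shape))
    if not mask.any():
        raise ValueError("canopy mask is empty")
    link = link if link is not None else LinkParams()
    rng = np.random.default_rng(seed)
    n_fg = int(mask.sum())

    conc = np.full(n_fg, float(plant_shikimate))
    if pixel_heterogeneity_sd > 0:
        conc = conc + rng.normal(0.0, pixel_heterogeneity_sd, n_fg)
        conc = np.clip(conc, 0.5, None)
    pigment = np.clip(link.pigment_base + link.pigment_per_shikimate * conc, 0.02, None)
    water = np.clip(link.water_base + link.water_per_shikimate * conc, 0.0, None)
    absorb = _pigment_water_absorbance(lib, pigment, water)
    fg = lib.baseline * np.exp(-absorb)

    nb = lib.wavelengths.size
    data = np.broadcast_to(soil_spectrum(lib.wavelengths), mask.shape + (nb,)).copy()
    data[mask] = fg
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    data = np.clip(data, 0.0, 1.2).astype(np.float32)

    truth = np.full(mask.shape, np.nan)
    truth[mask] = conc
    return HyperCube(data, lib.wavelengths.copy(), mask=mask), truth
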