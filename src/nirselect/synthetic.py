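"""Synthetic NIR-like mixture spectra with a known informative-channel mask.

Emulates the structure of diffuse-reflectance NIR calibration data:
pure-component spectra built from smooth, heavily overlapping Gaussian
absorbance bands, Beer-Lambert linear mixing with random component
concentrations, a per-sample affine scatter distortion
(x -> a + b * x, the distortion SNV/MSC are designed to undo) and
additive channel noise.  The response is the concentration of one
designated component, so the channels under that component's bands —
within two band widths of each centre — form a known ground-truth
informative mask against which selector recall can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset, WavelengthGrid, make_wavelength_grid

__all__ = ["SyntheticSpec", "generate", "planted_band_benchmark"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``band_centers``/``band_widths``/``band_heights`` hold one sequence of
    Gaussian band parameters per component, in axis units.  ``noise_sd``
    is the additive channel-noise standard deviation in absorbance units;
    ``baseline_amp`` the half-range of the uniform per-sample additive
    offset; ``scatter_slope_sd`` the spread of the per-sample
    multiplicative gain around 1.  ``background_height`` scales a fixed,
    concentration-independent broad absorbance profile shared by every
    sample — the stable sample matrix that dominates real NIR spectra and
    makes scatter correction well-posed.
    """

    n_samples: int
    grid: WavelengthGrid
    n_components: int
    band_centers: tuple = ()
    band_widths: tuple = ()
    band_heights: tuple = ()
    target_component: int = 0
    conc_range: tuple = (0.2, 1.0)
    background_height: float = 0.0
    baseline_amp: float = 0.0
    scatter_slope_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0 <= self.target_component < self.n_components:
            raise ValueError("target_component out of range")
        if self.noise_sd < 0 or self.baseline_amp < 0 or self.scatter_slope_sd < 0:
            raise ValueError("artifact magnitudes must be nonnegative")
        if not (len(self.band_centers) == len(self.band_widths)
                == len(self.band_heights) == self.n_components):
            raise ValueError("need one band-parameter sequence per component")
        lo, hi = min(self.grid.start, self.grid.stop), max(self.grid.start, self.grid.stop)
        for centers in self.band_centers:
            for c in np.atleast_1d(centers):
                if not lo <= c <= hi:
                    raise ValueError(f"band centre {c} outside grid range")


def _pure_spectra(spec: SyntheticSpec, wl: np.ndarray) -> np.ndarray:
    K = np.zeros((spec.n_components, wl.size))
    for k in range(spec.n_components):
        for c, w, h in zip(np.atleast_1d(spec.band_centers[k]),
                           np.atleast_1d(spec.band_widths[k]),
                           np.atleast_1d(spec.band_heights[k])):
            K[k] += h * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return K


def generate(spec: SyntheticSpec) -> tuple[SpectralDataset, np.ndarray]:
    """Draw one dataset; a pure function of the spec (seed included).

    Returns the dataset and the boolean informative mask: channels within
    two band widths of any of the target component's band centres.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.grid.values
    K = _pure_spectra(spec, wl)
    lo, hi = spec.conc_range
    conc = rng.uniform(lo, hi, size=(spec.n_samples, spec.n_components))
    X = conc @ K
    if spec.background_height > 0:
        span = abs(spec.grid.stop - spec.grid.start)
        mid = (spec.grid.start + spec.grid.stop) / 2.0
        bg = spec.background_height * (
            np.exp(-0.5 * ((wl - mid) / (0.5 * span)) ** 2)
            + 0.3 * np.exp(-0.5 * ((wl - mid - 0.3 * span) / (0.2 * span)) ** 2))
        X += bg
    if spec.scatter_slope_sd > 0:
        X *= rng.normal(1.0, spec.scatter_slope_sd, size=(spec.n_samples, 1))
    if spec.baseline_amp > 0:
        X += rng.uniform(-spec.baseline_amp, spec.baseline_amp,
                         size=(spec.n_samples, 1))
    if spec.noise_sd > 0:
        X += rng.normal(0.0, spec.noise_sd, size=X.shape)
    y = conc[:, spec.target_component]

    mask = np.zeros(wl.size, dtype=bool)
    k = spec.target_component
    for c, w in zip(np.atleast_1d(spec.band_centers[k]),
                    np.atleast_1d(spec.band_widths[k])):
        mask |= np.abs(wl - c) <= 2.0 * w
    ds = SpectralDataset(X=X, wavelengths=wl, y=y,
                         axis_unit=spec.grid.unit, y_unit="conc",
                         meta={"synthetic": True, "seed": spec.seed})
    return ds, mask


def planted_band_benchmark(seed: int = 0) -> tuple[SpectralDataset, np.ndarray]:
    """The canonical selector benchmark: 60 samples on a 200-channel grid.

    The target component contributes a single narrow band at 1300 nm (15
    informative channels at the +/- 2-width convention), overlapped by two
    broad interferent components whose channels a good model also needs
    for correction.  Five further narrow-band nuisance components with
    large absorbances vary independently elsewhere in the spectrum: they
    carry no information about the response but dominate the spectral
    variance, which is exactly the situation in which discarding
    irrelevant channels improves a fixed-complexity PLS model.  Moderate
    affine scatter and channel noise on top.  Used throughout the selector
    and optimizer tests (with n_lv = 7, which is enough for the target and
    overlapping interferents plus scatter but cannot also absorb every
    nuisance direction at full spectrum).
    """
    grid = make_wavelength_grid(1100, 1498, 2)
    spec = SyntheticSpec(
        n_samples=60,
        grid=grid,
        n_components=8,
        band_centers=((1300.0,),
                      (1250.0,), (1320.0,),
                      (1120.0,), (1160.0,), (1200.0,), (1360.0,), (1400.0,)),
        band_widths=((7.0,),
                     (55.0,), (70.0,),
                     (18.0,), (25.0,), (20.0,), (22.0,), (16.0,)),
        band_heights=((0.6,),
                      (0.8,), (0.9,),
                      (1.2,), (1.2,), (1.2,), (1.2,), (1.2,)),
        target_component=0,
        conc_range=(0.2, 1.0),
        baseline_amp=0.05,
        scatter_slope_sd=0.05,
        noise_sd=0.02,
        seed=seed,
    )
    return generate(spec)


BENCHMARK_N_LV = 7  # latent variables used with the planted-band benchmark
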