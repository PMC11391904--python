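"""Vertical absorption spectra from energies and transition dipoles.

For an upward transition i → j the oscillator strength in atomic units is

    f = (2/3) · ΔE · ‖μ_ij‖²,

with ΔE = E_j − E_i in Hartree and μ_ij the transition dipole (e·Bohr).
Stick spectra from an ensemble of geometries are broadened with Gaussians
of fixed full width at half maximum (default 0.1 eV) and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import units
from .data import StateSpace
from .heads import CapabilityError, ExcitedStateModel

__all__ = [
    "StickSpectrum", "oscillator_strength", "broaden",
    "spectrum_from_samples", "ensemble_spectrum", "FWHM_DEFAULT_EV",
]

FWHM_DEFAULT_EV = 0.1


@dataclass
class StickSpectrum:
    """Vertical transitions: excitation energies (Hartree) and strengths."""

    energies: np.ndarray        # [n_sticks], E_abs = E_j - E_i > 0
    strengths: np.ndarray       # [n_sticks], dimensionless f >= 0

    def __post_init__(self):
        self.energies = np.atleast_1d(np.asarray(self.energies, float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, float))
        if np.any(self.strengths < -1e-300):
            raise ValueError("oscillator strengths must be non-negative")
        if np.any(self.energies <= 0):
            raise ValueError("absorption energies must be positive")

    @property
    def energies_ev(self) -> np.ndarray:
        return self.energies / units.EV


def oscillator_strength(delta_e: float, transition_dipole) -> float:
    """f = (2/3) ΔE ‖μ‖² in atomic units; rotation invariant in μ."""
    if delta_e <= 0:
        raise ValueError(
            f"oscillator strength needs an upward transition; got "
            f"delta_e = {delta_e}")
    mu = np.asarray(transition_dipole, dtype=float)
    return (2.0 / 3.0) * float(delta_e) * float(np.dot(mu, mu))


def broaden(stick_energies, strengths, grid, fwhm: float = FWHM_DEFAULT_EV):
    """Gaussian-broadened intensity on ``grid``.

    All energies (sticks, grid, fwhm) must share one unit. The integral of
    the returned intensity over an adequate grid equals the summed
    oscillator strength; a warning reports the truncated mass fraction if
    the grid is too narrow (sticks within 5 sigma of an edge).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    e = np.atleast_1d(np.asarray(stick_energies, float))
    f = np.atleast_1d(np.asarray(strengths, float))
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if e.size and (e.min() - grid.min() < 5 * sigma
                   or grid.max() - e.max() < 5 * sigma):
        from scipy.stats import norm
        lost = np.sum(f * (norm.cdf(grid.min(), e, sigma)
                           + norm.sf(grid.max(), e, sigma)))
        total = f.sum()
        if total > 0 and lost / total > 1e-12:
            warnings.warn(
                f"grid truncates {lost / total:.2e} of the spectral mass",
                RuntimeWarning)
    z = (grid[:, None] - e[None, :]) / sigma
    gauss = np.exp(-0.5 * z ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return gauss @ f


def _pairs_or_default(space: StateSpace, pairs):
    if pairs is None:
        return list(space.pairs)
    return [tuple(p) for p in pairs]


def spectrum_from_samples(samples: Sequence, space: StateSpace,
                          pairs=None, fwhm_ev: float = FWHM_DEFAULT_EV,
                          grid_ev: Optional[np.ndarray] = None):
    """Averaged broadened spectrum from objects carrying ``energies`` and
    ``transition_dipoles`` (dataset samples or predictions).

    Returns ``(grid_ev, intensity, sticks)``; intensities are per
    geometry (the ensemble average, each geometry weighted equally).
    """
    pairs = _pairs_or_default(space, pairs)
    stick_e, stick_f = [], []
    skipped = 0
    for s in samples:
        for (i, j) in pairs:
            de = float(s.energies[j] - s.energies[i])
            mu = s.transition_dipoles[space.pair_index(i, j)]
            if de <= 0:
                # an inverted gap (possible for imperfect predictions)
                # carries no absorption stick
                skipped += 1
                continue
            stick_e.append(de / units.EV)
            stick_f.append(oscillator_strength(de, mu))
    if skipped:
        warnings.warn(f"skipped {skipped} non-upward transition(s)",
                      RuntimeWarning)
    if not stick_e:
        raise ValueError("no upward transitions in the ensemble")
    stick_e = np.array(stick_e)
    stick_f = np.array(stick_f)
    if grid_ev is None:
        sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        lo = stick_e.min() - 6 * sigma
        hi = stick_e.max() + 6 * sigma
        grid_ev = np.linspace(lo, hi, max(int((hi - lo) / (sigma / 8)), 200))
    intensity = broaden(stick_e, stick_f, grid_ev, fwhm_ev) / len(samples)
    sticks = StickSpectrum(stick_e * units.EV, stick_f)
    return grid_ev, intensity, sticks


def ensemble_spectrum(model: ExcitedStateModel, geometries: Sequence,
                      pairs=None, fwhm_ev: float = FWHM_DEFAULT_EV,
                      grid_ev: Optional[np.ndarray] = None):
    """Predicted absorption spectrum averaged over an ensemble of
    geometries (equal weights); deterministic given model and inputs."""
    heads = model.config.heads
    if not (heads.energies and heads.dipoles):
        raise CapabilityError(
            "ensemble_spectrum needs energy and dipole heads; trained "
            f"heads: {list(heads.active)}")
    preds = model.predict(list(geometries),
                          ("energies", "transition_dipoles"))
    return spectrum_from_samples(preds, model.state_space, pairs, fwhm_ev,
                                 grid_ev)
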