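"""Phase-locking value (PLV) functional connectivity.

Instantaneous phase is the complex angle of the analytic signal obtained
with the Hilbert transform.  For two phase series phi_x, phi_y the PLV is

    R = | (1/N) * sum_j exp(i * (phi_x[j] - phi_y[j])) |

i.e. the resultant length of the phase-difference distribution: 1 for
perfect (constant-lag) locking, and for independent phases it decays to
the Rayleigh noise floor sqrt(pi)/(2 sqrt(N)).

Connectivity matrices are computed per 2-s epoch and averaged across
epochs; a fraction of samples at each epoch edge is discarded to avoid
Hilbert-transform edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .eeg_preprocess import EpochSet

__all__ = ["PLVMatrix", "instantaneous_phase", "plv", "connectivity_matrix"]

#: Fraction of samples discarded at each epoch edge before the PLV sum.
DEFAULT_EDGE_TRIM = 0.05


@dataclass
class PLVMatrix:
    """Symmetric channel x channel phase-locking matrix for one band."""

    values: np.ndarray
    band_label: str
    n_epochs_averaged: int
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("PLV matrix must be square")


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians in (-pi, pi]) of a single-channel signal.

    Computed as the angle of the analytic signal, which realises
    arctan(x_hilbert / x) with correct quadrant handling.  Amplitude-invariant:
    scaling the signal by any positive constant leaves the phase unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.angle(hilbert(x))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value between two phase series of equal length."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape or phase_a.ndim != 1:
        raise ValueError("phase series must be 1-D and of equal length")
    # sum/N rather than np.mean (which scales by 1/N) so plv(x, x) == 1 exactly
    z = np.exp(1j * (phase_a - phase_b))
    return float(np.abs(z.sum()) / z.size)


def _epoch_plv(epoch: np.ndarray, edge_trim: float) -> np.ndarray:
    """PLV matrix of one (n_channels, n_samples) epoch, all pairs at once."""
    n_samples = epoch.shape[1]
    cut = int(round(edge_trim * n_samples))
    phases = np.angle(hilbert(epoch, axis=1))
    if cut:
        phases = phases[:, cut: n_samples - cut]
    z = np.exp(1j * phases)
    m = np.abs(z @ z.conj().T) / phases.shape[1]
    return m


def connectivity_matrix(es: EpochSet, edge_trim: float = DEFAULT_EDGE_TRIM) -> PLVMatrix:
    """Epoch-averaged PLV matrix of an epoch set.

    PLV is evaluated within each epoch (after trimming ``edge_trim`` of the
    samples at each edge) and averaged across epochs; the diagonal is set
    to 1 and the matrix is symmetric by construction.
    """
    if es.n_epochs < 1:
        raise ValueError("empty epoch set: PLV undefined")
    if not 0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must be in [0, 0.5)")
    acc = np.zeros((es.n_channels, es.n_channels))
    for epoch in es.epochs:
        acc += _epoch_plv(epoch, edge_trim)
    values = acc / es.n_epochs
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return PLVMatrix(
        values=values,
        band_label=es.band_label,
        n_epochs_averaged=es.n_epochs,
        channel_names=list(es.channel_names),
    )
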