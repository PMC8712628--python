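"""Phase lag index (PLI) connectivity.

The PLI between two signals is the absolute value of the time-average of the
sign of their wrapped instantaneous phase difference,

    PLI = | (1/N) * sum_k sign(dphi(t_k)) |,   dphi wrapped to (-pi, pi].

It ranges from 0 (no consistent lagged phase relation) to 1 (perfectly
consistent non-zero lag) and is by construction insensitive to zero-lag
synchrony, the signature of field spread / volume conduction: sign(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochedBandSignal

#: phase differences closer to 0 than this count as exactly zero, so the
#: sign(0) = 0 convention survives floating-point round-off (e.g. two
#: channels equal up to a positive gain)
PHASE_TOL = 1e-9


class ZeroChannelError(ValueError):
    """Instantaneous phase is undefined for an all-zero channel."""

    def __init__(self, channels, roi_labels=None):
        self.channels = list(channels)
        if roi_labels is not None:
            names = [roi_labels[c] for c in self.channels]
            msg = f"all-zero channel(s): {names}"
        else:
            msg = f"all-zero channel(s) at index {self.channels}"
        super().__init__(msg)


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal PLI matrix for one subject and band."""

    subject_id: str
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("values must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]; the boundary -pi maps to +pi."""
    out = np.mod(-np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return -out


def instantaneous_phase(epoch: np.ndarray, fs: float) -> np.ndarray:
    """Phase of the analytic signal, per channel and sample, in (-pi, pi].

    ``epoch`` is (n_roi, n_samples) and should already be band-limited.
    Raises :class:`ZeroChannelError` for silent channels, whose phase is
    undefined.
    """
    epoch = np.asarray(epoch, dtype=float)
    zero = np.where(~np.any(epoch != 0, axis=1))[0]
    if zero.size:
        raise ZeroChannelError(zero)
    return np.angle(hilbert(epoch, axis=1))


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two phase series of equal length."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    d = wrap_phase(phase_a - phase_b)
    s = np.sign(d)
    s[np.abs(d) < PHASE_TOL] = 0.0
    return float(abs(np.mean(s)))


def _epoch_pli(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI for one epoch of phases (n_roi, n_samples).

    sign(wrapped dphi) equals sign(sin dphi) except exactly at dphi = pi,
    where the wrap convention assigns +1; that case is handled explicitly so
    the fast path agrees with :func:`pli_pair` everywhere.
    """
    n = phases.shape[0]
    c = np.cos(phases)
    s = np.sin(phases)
    out = np.zeros((n, n))
    for i in range(n - 1):
        # Im / Re of exp(i phi_i) * conj(exp(i phi_j)) for j > i
        im = s[i] * c[i + 1 :] - c[i] * s[i + 1 :]
        sg = np.sign(im)
        sg[np.abs(im) < PHASE_TOL] = 0.0
        boundary = (np.abs(im) < PHASE_TOL) & (
            c[i] * c[i + 1 :] + s[i] * s[i + 1 :] < 0
        )
        if np.any(boundary):
            sg[boundary] = 1.0
        out[i, i + 1 :] = np.abs(sg.mean(axis=1))
    return out + out.T


def pli_matrix(band_signal: EpochedBandSignal, min_epochs: int = 10) -> list[ConnectivityMatrix]:
    """One symmetric zero-diagonal PLI matrix per epoch."""
    if band_signal.n_epochs < min_epochs:
        raise ValueError(
            f"need at least {min_epochs} epochs, got {band_signal.n_epochs}"
        )
    out = []
    for ep in band_signal.epochs:
        try:
            phases = instantaneous_phase(ep, band_signal.fs)
        except ZeroChannelError as err:
            raise ZeroChannelError(err.channels) from err
        out.append(
            ConnectivityMatrix(
                subject_id=band_signal.subject_id,
                band=band_signal.band,
                values=_epoch_pli(phases),
            )
        )
    return out


def average_epoch_matrices(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of per-epoch matrices for one subject and band."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.subject_id != first.subject_id or m.band != first.band:
            raise ValueError("cannot average matrices across subjects or bands")
        if m.values.shape != first.values.shape:
            raise ValueError("matrix shapes differ")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(first.subject_id, first.band, mean)
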