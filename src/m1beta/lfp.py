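"""Extracellular potential forward model (line-source approximation).

The potential at an electrode is the superposition of contributions from
every membrane-current source, assuming an infinite homogeneous ohmic
medium of conductivity ``sigma`` (default 0.3 mS/mm, numerically equal to
S/m; frequency-independent).

Two source models are provided:

* :func:`lfp_point` — each source collapsed to a point at its segment
  midpoint, ``V = I / (4 π σ d)``;
* :func:`lfp_line` — each source treated as a uniform line current along
  its segment, with the logarithmic closed form obtained by integrating
  the point kernel along the axis.

Units: currents in nA, distances in µm, potentials in mV (with σ in S/m the
conversion factor is exactly 1).  Both models are linear in the currents
and scale as 1/σ.  Source–electrode distances are clamped at
``MIN_DISTANCE_UM`` to avoid the 1/r singularity.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import LFPRecording

__all__ = ["lfp_point", "lfp_line", "transfer_point", "transfer_line",
           "MIN_DISTANCE_UM", "DEFAULT_SIGMA"]

MIN_DISTANCE_UM = 1.0
DEFAULT_SIGMA = 0.3  # mS/mm == S/m


def _as_segments(segments: np.ndarray) -> np.ndarray:
    seg = np.asarray(segments, dtype=float)
    if seg.ndim != 3 or seg.shape[1:] != (2, 3):
        raise ValueError("segments must have shape (n_seg, 2, 3)")
    return seg


def transfer_point(segments: np.ndarray, electrodes: np.ndarray,
                   sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Point-source transfer matrix, shape ``(n_electrodes, n_segments)``.

    Entry ``(j, i)`` maps the current of segment i (nA) to the potential at
    electrode j (mV), placing all of the segment's current at its midpoint.
    """
    seg = _as_segments(segments)
    el = np.atleast_2d(np.asarray(electrodes, dtype=float))
    mid = seg.mean(axis=1)  # (n_seg, 3)
    d = np.linalg.norm(el[:, None, :] - mid[None, :, :], axis=-1)
    if np.any(d < MIN_DISTANCE_UM):
        warnings.warn("electrode within minimum distance of a source; clamped",
                      stacklevel=2)
        d = np.maximum(d, MIN_DISTANCE_UM)
    return 1.0 / (4 * np.pi * sigma * d)


def transfer_line(segments: np.ndarray, electrodes: np.ndarray,
                  sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Uniform line-source transfer matrix, shape ``(n_electrodes, n_segments)``.

    For a segment of length L with axial electrode coordinate s (measured
    from the segment start) and radial distance r, the kernel is

        1/(4 π σ L) · ln[ (√(h²+r²) − h) / (√(s²+r²) − s) ],   h = s − L.

    Degenerate (near-axis, in-span) placements are clamped to the minimum
    radial distance with a warning; zero-length segments fall back to the
    point kernel.
    """
    seg = _as_segments(segments)
    el = np.atleast_2d(np.asarray(electrodes, dtype=float))
    a, b = seg[:, 0, :], seg[:, 1, :]
    axis = b - a
    length = np.linalg.norm(axis, axis=-1)  # (n_seg,)
    degenerate = length < 1e-9
    safe_len = np.where(degenerate, 1.0, length)
    u = axis / safe_len[:, None]
    rel = el[:, None, :] - a[None, :, :]  # (n_el, n_seg, 3)
    s = np.einsum("ijk,jk->ij", rel, u)  # axial coordinate
    radial_vec = rel - s[..., None] * u[None, :, :]
    r = np.linalg.norm(radial_vec, axis=-1)
    near_span = (s > -MIN_DISTANCE_UM) & (s < length[None, :] + MIN_DISTANCE_UM)
    clamp = near_span & (r < MIN_DISTANCE_UM)
    if np.any(clamp):
        warnings.warn("electrode on a segment axis within its span; "
                      "radial distance clamped", stacklevel=2)
        r = np.where(clamp, MIN_DISTANCE_UM, r)
    h = s - length[None, :]
    # ratio (sqrt(h^2+r^2) - h) / (sqrt(s^2+r^2) - s); for h > 0 both terms
    # underflow, so use the conjugate form (the r^2 factors cancel)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            h > 0,
            (np.hypot(s, r) + s) / (np.hypot(h, r) + h),
            (np.hypot(h, r) - h) / (np.hypot(s, r) - s),
        )
    kernel = np.log(ratio) / safe_len[None, :]
    if np.any(degenerate):
        d = np.linalg.norm(el[:, None, :] - a[None, :, :], axis=-1)
        d = np.maximum(d, MIN_DISTANCE_UM)
        kernel = np.where(degenerate[None, :], 1.0 / d, kernel)
    return kernel / (4 * np.pi * sigma)


def _assemble(transfer: np.ndarray, currents: np.ndarray,
              electrodes: np.ndarray, fs: float, sigma: float) -> LFPRecording:
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    if currents.shape[0] != transfer.shape[1]:
        raise ValueError("one current waveform per segment required")
    samples = (transfer @ currents).T  # (n_t, n_el)
    el = np.atleast_2d(np.asarray(electrodes, dtype=float))
    depths = el[:, 1]  # y = cortical depth from pia
    return LFPRecording(depths, samples, fs=fs, sigma=sigma)


def lfp_point(segments: np.ndarray, currents: np.ndarray,
              electrodes: np.ndarray, sigma: float = DEFAULT_SIGMA,
              fs: float = 1000.0) -> LFPRecording:
    """LFP from point sources at segment midpoints.

    ``segments``: (n_seg, 2, 3) endpoint coordinates in µm; ``currents``:
    (n_seg, n_t) waveforms in nA; ``electrodes``: (n_el, 3) positions in µm.
    """
    return _assemble(transfer_point(segments, electrodes, sigma),
                     currents, electrodes, fs, sigma)


def lfp_line(segments: np.ndarray, currents: np.ndarray,
             electrodes: np.ndarray, sigma: float = DEFAULT_SIGMA,
             fs: float = 1000.0) -> LFPRecording:
    """LFP from uniform line sources (same signature as :func:`lfp_point`)."""
    return _assemble(transfer_line(segments, electrodes, sigma),
                     currents, electrodes, fs, sigma)
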