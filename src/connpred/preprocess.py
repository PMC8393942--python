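"""ROI time-series cleaning: volume discard, nuisance regression, band-pass
filtering, framewise-displacement scrubbing, and the grey-matter ROI
retention rule.

The stage order is fixed — discard initial volumes, regress nuisance
signals, band-pass filter, scrub high-motion volumes — matching the usual
connectivity-preprocessing convention of filtering residuals and censoring
last.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from connpred.simulate import Parcellation, TimeSeriesBlock

__all__ = [
    "BlockUnusableError",
    "bandpass",
    "compute_fd",
    "discard_initial",
    "preprocess_block",
    "regress_nuisance",
    "retain_rois",
    "scrub",
]


class BlockUnusableError(RuntimeError):
    """Raised when scrubbing leaves too few volumes to use the block."""


def discard_initial(block: TimeSeriesBlock, n: int = 5) -> TimeSeriesBlock:
    """Drop the first ``n`` volumes (T1-saturation window) from the data and
    both sidecars."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if block.n_volumes <= n:
        raise ValueError(
            f"block has {block.n_volumes} volumes, cannot discard {n}")
    return block.replace(data=block.data[n:], nuisance=block.nuisance[n:],
                         motion=block.motion[n:])


def _design_matrix(block: TimeSeriesBlock) -> np.ndarray:
    t = block.n_volumes
    trend = np.linspace(-1.0, 1.0, t)
    return np.column_stack([np.ones(t), trend, block.nuisance, block.motion])


def regress_nuisance(block: TimeSeriesBlock) -> TimeSeriesBlock:
    """Replace each ROI series by its OLS residual against the nuisance
    design.

    The design holds an intercept, a linear trend, the white-matter and CSF
    mean signals, and the six rigid-body motion parameters.  Residuals are
    orthogonal to every regressor; a rank-deficient design triggers a
    warning and a pseudoinverse fit.
    """
    x = _design_matrix(block)
    if block.n_volumes < 2 * x.shape[1]:
        raise ValueError(
            f"need >= {2 * x.shape[1]} volumes for {x.shape[1]} regressors, "
            f"got {block.n_volumes}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
        beta = np.linalg.pinv(x) @ block.data
    else:
        beta, *_ = np.linalg.lstsq(x, block.data, rcond=None)
    return block.replace(data=block.data - x @ beta)


def bandpass(block: TimeSeriesBlock, low: float = 0.009,
             high: float = 0.08, order: int = 4) -> TimeSeriesBlock:
    """Zero-phase Butterworth band-pass of every ROI column.

    The default 0.009-0.08 Hz band isolates the low-frequency fluctuations
    used for functional connectivity; applied forward and backward so no
    phase shift is introduced.
    """
    fs = 1.0 / block.tr
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist "
                         f"{nyq:.4f} Hz for TR {block.tr}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    return block.replace(data=signal.sosfiltfilt(sos, block.data, axis=0))


def compute_fd(motion: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm from a (volumes, 6) motion trace.

    FD_t = sum |d translations| + head_radius * sum |d rotations| using
    backward differences; rotations (radians) are converted to arc length
    on a sphere of ``head_radius`` mm.  FD of the first volume is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub(block: TimeSeriesBlock, fd: np.ndarray, threshold: float = 0.5,
          min_volumes: int = 10) -> tuple[TimeSeriesBlock, np.ndarray]:
    """Remove volumes whose framewise displacement exceeds ``threshold`` mm.

    Returns the censored block and the boolean keep-mask.  Raises
    :class:`BlockUnusableError` if fewer than ``min_volumes`` survive.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != block.n_volumes:
        raise ValueError("FD series length does not match block")
    keep = fd <= threshold
    if keep.sum() < min_volumes:
        raise BlockUnusableError(
            f"{block.subject_id} {block.condition} block {block.block_index}: "
            f"only {int(keep.sum())} volumes survive scrubbing")
    out = block.replace(data=block.data[keep], nuisance=block.nuisance[keep],
                        motion=block.motion[keep])
    return out, keep


def retain_rois(parcellation: Parcellation) -> list[int]:
    """ROIs with grey-matter coverage in every subject, original order."""
    cov = parcellation.coverage
    if cov.shape[0] == 0:
        raise ValueError("parcellation has no coverage information")
    kept = [int(r) for r in parcellation.table["roi_id"]
            if bool(cov[r].all())]
    if not kept:
        raise ValueError("no ROI is covered in all subjects")
    return kept


def preprocess_block(block: TimeSeriesBlock, n_discard: int = 5,
                     low: float = 0.009, high: float = 0.08,
                     fd_threshold: float = 0.5,
                     head_radius: float = 50.0
                     ) -> tuple[TimeSeriesBlock, np.ndarray]:
    """Full cleaning chain: discard -> nuisance regression -> band-pass ->
    scrub.  Returns the cleaned block and the scrub keep-mask."""
    b = discard_initial(block, n=n_discard)
    b = regress_nuisance(b)
    b = bandpass(b, low=low, high=high)
    fd = compute_fd(b.motion, head_radius=head_radius)
    return scrub(b, fd, threshold=fd_threshold)
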