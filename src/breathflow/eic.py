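"""Unit-mass binning of profile scans into an EIC matrix.

Single-quadrupole data are worked with at integer m/z throughout the
pipeline: the intensity observed at m/z x accrues to bin round(x), with
.5 ties rounding half up.  The dense (n_scans x n_bins) matrix this
produces is the workhorse of peak picking, clique building and
deconvolution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BinnedRun", "bin_run", "round_half_up"]


def round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


class BinnedRun:
    """EIC matrix view of a RawRun: rts (minutes) x integer m/z bins."""

    __slots__ = ("rts", "mz_bins", "matrix")

    def __init__(self, rts: np.ndarray, mz_bins: np.ndarray, matrix: np.ndarray):
        self.rts = rts
        self.mz_bins = mz_bins  # ascending integers
        self.matrix = matrix  # shape (len(rts), len(mz_bins))

    @property
    def scan_interval(self) -> float:
        if len(self.rts) < 2:
            return 0.0
        return float(np.median(np.diff(self.rts)))

    def eic(self, mz: int) -> np.ndarray:
        """Extracted ion chromatogram for one unit-mass bin (zeros if absent)."""
        idx = np.searchsorted(self.mz_bins, mz)
        if idx < len(self.mz_bins) and self.mz_bins[idx] == mz:
            return self.matrix[:, idx]
        return np.zeros(len(self.rts))


def bin_run(run, mz_range: tuple[int, int] | None = None) -> BinnedRun:
    """Bin a RawRun's scans to unit mass.

    ``mz_range`` is the closed integer interval of bins to keep; by
    default every bin observed in the run is kept.  Synthetic runs carry
    a pre-binned dense matrix which is reused directly.
    """
    dense = getattr(run, "_dense", None)
    if dense is not None:
        rts, mz_bins, matrix = dense
        if mz_range is not None:
            lo, hi = mz_range
            keep = (mz_bins >= lo) & (mz_bins <= hi)
            mz_bins, matrix = mz_bins[keep], matrix[:, keep]
        return BinnedRun(rts, mz_bins, matrix)

    rts = run.rts
    if mz_range is None:
        lo = min(int(round_half_up(s.mz).min()) for s in run.scans if len(s.mz))
        hi = max(int(round_half_up(s.mz).max()) for s in run.scans if len(s.mz))
    else:
        lo, hi = int(mz_range[0]), int(mz_range[1])
    mz_bins = np.arange(lo, hi + 1)
    matrix = np.zeros((len(rts), len(mz_bins)))
    for i, scan in enumerate(run.scans):
        if not len(scan.mz):
            continue
        bins = round_half_up(scan.mz)
        ok = (bins >= lo) & (bins <= hi)
        np.add.at(matrix[i], bins[ok] - lo, scan.intensity[ok])
    return BinnedRun(rts, mz_bins, matrix)
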