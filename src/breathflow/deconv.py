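"""Compound-centric route: segment-wise spectral deconvolution,
cross-sample compound alignment, and missing-compound recovery.

Each run is split at the temperature-ramp boundaries and the three
segments are deconvolved independently.  Compound detection finds
total-ion-current maxima whose co-varying EIC bundle is large enough;
spectrum extraction solves each member ion's contribution by
non-negative least squares against the Gaussian elution models of all
locally overlapping candidates, so co-eluting compounds are unmixed.
Spectra are rescaled to a base peak of 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .eic import bin_run
from .errors import ConfigError
from .merge import spectral_dot, vectorize
from .msio import RawRun

log = logging.getLogger(__name__)

__all__ = [
    "DeconvCompound",
    "AlignedCompound",
    "segment_run",
    "deconvolve",
    "align_compounds",
    "recover_missing",
]

DEFAULT_MIN_IONS = 4
DEFAULT_CORR_GATE = 0.9
DEFAULT_ALIGN_DOT = 0.7  # reuses the inter-route spectral threshold
DEFAULT_RT_TOL = 0.05


@dataclass
class DeconvCompound:
    """One deconvolved compound in one sample."""

    compound_id: str
    sample_id: str
    rt: float
    spectrum: dict[int, float]  # unit m/z -> relative intensity, base peak 1000
    area: float  # abundance * minutes
    segment: int  # 1..3

    def __post_init__(self) -> None:
        peak = max(self.spectrum.values())
        if abs(peak - 1000.0) > 1e-9:
            self.spectrum = {m: v * 1000.0 / peak for m, v in self.spectrum.items()}


@dataclass
class AlignedCompound:
    """One compound matched across samples."""

    aligned_id: str
    rt_consensus: float
    spectrum_consensus: dict[int, float]
    areas: dict[str, float]
    segment: int = 0
    recovered: set[str] = field(default_factory=set)
    members: list[DeconvCompound] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------


def segment_run(
    run: RawRun, boundaries: tuple[float, float] = (10.0, 38.67)
) -> list[RawRun]:
    """Partition a run's scans at the ramp boundaries into 3 sub-runs.

    Segment 1 owns its right edge (a scan at exactly 10.00 min falls in
    segment 1); segment 3 runs from just past the second boundary to the
    end.  An empty segment or a boundary outside the run's RT span is a
    configuration error.
    """
    rts = run.rts
    b1, b2 = boundaries
    if not (rts[0] <= b1 < b2 <= rts[-1]):
        raise ConfigError(
            f"segment boundaries {boundaries} outside run RT span "
            f"[{rts[0]:.2f}, {rts[-1]:.2f}] for {run.sample_id}"
        )
    masks = [rts <= b1, (rts > b1) & (rts <= b2), rts > b2]
    subs = []
    for seg, mask in enumerate(masks, start=1):
        scans = [s for s, m in zip(run.scans, mask) if m]
        if not scans:
            raise ConfigError(f"segment {seg} of {run.sample_id} is empty")
        sub = RawRun(run.sample_id, run.group_id, run.subset, scans, run.ramp_program)
        dense = getattr(run, "_dense", None)
        if dense is not None:
            rts_d, mz_bins, matrix = dense
            sub._dense = (rts_d[mask], mz_bins, matrix[mask])
        sub.segment = seg
        subs.append(sub)
    return subs


def deconvolve(
    subrun: RawRun,
    noise_threshold: float = 200.0,
    peak_sigma: float = 0.02,
    min_ions: int = DEFAULT_MIN_IONS,
    corr_gate: float = DEFAULT_CORR_GATE,
    segment: int | None = None,
) -> list[DeconvCompound]:
    """Two-stage deconvolution of one temperature-ramp segment.

    (i) compound detection: intensities below ``noise_threshold`` are
    floored, apexes are found in every unit-mass EIC, and apexes of
    different ions that coincide in retention time are clustered — a
    cluster of at least ``min_ions`` distinct ions whose EICs correlate
    (>= ``corr_gate``) with the cluster's Gaussian elution model is a
    candidate compound;
    (ii) spectrum extraction: member-ion contributions are solved
    jointly by non-negative least squares against the elution models of
    all overlapping candidates.  The area is the elution-model area
    times the summed loadings.
    """
    br = bin_run(subrun)
    if br.matrix.size == 0 or len(br.rts) < 5:
        return []
    seg = segment if segment is not None else getattr(subrun, "segment", 0)
    dt = br.scan_interval
    mat = np.where(br.matrix >= noise_threshold, br.matrix, 0.0)
    sigma_scans = max(1.0, peak_sigma / dt)

    # per-EIC apex detection, then co-elution clustering of apex times
    apex_idx: list[int] = []
    apex_mz: list[int] = []
    for j in np.nonzero(mat.max(axis=0) > 0)[0]:
        peaks, _ = signal.find_peaks(mat[:, j], prominence=noise_threshold)
        apex_idx.extend(int(p) for p in peaks)
        apex_mz.extend([int(j)] * len(peaks))
    if not apex_idx:
        return []
    order = np.argsort(apex_idx, kind="stable")
    apex_arr = np.array(apex_idx)[order]
    mz_arr = np.array(apex_mz)[order]
    bw = max(1.0, 0.75 * sigma_scans)
    breaks = np.nonzero(np.diff(apex_arr) > bw)[0]
    apexes: list[int] = []
    for chunk in np.split(np.arange(len(apex_arr)), breaks + 1):
        if len(set(mz_arr[chunk])) >= min_ions:
            apexes.append(int(np.median(apex_arr[chunk])))
    if not apexes:
        return []

    n = len(br.rts)
    half = int(np.ceil(4 * sigma_scans))
    models = []  # (apex_idx, lo, hi, model over full axis)
    for a in apexes:
        lo, hi = max(0, a - half), min(n, a + half + 1)
        model = np.zeros(n)
        model[lo:hi] = np.exp(
            -((br.rts[lo:hi] - br.rts[a]) ** 2) / (2 * peak_sigma**2)
        )
        models.append((int(a), lo, hi, model))

    # membership gate: EIC correlates with the candidate's elution model
    members: list[list[int]] = []
    for a, lo, hi, model in models:
        m_local = model[lo:hi]
        block = mat[lo:hi]
        active = np.nonzero(block.max(axis=0) > 0)[0]
        mem = []
        mc = m_local - m_local.mean()
        for j in active:
            e = block[:, j]
            ec = e - e.mean()
            denom = np.linalg.norm(ec) * np.linalg.norm(mc)
            if denom > 0 and float(np.dot(ec, mc)) / denom >= corr_gate:
                mem.append(int(j))
        members.append(mem)

    valid = [k for k in range(len(models)) if len(members[k]) >= min_ions]
    if not valid:
        return []

    # group overlapping candidates into blocks for joint unmixing
    blocks: list[list[int]] = []
    for k in valid:
        placed = False
        for blk in blocks:
            if any(
                models[k][1] < models[q][2] and models[q][1] < models[k][2]
                for q in blk
            ):
                blk.append(k)
                placed = True
                break
        if not placed:
            blocks.append([k])

    compounds: list[DeconvCompound] = []
    counter = 0
    for blk in blocks:
        lo = min(models[k][1] for k in blk)
        hi = max(models[k][2] for k in blk)
        design = np.column_stack([models[k][3][lo:hi] for k in blk])
        ions = sorted({j for k in blk for j in members[k]})
        loadings = np.zeros((len(blk), len(ions)))
        for col, j in enumerate(ions):
            sol, _ = optimize.nnls(design, mat[lo:hi, j])
            loadings[:, col] = sol
        for row, k in enumerate(blk):
            spec = {
                int(br.mz_bins[ions[col]]): float(loadings[row, col])
                for col in range(len(ions))
                if ions[col] in members[k] and loadings[row, col] > 0
            }
            if len(spec) < min_ions:
                continue
            model_area = peak_sigma * np.sqrt(2 * np.pi)
            counter += 1
            compounds.append(
                DeconvCompound(
                    compound_id=f"{subrun.sample_id}_S{seg}C{counter:03d}",
                    sample_id=subrun.sample_id,
                    rt=float(br.rts[models[k][0]]),
                    spectrum=spec,
                    area=float(model_area * sum(loadings[row])),
                    segment=seg,
                )
            )
    compounds.sort(key=lambda c: c.rt)
    return compounds


# ---------------------------------------------------------------------------


def _dot(spec_a: dict[int, float], spec_b: dict[int, float]) -> float:
    return spectral_dot(vectorize(spec_a), vectorize(spec_b))


def _consensus(members: list[DeconvCompound]) -> dict[int, float]:
    total: dict[int, float] = {}
    wsum = sum(m.area for m in members) or 1.0
    for m in members:
        for mz, rel in m.spectrum.items():
            total[mz] = total.get(mz, 0.0) + rel * m.area
    peak = max(total.values())
    return {mz: v * 1000.0 / peak for mz, v in total.items()}


def align_compounds(
    per_sample: dict[str, list[DeconvCompound]],
    rt_tol: float = DEFAULT_RT_TOL,
    min_spectral_dot: float = DEFAULT_ALIGN_DOT,
) -> list[AlignedCompound]:
    """Greedy cross-sample clustering of deconvolved compounds.

    Compounds are visited by descending area; one joins an existing
    cluster iff the RT (after a per-sample median-shift correction
    estimated from a first pass) agrees within ``rt_tol``, the spectral
    dot is >= ``min_spectral_dot`` and the cluster has no member from the
    same sample yet.  The consensus spectrum is the area-weighted mean,
    rescaled to base peak 1000.
    """
    all_comps = [c for comps in per_sample.values() for c in comps]
    if not all_comps:
        return []

    def cluster(shifts: dict[str, float]) -> list[list[DeconvCompound]]:
        clusters: list[list[DeconvCompound]] = []
        c_rts: list[float] = []
        c_specs: list[dict[int, float]] = []
        for comp in sorted(all_comps, key=lambda c: (-c.area, c.compound_id)):
            rt = comp.rt - shifts.get(comp.sample_id, 0.0)
            best, best_dot = None, -1.0
            for idx, members in enumerate(clusters):
                if abs(rt - c_rts[idx]) > rt_tol:
                    continue
                if any(m.sample_id == comp.sample_id for m in members):
                    continue
                d = _dot(comp.spectrum, c_specs[idx])
                if d >= min_spectral_dot and d > best_dot:
                    best, best_dot = idx, d
            if best is None:
                clusters.append([comp])
                c_rts.append(rt)
                c_specs.append(dict(comp.spectrum))
            else:
                clusters[best].append(comp)
                mem = clusters[best]
                c_rts[best] = float(
                    np.average(
                        [m.rt - shifts.get(m.sample_id, 0.0) for m in mem],
                        weights=[m.area for m in mem],
                    )
                )
                c_specs[best] = _consensus(mem)
        return clusters

    clusters = cluster({})
    # per-sample systematic shift: median residual against cluster means
    residuals: dict[str, list[float]] = {}
    for members in clusters:
        if len(members) < 2:
            continue
        center = float(np.median([m.rt for m in members]))
        for m in members:
            residuals.setdefault(m.sample_id, []).append(m.rt - center)
    shifts = {s: float(np.median(v)) for s, v in residuals.items() if v}
    if shifts and max(abs(v) for v in shifts.values()) > 1e-4:
        clusters = cluster(shifts)

    aligned: list[AlignedCompound] = []
    clusters.sort(key=lambda mem: float(np.median([m.rt for m in mem])))
    for i, members in enumerate(clusters, start=1):
        aligned.append(
            AlignedCompound(
                aligned_id=f"cmp_{i:04d}",
                rt_consensus=float(np.median([m.rt for m in members])),
                spectrum_consensus=_consensus(members),
                areas={m.sample_id: m.area for m in members},
                segment=members[0].segment,
                members=list(members),
            )
        )
    return aligned


def recover_missing(
    aligned: list[AlignedCompound],
    runs: dict[str, RawRun],
    top_k: int = 3,
    peak_sigma: float = 0.02,
) -> list[AlignedCompound]:
    """Integrate missing compounds' top ions where detection missed them.

    For every sample lacking an aligned compound the EICs of the
    compound's ``top_k`` most intense ions are integrated over the
    consensus RT window (±3 sigma, local background subtracted), scaled
    up by the spectrum weight the top ions carry, and recorded as a
    recovered area.  Existing areas are never altered.
    """
    binned = {s: bin_run(r) for s, r in runs.items()}
    for comp in aligned:
        top = sorted(comp.spectrum_consensus, key=comp.spectrum_consensus.get)[-top_k:]
        w_top = sum(comp.spectrum_consensus[m] for m in top)
        w_all = sum(comp.spectrum_consensus.values())
        scale = w_all / w_top if w_top > 0 else 1.0
        for s in sorted(runs):
            if s in comp.areas:
                continue
            br = binned[s]
            sel = np.abs(br.rts - comp.rt_consensus) <= 3 * peak_sigma
            if not sel.any():
                comp.areas[s] = 0.0
                comp.recovered.add(s)
                continue
            total = 0.0
            for mz in top:
                eic = br.eic(int(mz))[sel]
                background = float(np.median((eic[0], eic[-1])))
                seg = np.clip(eic - background, 0.0, None)
                total += float(np.trapezoid(seg, br.rts[sel]))
            comp.areas[s] = total * scale
            comp.recovered.add(s)
    return aligned
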