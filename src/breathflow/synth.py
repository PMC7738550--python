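"""Synthetic breath-like GC/MS cohorts with known ground truth.

The generator emulates what the downstream stages must cope with: Gaussian
compound elution over a three-ramp temperature program, unit-mass EI
fragment spectra, a flat baseline with additive detector noise, a constant
between-group retention-time shift (the column change), per-sample
injection shifts plus per-compound RT jitter, two ubiquitous sampling-bag
artifacts (N,N-dimethylacetamide and phenol), and alkane / VOC standard
runs.  Every run carries its ground truth so parameter recovery can be
scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import (
    LibraryEntry,
    RawRun,
    Scan,
    SpectralLibrary,
    Subset,
    TemperatureProgram,
)

__all__ = [
    "TrueCompound",
    "CohortDesign",
    "SimulatedCohort",
    "make_library",
    "default_artifacts",
    "alkane_series",
    "alkane_rt",
    "true_retention_index",
    "entries_for",
    "simulate_run",
    "simulate_cohort",
]


@dataclass
class TrueCompound:
    """Ground-truth compound: spectrum, elution position and abundances."""

    name: str
    spectrum: dict[int, float]  # unit m/z -> relative intensity, base peak 1000
    rt_mean: float  # minutes
    peak_sigma: float = 0.02  # minutes
    abundance_by_sample: dict[str, float] = field(default_factory=dict)
    mw: int | None = None
    ri: float | None = None

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        peak = max(self.spectrum.values())
        if abs(peak - 1000.0) > 1e-9:
            self.spectrum = {m: v * 1000.0 / peak for m, v in self.spectrum.items()}


@dataclass
class CohortDesign:
    """Study conditions for one simulated cohort."""

    n_mothers: int = 3
    n_children: int = 3
    n_room_air: int = 2
    groups: dict[str, float] = field(
        default_factory=lambda: {"group1": 0.0, "group2": 0.3}
    )
    noise_sd: float = 30.0
    baseline_level: float = 100.0
    artifact_compounds: list[TrueCompound] | None = None
    include_alkane_ladder: bool = True
    include_voc_standard: bool = True
    alkane_carbons: tuple[int, ...] = tuple(range(7, 13))
    seed: int = 0
    program: TemperatureProgram = field(default_factory=TemperatureProgram)
    scan_interval: float = 0.005  # minutes; ~20 scans across a 0.02 min sigma peak
    mz_range: tuple[int, int] = (38, 450)
    sample_shift_sd: float = 0.03  # minutes, corrected by alignment
    rt_jitter_sd: float = 0.02  # minutes, per compound per sample
    abundance_median: float = 5e4
    abundance_sigma: float = 0.5  # log-normal sigma across samples

    def __post_init__(self) -> None:
        if min(self.n_mothers, self.n_children, self.n_room_air) < 0:
            raise ValueError("sample counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.artifact_compounds is None:
            self.artifact_compounds = default_artifacts(self.program)


@dataclass
class SimulatedCohort:
    runs: list[RawRun] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)  # compound, sample, rt_true, abundance
    compounds: list[TrueCompound] = field(repr=False)
    design: CohortDesign = field(repr=False)


# ---------------------------------------------------------------------------
# ground-truth retention scale

_DEFAULT_PROGRAM = TemperatureProgram()


def alkane_rt(n_carbons: int, program: TemperatureProgram | None = None) -> float:
    """Ground-truth retention time of the n-alkane with ``n_carbons`` carbons.

    Piecewise linear in carbon number — linear spacing within a constant
    ramp, with slope breaks where the program changes ramp — rescaled
    linearly onto non-default programs.  C7 elutes near the end of the
    isothermal hold, C30 near the end of the fast ramp.
    """
    program = program or _DEFAULT_PROGRAM
    rt_default = float(np.interp(n_carbons, [7, 12, 24, 30], [6.0, 16.0, 38.0, 44.5]))
    if program == _DEFAULT_PROGRAM:
        return rt_default
    span = program.end - program.start
    return program.start + (rt_default / _DEFAULT_PROGRAM.end) * span


def true_retention_index(rt: float, program: TemperatureProgram | None = None) -> float:
    """RI of a retention time on the cohort's alkane grid (RI(Cn) = 100 n)."""
    carbons = np.arange(7, 31)
    rts = np.array([alkane_rt(int(n), program) for n in carbons])
    ris = 100.0 * carbons
    if rt <= rts[0]:
        k = 0
    elif rt >= rts[-1]:
        k = len(rts) - 2
    else:
        k = int(np.searchsorted(rts, rt) - 1)
    slope = (ris[k + 1] - ris[k]) / (rts[k + 1] - rts[k])
    return float(ris[k] + slope * (rt - rts[k]))


# ---------------------------------------------------------------------------
# compound construction


def make_library(
    n_compounds: int,
    seed: int,
    mz_range: tuple[int, int] = (38, 450),
    program: TemperatureProgram | None = None,
) -> tuple[SpectralLibrary, list[TrueCompound]]:
    """Generate ``n_compounds`` random EI-like compounds plus their library.

    Each compound has 5-25 fragment ions inside ``mz_range``, a base peak
    of 1000, its molecular ion recorded as the molecular weight, and a
    ground-truth RI on the cohort's alkane grid.  Deterministic for a
    fixed seed.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    program = program or _DEFAULT_PROGRAM
    lo, hi = int(mz_range[0]), int(mz_range[1])
    if hi < lo:
        raise ValueError("mz_range must be ordered")
    rng = np.random.default_rng(seed)
    compounds: list[TrueCompound] = []
    boundaries = [b for (_, b) in program.segments[:-1]]
    rt_lo = program.start + 0.04 * (program.end - program.start)
    rt_hi = program.end - 0.03 * (program.end - program.start)
    for i in range(n_compounds):
        n_frag = int(rng.integers(5, 26))
        pool = np.arange(lo, hi + 1)
        n_frag = min(n_frag, len(pool))
        frags = rng.choice(pool, size=n_frag, replace=False)
        rels = rng.uniform(20.0, 1000.0, size=n_frag)
        rels[int(rng.integers(n_frag))] = 1000.0
        spectrum = dict(zip((int(m) for m in frags), (float(r) for r in rels)))
        mol_ion = int(frags.max())
        if spectrum[mol_ion] < 50.0:  # molecular ion visible but can be minor
            spectrum[mol_ion] = float(rng.uniform(50.0, 300.0))
        # keep elution clear of segment boundaries so a peak sits in one ramp
        while True:
            rt = float(rng.uniform(rt_lo, rt_hi))
            if all(abs(rt - b) > 0.3 for b in boundaries):
                break
        compounds.append(
            TrueCompound(
                name=f"compound_{i:03d}",
                spectrum=spectrum,
                rt_mean=rt,
                mw=mol_ion,
                ri=true_retention_index(rt, program),
            )
        )
    return SpectralLibrary(entries_for(compounds)), compounds


def default_artifacts(program: TemperatureProgram | None = None) -> list[TrueCompound]:
    """The two ubiquitous Tedlar-bag contaminants planted in every sample."""
    program = program or _DEFAULT_PROGRAM
    span = program.end - program.start

    def pos(frac: float) -> float:
        return program.start + frac * span

    dma = TrueCompound(
        name="N,N-dimethylacetamide",
        spectrum={44: 1000.0, 43: 450.0, 87: 350.0, 72: 300.0, 42: 200.0, 45: 60.0},
        rt_mean=pos(0.18),
        mw=87,
    )
    phenol = TrueCompound(
        name="phenol",
        spectrum={94: 1000.0, 66: 250.0, 65: 200.0, 39: 180.0, 40: 90.0, 55: 60.0},
        rt_mean=pos(0.45),
        mw=94,
    )
    for c in (dma, phenol):
        c.ri = true_retention_index(c.rt_mean, program)
    return [dma, phenol]


def alkane_series(
    carbons=range(7, 31), program: TemperatureProgram | None = None
) -> list[TrueCompound]:
    """n-alkane compounds (CnH2n+2) with typical hydrocarbon EI spectra.

    The molecular ion (m/z 14n+2) is present at low relative intensity —
    it must be, for the molecular-ion filter of the alkane-anchoring
    procedure to have something to find.
    """
    program = program or _DEFAULT_PROGRAM
    out = []
    for n in carbons:
        mw = 14 * n + 2
        spectrum: dict[int, float] = {43: 1000.0, 57: 900.0, 41: 400.0, 55: 220.0}
        rel = 600.0
        mz = 71
        while mz <= mw - 15:
            spectrum[mz] = rel
            rel *= 0.55
            mz += 14
        spectrum[mw] = 60.0  # molecular ion
        out.append(
            TrueCompound(
                name=f"n-alkane C{n:02d}",
                spectrum=spectrum,
                rt_mean=alkane_rt(n, program),
                mw=mw,
                ri=100.0 * n,
            )
        )
    return out


def entries_for(compounds: list[TrueCompound]) -> list[LibraryEntry]:
    return [
        LibraryEntry(
            name=c.name,
            spectrum=dict(c.spectrum),
            retention_index=c.ri,
            molecular_weight=c.mw,
        )
        for c in compounds
    ]


# ---------------------------------------------------------------------------
# simulation


def _sample_rng(design: CohortDesign, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([design.seed, zlib.crc32(sample_id.encode())])


def simulate_run(
    compounds: list[TrueCompound],
    design: CohortDesign,
    sample_id: str,
    group_id: str,
    subset: Subset | str,
    sample_shift: float = 0.0,
    jitter_sd: float | None = None,
) -> RawRun:
    """Simulate one profile-mode run.

    Each compound contributes ``abundance * rel/1000 * Gaussian(rt)`` to
    its fragment EICs; the apex sits at ``rt_mean + group shift +
    sample shift + per-compound jitter``.  Baseline and truncated additive
    noise go on top.  The run keeps its ground truth in ``run.truth``.
    """
    subset = Subset(subset)
    rng = _sample_rng(design, sample_id)
    group_shift = design.groups.get(group_id, 0.0)
    jitter_sd = design.rt_jitter_sd if jitter_sd is None else jitter_sd

    program = design.program
    n_scans = int(round((program.end - program.start) / design.scan_interval))
    rts = program.start + design.scan_interval * np.arange(n_scans, dtype=float)
    lo, hi = design.mz_range
    mz_bins = np.arange(int(lo), int(hi) + 1)
    matrix = np.zeros((n_scans, len(mz_bins)))

    truth_rows = []
    for comp in compounds:
        abundance = comp.abundance_by_sample.get(sample_id, design.abundance_median)
        jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        apex = comp.rt_mean + group_shift + sample_shift + jitter
        sigma = comp.peak_sigma
        i0 = int(np.searchsorted(rts, apex - 5 * sigma))
        i1 = int(np.searchsorted(rts, apex + 5 * sigma))
        if i1 <= i0:
            continue
        profile = abundance * np.exp(-((rts[i0:i1] - apex) ** 2) / (2 * sigma**2))
        mzs = np.array([m for m in comp.spectrum if lo <= m <= hi], dtype=int)
        if len(mzs) == 0:
            continue
        rels = np.array([comp.spectrum[m] for m in mzs]) / 1000.0
        matrix[i0:i1, mzs - int(lo)] += np.outer(profile, rels)
        truth_rows.append(
            {
                "compound": comp.name,
                "sample_id": sample_id,
                "group_id": group_id,
                "subset": subset.value,
                "rt_true": apex,
                "abundance": abundance,
            }
        )

    matrix += design.baseline_level
    if design.noise_sd > 0:
        matrix += rng.normal(0.0, design.noise_sd, size=matrix.shape)
    np.clip(matrix, 0.0, None, out=matrix)

    mz_vals = mz_bins.astype(float)
    scans = [Scan(float(rt), mz_vals, matrix[i]) for i, rt in enumerate(rts)]
    run = RawRun(sample_id, group_id, subset, scans, program)
    run._dense = (rts, mz_bins, matrix)  # fast path for eic.bin_run
    run.truth = pd.DataFrame(
        truth_rows,
        columns=["compound", "sample_id", "group_id", "subset", "rt_true", "abundance"],
    )
    return run


def simulate_cohort(
    design: CohortDesign, compounds: list[TrueCompound]
) -> SimulatedCohort:
    """Simulate a full cohort with partially overlapping per-subset panels.

    Mothers, children and room air share the ubiquitous artifacts; the
    mother panel additionally carries the alkane series (breath alkanes
    anchor the RI scale); each group gets an alkane-ladder standard run
    and, optionally, a VOC standard.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng([design.seed, 0x5EED])
    artifacts = list(design.artifact_compounds or [])
    alkanes = (
        alkane_series(design.alkane_carbons, design.program)
        if design.alkane_carbons
        else []
    )
    n = len(compounds)
    mother_panel = compounds[: max(1, int(np.ceil(0.7 * n)))] if n else []
    child_panel = compounds[int(np.floor(0.3 * n)) :] if n else []
    room_panel = compounds[int(np.floor(0.5 * n)) :] if n else []

    runs: list[RawRun] = []
    all_compounds = {id(c): c for c in compounds + artifacts + alkanes}

    def add_run(panel, sample_id, group_id, subset):
        shift = (
            rng.normal(0.0, design.sample_shift_sd)
            if design.sample_shift_sd > 0 and subset != Subset.STANDARD
            else 0.0
        )
        for comp in panel:
            log_mu = np.log(design.abundance_median)
            comp.abundance_by_sample[sample_id] = float(
                np.exp(rng.normal(log_mu, design.abundance_sigma))
            )
        jitter_sd = 0.0 if subset == Subset.STANDARD else None
        runs.append(
            simulate_run(
                panel, design, sample_id, group_id, subset, shift, jitter_sd
            )
        )

    for group_id in design.groups:
        for i in range(design.n_mothers):
            add_run(
                mother_panel + artifacts + alkanes,
                f"{group_id}_mother{i + 1}",
                group_id,
                Subset.MOTHER,
            )
        for i in range(design.n_children):
            add_run(
                child_panel + artifacts,
                f"{group_id}_child{i + 1}",
                group_id,
                Subset.CHILD,
            )
        for i in range(design.n_room_air):
            add_run(
                room_panel + artifacts,
                f"{group_id}_room{i + 1}",
                group_id,
                Subset.ROOM_AIR,
            )
        if design.include_alkane_ladder and alkanes:
            add_run(alkanes, f"{group_id}_alkane_ladder", group_id, Subset.STANDARD)
        if design.include_voc_standard and compounds:
            add_run(
                compounds[: min(8, n)],
                f"{group_id}_voc_standard",
                group_id,
                Subset.STANDARD,
            )

    truth = (
        pd.concat([r.truth for r in runs], ignore_index=True)
        if runs
        else pd.DataFrame(
            columns=[
                "compound",
                "sample_id",
                "group_id",
                "subset",
                "rt_true",
                "abundance",
            ]
        )
    )
    return SimulatedCohort(
        runs=runs,
        truth=truth,
        compounds=list(all_compounds.values()),
        design=design,
    )
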