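"""Workflow orchestration: raw runs -> filtered, normalized, identified.

Each (group, subset) unit of breath samples is preprocessed separately —
the two routes never see samples of another subset — then the routes are
merged, duplicates reported, the filtered matrix normalized and the
filtered compounds identified.  Retention-index anchors come either from
a user CSV or from the alkane-anchoring procedure run on the group's
mother samples ("auto-alkane").
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cliques as cq
from . import deconv as dc
from . import identify as idf
from . import merge as mg
from . import peakpick as pp
from .errors import AnchorError, ConfigError
from .msio import (
    RawRun,
    SpectralLibrary,
    Subset,
    TemperatureProgram,
    read_msp_library,
    read_raw_run,
    write_feature_matrix,
)
from .synth import (
    CohortDesign,
    SimulatedCohort,
    alkane_series,
    entries_for,
    make_library,
    simulate_cohort,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "demo", "demo_cohort"]


@dataclass
class PipelineConfig:
    """Everything the workflow needs, with the documented defaults."""

    samples: list[dict] = field(default_factory=list)  # path/sample_id/group/subset
    library_path: str | None = None
    anchors: str | None = "auto-alkane"  # path to CSV, "auto-alkane", or None
    outdir: str = "breathflow_out"
    seed: int = 0
    identification: bool = True
    program: list | None = None  # ramp segments [[start, end], ...]; None = default
    # peak picking
    smooth_window: int = 5
    baseline_quantile: float = 0.25
    fwhm: float = pp.DEFAULT_FWHM
    snr_threshold: float = pp.DEFAULT_SNR
    rt_bw: float = pp.DEFAULT_RT_BW
    minfrac: float = pp.DEFAULT_MINFRAC
    mz_range: tuple[int, int] | None = None
    # cliques
    clique_rt_tol: float = cq.DEFAULT_RT_TOL
    min_cosine: float = cq.DEFAULT_MIN_COSINE
    # deconvolution
    noise_threshold: float = 200.0
    peak_sigma: float = 0.02
    min_ions: int = dc.DEFAULT_MIN_IONS
    corr_gate: float = dc.DEFAULT_CORR_GATE
    align_rt_tol: float = dc.DEFAULT_RT_TOL
    align_min_dot: float = dc.DEFAULT_ALIGN_DOT
    # merge
    dot_threshold: float = mg.DOT_FILTER
    dup_dot: float = mg.DOT_DUPLICATE
    dup_rt_tol: float = mg.RT_TOL
    dup_pearson: float = mg.PEARSON_MIN
    feature_ion_rt_tol: float = mg.RT_TOL
    vector_mz_lo: int = mg.MZ_LO
    vector_mz_hi: int = mg.MZ_HI
    normalization_mode: str = "sum"
    # identification
    mf_floor: float = idf.MF_FLOOR
    mf_window: float = idf.MF_WINDOW
    entry_cap: int = idf.ENTRY_CAP
    ri_error_max: float = idf.RI_ERROR_MAX
    alkane_mf_floor: float = idf.ALKANE_MF_FLOOR
    alkane_mf_window: float = idf.ALKANE_MF_WINDOW
    alkane_name_pattern: str = r"(?i)alkane"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self, have_library: bool = False) -> None:
        for s in self.samples:
            p = Path(s["path"])
            if not p.exists():
                raise ConfigError(f"input file does not exist: {p}")
        if self.identification and not self.library_path and not have_library:
            raise ConfigError("identification enabled but no library path given")
        if self.library_path and not Path(self.library_path).exists():
            raise ConfigError(f"library does not exist: {self.library_path}")
        for name, lo, hi in [
            ("dot_threshold", 0, 1),
            ("dup_dot", 0, 1),
            ("dup_pearson", -1, 1),
            ("min_cosine", 0, 1),
            ("corr_gate", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class UnitResult:
    """Products of one (group, subset) preprocessing unit."""

    group_id: str
    subset: str
    matrix: pp.FeatureMatrix = field(repr=False)
    feature_groups: list[pp.FeatureGroup] = field(repr=False)
    clique_compounds: list[cq.CliqueCompound] = field(repr=False)
    clique_spectra: dict[str, dict[int, float]] = field(repr=False)
    aligned_compounds: list[dc.AlignedCompound] = field(repr=False)
    filtered: mg.FilteredSet = field(repr=False)
    match_results: list[mg.MatchResult] = field(repr=False)
    duplicates: dict[str, list[mg.DuplicatePair]] = field(repr=False)
    dup_percent: dict[str, float] = field(repr=False)
    normalized: pd.DataFrame = field(repr=False)
    identifications: list[idf.Identification] = field(repr=False)


@dataclass
class PipelineResult:
    units: list[UnitResult] = field(repr=False)
    anchors: dict[str, list[idf.RIAnchor]] = field(repr=False)
    summary: dict = field(repr=False)
    outdir: Path = field(default=None)


# ---------------------------------------------------------------------------


def _dup_percent(records, pairs) -> float:
    if not records:
        return 0.0
    flagged = {p.id_a for p in pairs} | {p.id_b for p in pairs}
    return 100.0 * len(flagged) / len(records)


def _process_unit(
    cfg: PipelineConfig,
    group_id: str,
    subset: str,
    runs: dict[str, RawRun],
    library: SpectralLibrary | None,
    anchors: list[idf.RIAnchor] | None,
) -> tuple[UnitResult, dict]:
    t0 = time.perf_counter()
    # --- route 1, steps 1-4 ---------------------------------------------
    prepared = {
        s: pp.smooth_and_baseline(r, cfg.smooth_window, cfg.baseline_quantile)
        for s, r in runs.items()
    }
    raw_features = {
        s: pp.detect_peaks(r, cfg.fwhm, cfg.snr_threshold, cfg.mz_range)
        for s, r in prepared.items()
    }
    aligned_features, warps = pp.align_retention_times(raw_features, cfg.fwhm)
    groups = pp.group_features(aligned_features, cfg.rt_bw, cfg.minfrac)
    matrix = pp.fill_missing(groups, prepared, warps)

    # --- route 1, clique grouping (per sample, on unaligned features) ----
    feature_to_group = {
        f.feature_id: g.group_feature_id for g in groups for f in g.members.values()
    }
    groups_by_id = {g.group_feature_id: g for g in groups}
    clique_compounds = cq.annotate_all_samples(
        raw_features,
        prepared,
        feature_to_group,
        groups_by_id,
        cfg.clique_rt_tol,
        cfg.min_cosine,
    )
    clique_spectra: dict[str, dict[int, float]] = {}
    clique_rts: dict[str, float] = {}
    clique_magnitude: dict[str, float] = {}
    for cc in clique_compounds:
        rel = mg.relative_intensities(cc, matrix)
        spectrum: dict[int, float] = {}
        for g in cc.member_groups:
            ri = rel.get(g.group_feature_id, 0.0)
            spectrum[g.mz] = max(spectrum.get(g.mz, 0.0), ri)
        clique_spectra[cc.clique_id] = spectrum
        clique_rts[cc.clique_id] = cc.rt
        clique_magnitude[cc.clique_id] = float(
            sum(
                matrix.values.loc[g.group_feature_id].mean()
                for g in cc.member_groups
            )
        )

    # --- route 2 ----------------------------------------------------------
    per_sample: dict[str, list[dc.DeconvCompound]] = {}
    for s, r in runs.items():
        segs = r.ramp_program.segments
        boundaries = (segs[0][1], segs[1][1]) if len(segs) >= 3 else None
        subs = dc.segment_run(r, boundaries) if boundaries else [r]
        comps: list[dc.DeconvCompound] = []
        for sub in subs:
            comps.extend(
                dc.deconvolve(
                    sub,
                    cfg.noise_threshold,
                    cfg.peak_sigma,
                    cfg.min_ions,
                    cfg.corr_gate,
                )
            )
        per_sample[s] = comps
    aligned = dc.align_compounds(per_sample, cfg.align_rt_tol, cfg.align_min_dot)
    aligned = dc.recover_missing(aligned, runs, peak_sigma=cfg.peak_sigma)

    # --- merge ------------------------------------------------------------
    filtered, results = mg.match_compounds(
        clique_spectra,
        clique_rts,
        aligned,
        groups,
        cfg.dot_threshold,
        cfg.feature_ion_rt_tol,
        cfg.vector_mz_lo,
        cfg.vector_mz_hi,
    )
    clique_records = [
        mg.DupRecord(cid, clique_rts[cid], clique_spectra[cid],
                     magnitude=clique_magnitude[cid])
        for cid in sorted(clique_spectra)
    ]
    deconv_records = [
        mg.DupRecord(a.aligned_id, a.rt_consensus, a.spectrum_consensus, a.areas)
        for a in aligned
    ]
    filtered_records = [
        r for r in deconv_records if r.id in set(filtered.filtered_compounds)
    ]
    kw = dict(
        dot_min=cfg.dup_dot,
        rt_tol=cfg.dup_rt_tol,
        pearson_min=cfg.dup_pearson,
        mz_lo=cfg.vector_mz_lo,
        mz_hi=cfg.vector_mz_hi,
    )
    dup_clique, _ = mg.detect_duplicates(clique_records, **kw)
    dup_deconv, _ = mg.detect_duplicates(deconv_records, **kw)
    dup_filtered, _ = mg.detect_duplicates(filtered_records, **kw)
    duplicates = {
        "clique": dup_clique,
        "deconv": dup_deconv,
        "filtered": dup_filtered,
    }
    dup_percent = {
        "clique": _dup_percent(clique_records, dup_clique),
        "deconv": _dup_percent(deconv_records, dup_deconv),
        "filtered": _dup_percent(filtered_records, dup_filtered),
    }

    if filtered.filtered_features:
        normalized = mg.normalize_matrix(
            matrix.values.loc[filtered.filtered_features],
            mode=cfg.normalization_mode,
        )
    else:
        normalized = pd.DataFrame(columns=matrix.columns)

    # --- identification ----------------------------------------------------
    identifications: list[idf.Identification] = []
    if cfg.identification and library is not None:
        by_id = {a.aligned_id: a for a in aligned}
        for aid in filtered.filtered_compounds:
            comp = by_id[aid]
            cands = idf.candidate_entries(
                comp.spectrum_consensus,
                library,
                cfg.mf_floor,
                cfg.mf_window,
                cfg.entry_cap,
            )
            ri_query = None
            if anchors:
                ri_query = idf.compute_ri(comp.rt_consensus, anchors)
            identifications.append(
                idf.select_best(cands, ri_query, cfg.ri_error_max, aligned_id=aid)
            )

    elapsed = time.perf_counter() - t0
    n_raw_features = sum(len(v) for v in raw_features.values())
    counts = {
        "n_samples": len(runs),
        "n_features": n_raw_features,
        "n_feature_groups": len(groups),
        "n_clique_compounds": len(clique_compounds),
        "n_deconv_compounds": len(aligned),
        "n_filtered_features": len(filtered.filtered_features),
        "n_filtered_compounds": len(filtered.filtered_compounds),
        "n_identified": sum(1 for i in identifications if i),
        "duplicate_percent": dup_percent,
    }
    log.info(
        "unit %s/%s: %d samples in %.1f s (%.1f s/sample)",
        group_id,
        subset,
        len(runs),
        elapsed,
        elapsed / max(1, len(runs)),
    )
    unit = UnitResult(
        group_id,
        subset,
        matrix,
        groups,
        clique_compounds,
        clique_spectra,
        aligned,
        filtered,
        results,
        duplicates,
        dup_percent,
        normalized,
        identifications,
    )
    return unit, counts


def _auto_anchors(
    cfg: PipelineConfig,
    group_id: str,
    units: dict[tuple[str, str], dict[str, RawRun]],
    library: SpectralLibrary,
) -> list[idf.RIAnchor] | None:
    """Alkane anchors from the group's mother samples (second route)."""
    mothers = units.get((group_id, Subset.MOTHER.value))
    if not mothers:
        log.warning("%s: no mother samples; RI anchors unavailable", group_id)
        return None
    pattern = re.compile(cfg.alkane_name_pattern)
    alkane_entries = [e for e in library.entries if pattern.search(e.name)]
    if not alkane_entries:
        log.warning("%s: no alkane entries in library", group_id)
        return None
    compounds: list[dc.DeconvCompound] = []
    features: dict[str, list[pp.Feature]] = {}
    for s, r in mothers.items():
        prepared = pp.smooth_and_baseline(r, cfg.smooth_window, cfg.baseline_quantile)
        features[s] = pp.detect_peaks(prepared, cfg.fwhm, cfg.snr_threshold,
                                      cfg.mz_range)
        segs = r.ramp_program.segments
        boundaries = (segs[0][1], segs[1][1]) if len(segs) >= 3 else None
        subs = dc.segment_run(r, boundaries) if boundaries else [r]
        for sub in subs:
            compounds.extend(
                dc.deconvolve(sub, cfg.noise_threshold, cfg.peak_sigma,
                              cfg.min_ions, cfg.corr_gate)
            )
    try:
        anchors, diag = idf.anchor_alkanes(
            compounds,
            features,
            alkane_entries,
            cfg.alkane_mf_floor,
            cfg.alkane_mf_window,
            cfg.feature_ion_rt_tol,
        )
    except AnchorError as exc:
        log.warning("%s: %s", group_id, exc)
        return None
    log.info("%s: %d alkane anchors (%s)", group_id, len(anchors), diag)
    return anchors


def _load_anchor_csv(path: str | Path) -> list[idf.RIAnchor]:
    df = pd.read_csv(path)
    return [
        idf.RIAnchor(str(r["label"]), float(r["rt"]), float(r["ri"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------


def run_pipeline(
    cfg: PipelineConfig,
    runs: list[RawRun] | None = None,
    library: SpectralLibrary | None = None,
) -> PipelineResult:
    """Execute the full workflow and write all tabular outputs.

    ``runs``/``library`` may be passed in memory (the demo does); when
    absent they are read from the paths in the configuration.  Outputs
    are deterministic for a fixed configuration and inputs.
    """
    cfg.validate(have_library=library is not None)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("breathflow")
    root.addHandler(fh)
    try:
        if runs is None:
            prog = (
                TemperatureProgram(tuple(map(tuple, cfg.program)))
                if cfg.program
                else None
            )
            runs = [
                read_raw_run(
                    s["path"],
                    s["sample_id"],
                    s.get("group", "group1"),
                    s.get("subset", "mother"),
                    ramp_program=prog,
                )
                for s in cfg.samples
            ]
        if library is None and cfg.library_path:
            library = read_msp_library(cfg.library_path)

        units: dict[tuple[str, str], dict[str, RawRun]] = {}
        for r in runs:
            if r.subset == Subset.STANDARD:
                continue  # standards feed diagnostics, not the breath units
            units.setdefault((r.group_id, r.subset.value), {})[r.sample_id] = r

        anchors_by_group: dict[str, list[idf.RIAnchor]] = {}
        if cfg.identification and library is not None:
            for group_id in sorted({g for g, _ in units}):
                if cfg.anchors == "auto-alkane":
                    a = _auto_anchors(cfg, group_id, units, library)
                elif cfg.anchors:
                    a = _load_anchor_csv(cfg.anchors)
                else:
                    a = None
                if a:
                    anchors_by_group[group_id] = a

        results: list[UnitResult] = []
        summary: dict = {"units": {}, "totals": {}}
        for (group_id, subset) in sorted(units):
            unit_runs = units[(group_id, subset)]
            try:
                unit, counts = _process_unit(
                    cfg,
                    group_id,
                    subset,
                    unit_runs,
                    library,
                    anchors_by_group.get(group_id),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage failure in unit {group_id}/{subset} "
                    f"(samples {sorted(unit_runs)}): {exc}"
                ) from exc
            results.append(unit)
            summary["units"][f"{group_id}/{subset}"] = counts
            _write_unit(outdir, unit)

        for key in (
            "n_features",
            "n_feature_groups",
            "n_clique_compounds",
            "n_deconv_compounds",
            "n_filtered_features",
            "n_filtered_compounds",
            "n_identified",
        ):
            summary["totals"][key] = sum(
                u[key] for u in summary["units"].values()
            )
        summary["anchors"] = {
            g: [{"label": a.label, "rt": round(a.rt, 4), "ri": a.ri} for a in ans]
            for g, ans in anchors_by_group.items()
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        for g, ans in anchors_by_group.items():
            pd.DataFrame(
                [{"label": a.label, "rt": a.rt, "ri": a.ri} for a in ans]
            ).to_csv(outdir / f"{g}_anchors.csv", index=False)
        return PipelineResult(results, anchors_by_group, summary, outdir)
    finally:
        root.removeHandler(fh)
        fh.close()


def _write_unit(outdir: Path, unit: UnitResult) -> None:
    prefix = f"{unit.group_id}_{unit.subset}"
    write_feature_matrix(unit.matrix, outdir / f"{prefix}_feature_matrix.csv")
    pd.DataFrame(
        [
            {
                "clique_id": cc.clique_id,
                "rt": cc.rt,
                "support": cc.support,
                "member_features": ";".join(
                    g.group_feature_id for g in cc.member_groups
                ),
            }
            for cc in unit.clique_compounds
        ]
    ).to_csv(outdir / f"{prefix}_cliques.csv", index=False)
    pd.DataFrame(
        [
            {
                "aligned_id": a.aligned_id,
                "rt": a.rt_consensus,
                "segment": a.segment,
                "spectrum": ";".join(
                    f"{mz}:{a.spectrum_consensus[mz]:.0f}"
                    for mz in sorted(a.spectrum_consensus)
                ),
                "n_samples": len(a.areas),
                "n_recovered": len(a.recovered),
                "total_area": sum(a.areas.values()),
            }
            for a in unit.aligned_compounds
        ]
    ).to_csv(outdir / f"{prefix}_compounds.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        [
            {
                "clique_id": r.clique_id,
                "aligned_id": r.aligned_id,
                "dot": round(r.dot, 6),
                "is_best_for_clique": r.is_best_for_clique,
            }
            for r in unit.match_results
        ]
    ).to_csv(outdir / f"{prefix}_match_results.csv", index=False)
    unit.normalized.round(4).to_csv(
        outdir / f"{prefix}_filtered_normalized_matrix.csv"
    )
    rows = []
    for side, pairs in unit.duplicates.items():
        for p in pairs:
            rows.append(
                {
                    "side": side,
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "dot": round(p.dot, 4),
                    "delta_rt": round(p.delta_rt, 4),
                    "area_pearson": None
                    if p.area_pearson is None
                    else round(p.area_pearson, 4),
                }
            )
    pd.DataFrame(
        rows, columns=["side", "id_a", "id_b", "dot", "delta_rt", "area_pearson"]
    ).to_csv(outdir / f"{prefix}_duplicates.csv", index=False)
    pd.DataFrame(
        [
            {
                "aligned_id": i.aligned_id,
                "entry": i.entry_name,
                "match_factor": round(i.match_factor, 2),
                "ri": None if i.ri_query is None else round(i.ri_query, 1),
                "ri_error": None if i.ri_error is None else round(i.ri_error, 2),
                "rank_basis": i.rank_basis.value,
            }
            for i in unit.identifications
        ],
        columns=["aligned_id", "entry", "match_factor", "ri", "ri_error",
                 "rank_basis"],
    ).to_csv(outdir / f"{prefix}_identifications.csv", index=False)


# ---------------------------------------------------------------------------


def demo_cohort(
    seed: int, n_compounds: int = 20, n_decoys: int = 10
) -> tuple[SimulatedCohort, SpectralLibrary]:
    """The demonstration cohort: 2 groups x {3 mothers, 3 children, 2 room
    air} plus standards, 20 planted compounds, 2 ubiquitous artifacts, a
    C7-C12 alkane ladder, and a library with extra decoy entries."""
    design = CohortDesign(seed=seed)
    lib, compounds = make_library(n_compounds, seed)
    decoy_lib, _ = make_library(n_decoys, seed + 7919)
    decoys = []
    for i, e in enumerate(decoy_lib.entries):
        e.name = f"decoy_{i:03d}"
        decoys.append(e)
    entries = (
        lib.entries
        + entries_for(design.artifact_compounds)
        + entries_for(alkane_series(design.alkane_carbons, design.program))
        + decoys
    )
    cohort = simulate_cohort(design, compounds)
    return cohort, SpectralLibrary(entries)


def demo(seed: int = 1, outdir: str | Path = "breathflow_demo") -> PipelineResult:
    """Run the full workflow on a freshly simulated cohort."""
    cohort, library = demo_cohort(seed)
    cfg = PipelineConfig(outdir=str(outdir), seed=seed)
    result = run_pipeline(cfg, runs=cohort.runs, library=library)
    result.cohort = cohort
    return result
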