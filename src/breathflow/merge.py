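"""Connecting the two preprocessing routes.

Features from the peak-picking route are matched to the ions of
deconvolved compounds (same unit m/z, RT within ±0.05 min), each clique
compound gets a relative-intensity spectrum from the feature matrix,
spectra are embedded as fixed 412-position vectors over m/z 38-450 and
compared by dot product.  Deconvolved compounds that are the best match
(dot > 0.7) for some clique compound become the filtered compounds; the
features matched to them become the filtered features.  Duplicates are
flagged (dot > 0.8, RT ±0.05 min, and — on the deconvolution side —
area correlation > 0.75) and the final matrix is log-normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cliques import CliqueCompound
from .peakpick import FeatureGroup, FeatureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SpectrumVector",
    "MatchResult",
    "FilteredSet",
    "DuplicatePair",
    "match_features_to_ions",
    "relative_intensities",
    "vectorize",
    "spectral_dot",
    "match_compounds",
    "detect_duplicates",
    "normalize_matrix",
]

MZ_LO = 38
MZ_HI = 450  # half-open: positions cover [38, 450) -> 412 positions
DOT_FILTER = 0.7
DOT_DUPLICATE = 0.8
RT_TOL = 0.05
PEARSON_MIN = 0.75
# numerical guard so decision boundaries behave as printed despite float noise
EPS = 1e-9


@dataclass
class SpectrumVector:
    """Fixed-length unit-norm embedding of a unit-mass spectrum."""

    values: np.ndarray
    mz_lo: int = MZ_LO
    mz_hi: int = MZ_HI
    normalized: bool = True
    empty: bool = False  # all-zero input spectrum

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MatchResult:
    clique_id: str
    aligned_id: str
    dot: float
    is_best_for_clique: bool = False


@dataclass
class FilteredSet:
    filtered_compounds: list[str]
    filtered_features: list[str]
    feature_to_compound: dict[str, list[str]]


@dataclass
class DuplicatePair:
    id_a: str
    id_b: str
    dot: float
    delta_rt: float
    area_pearson: float | None = None


# ---------------------------------------------------------------------------


def match_features_to_ions(
    feature_groups: Sequence[FeatureGroup],
    compound_rt: float,
    compound_spectrum: Mapping[int, float],
    rt_tol: float = RT_TOL,
) -> list[tuple[str, int]]:
    """Match feature groups to the ions of one deconvolved compound.

    A feature and an ion are the same signal iff they share the unit m/z
    and the feature's median RT is within ``rt_tol`` of the compound RT.
    Within the compound each ion takes at most one feature — the nearest
    RT wins.
    """
    pairs: list[tuple[str, int]] = []
    for mz in sorted(compound_spectrum):
        best: FeatureGroup | None = None
        for g in feature_groups:
            if g.mz != mz or abs(g.rt_median - compound_rt) > rt_tol + EPS:
                continue
            if best is None or abs(g.rt_median - compound_rt) < abs(
                best.rt_median - compound_rt
            ):
                best = g
        if best is not None:
            pairs.append((best.group_feature_id, mz))
    return pairs


def relative_intensities(
    clique: CliqueCompound, matrix: FeatureMatrix
) -> dict[str, float]:
    """Three-step relative-intensity protocol for one clique compound.

    1) average each member feature's intensity across all samples,
    2) assign 1000 to the feature with the highest average (base peak),
    3) scale the rest as (average / base average) * 1000.
    Ties for the base peak all receive 1000 (the formula applied
    verbatim); a zero-average member is floored at 0 and logged.
    """
    averages = {
        g.group_feature_id: float(matrix.values.loc[g.group_feature_id].mean())
        for g in clique.member_groups
    }
    base = max(averages.values())
    if base <= 0:
        log.warning("clique %s has no positive average intensity", clique.clique_id)
        return {k: 0.0 for k in averages}
    out = {}
    for k, v in averages.items():
        if v <= 0:
            log.warning("feature %s has zero average intensity; floored to 0", k)
            out[k] = 0.0
        else:
            out[k] = v / base * 1000.0
    return out


def vectorize(
    spectrum: Mapping[int, float], mz_lo: int = MZ_LO, mz_hi: int = MZ_HI
) -> SpectrumVector:
    """Embed a unit-mass spectrum on the fixed comparison grid.

    Positions cover the half-open integer range [mz_lo, mz_hi) — 412
    positions for the default 38-450 bounds.  In-range intensities are
    copied, out-of-range keys dropped with a warning, absent positions
    are 0, and the vector is scaled to unit Euclidean norm (an all-zero
    spectrum stays all-zero and is flagged).
    """
    if mz_lo >= mz_hi:
        raise ValueError("mz_lo must be < mz_hi")
    values = np.zeros(mz_hi - mz_lo)
    for mz, inten in spectrum.items():
        mz = int(mz)
        if mz_lo <= mz < mz_hi:
            values[mz - mz_lo] += float(inten)
        else:
            log.warning("m/z %d outside comparison range [%d, %d)", mz, mz_lo, mz_hi)
    norm = float(np.linalg.norm(values))
    if norm == 0:
        return SpectrumVector(values, mz_lo, mz_hi, normalized=True, empty=True)
    return SpectrumVector(values / norm, mz_lo, mz_hi)


def spectral_dot(a: SpectrumVector, b: SpectrumVector) -> float:
    """Dot product of two unit-norm spectrum vectors — a value in [0, 1]."""
    if (a.mz_lo, a.mz_hi) != (b.mz_lo, b.mz_hi):
        raise ValueError("spectrum vectors cover different m/z ranges")
    return float(min(1.0, np.dot(a.values, b.values)))


# ---------------------------------------------------------------------------


def match_compounds(
    clique_spectra: Mapping[str, Mapping[int, float]],
    clique_rts: Mapping[str, float],
    aligned_compounds: Sequence,
    feature_groups: Sequence[FeatureGroup] = (),
    dot_threshold: float = DOT_FILTER,
    rt_tol: float = RT_TOL,
    mz_lo: int = MZ_LO,
    mz_hi: int = MZ_HI,
) -> tuple[FilteredSet, list[MatchResult]]:
    """Compare every clique compound with every deconvolved compound.

    For each clique compound the arg-max dot product marks the best
    deconvolved compound (ties broken by smaller |ΔRT|, then id).
    Filtered compounds are those that are best for at least one clique
    with dot strictly greater than ``dot_threshold``; filtered features
    are the features previously matched to any filtered compound.
    """
    if not clique_spectra or not len(aligned_compounds):
        log.warning("match_compounds called with an empty compound list")
        return FilteredSet([], [], {}), []

    vec_cliques = {
        cid: vectorize(spec, mz_lo, mz_hi) for cid, spec in clique_spectra.items()
    }
    vec_deconv = [
        (c.aligned_id, c.rt_consensus, vectorize(c.spectrum_consensus, mz_lo, mz_hi))
        for c in aligned_compounds
    ]

    results: list[MatchResult] = []
    best_ids: dict[str, tuple[str, float]] = {}  # clique -> (aligned_id, dot)
    for cid in sorted(vec_cliques):
        vc = vec_cliques[cid]
        crt = clique_rts.get(cid, math.nan)
        scored = []
        for aid, art, va in vec_deconv:
            d = spectral_dot(vc, va)
            scored.append((d, abs(crt - art) if not math.isnan(crt) else 0.0, aid))
            results.append(MatchResult(cid, aid, d))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        best_dot, _, best_aid = scored[0]
        best_ids[cid] = (best_aid, best_dot)
        for r in results:
            if r.clique_id == cid and r.aligned_id == best_aid:
                r.is_best_for_clique = True
                break

    filtered = sorted(
        {aid for aid, d in best_ids.values() if d > dot_threshold + EPS}
    )

    feature_to_compound: dict[str, list[str]] = {}
    by_id = {c.aligned_id: c for c in aligned_compounds}
    for aid in filtered:
        comp = by_id[aid]
        for gid, _mz in match_features_to_ions(
            feature_groups, comp.rt_consensus, comp.spectrum_consensus, rt_tol
        ):
            feature_to_compound.setdefault(gid, []).append(aid)
    filtered_features = sorted(feature_to_compound)
    return FilteredSet(filtered, filtered_features, feature_to_compound), results


@dataclass
class DupRecord:
    """Minimal view of a compound for duplicate detection."""

    id: str
    rt: float
    spectrum: Mapping[int, float]
    areas: Mapping[str, float] | None = None  # deconvolution side only
    magnitude: float = 0.0  # tie-break size: total area / summed intensity

    def __post_init__(self) -> None:
        if not self.magnitude:
            if self.areas:
                self.magnitude = float(sum(self.areas.values()))
            else:
                self.magnitude = float(sum(self.spectrum.values()))


def detect_duplicates(
    records: Sequence[DupRecord],
    dot_min: float = DOT_DUPLICATE,
    rt_tol: float = RT_TOL,
    pearson_min: float = PEARSON_MIN,
    mz_lo: int = MZ_LO,
    mz_hi: int = MZ_HI,
) -> tuple[list[DuplicatePair], list[DupRecord]]:
    """Flag possible duplicate compounds and return a deduplicated list.

    A pair is a possible duplicate iff its spectral dot product is
    strictly above ``dot_min`` and the RTs agree within ``rt_tol``; on
    records that carry per-sample areas the areas must additionally
    correlate (Pearson strictly above ``pearson_min`` over >= 3 shared
    samples).  Deduplication keeps the larger-magnitude member of each
    flagged pair.
    """
    if len(records) < 2:
        return [], list(records)
    vecs = [vectorize(r.spectrum, mz_lo, mz_hi) for r in records]
    pairs: list[DuplicatePair] = []
    drop: set[str] = set()
    order = sorted(range(len(records)), key=lambda i: records[i].rt)
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            ri, rj = records[i], records[j]
            delta = abs(rj.rt - ri.rt)
            if rj.rt - ri.rt > rt_tol + EPS:
                break
            if delta > rt_tol + EPS:
                continue
            d = spectral_dot(vecs[i], vecs[j])
            if d <= dot_min + EPS:
                continue
            pearson: float | None = None
            if ri.areas is not None and rj.areas is not None:
                common = sorted(set(ri.areas) & set(rj.areas))
                if len(common) < 3:
                    continue  # correlation cannot be assessed: not flagged
                a = np.array([ri.areas[s] for s in common])
                b = np.array([rj.areas[s] for s in common])
                if a.std() == 0 or b.std() == 0:
                    continue
                pearson = float(stats.pearsonr(a, b).statistic)
                if pearson <= pearson_min + EPS:
                    continue
            pairs.append(DuplicatePair(ri.id, rj.id, d, delta, pearson))
            loser = ri if ri.magnitude < rj.magnitude else rj
            drop.add(loser.id)
    dedup = [r for r in records if r.id not in drop]
    return pairs, dedup


# ---------------------------------------------------------------------------


def normalize_matrix(
    values: pd.DataFrame,
    subsets: Mapping[str, str] | None = None,
    mode: str = "sum",
) -> pd.DataFrame:
    """Log-normalize a (features x samples) intensity matrix per subset.

    normalized(f, s) = log10(value(f, s)) / D(f) * 1000, computed within
    each subset's samples.  The denominator D(f) follows ``mode``:
    ``sum`` (default) log10 of the sum of the feature's values across the
    subset's samples; ``mean`` log10 of their mean; ``sumlog`` the sum of
    the per-sample log10 values.  Zeros are floored to 1 intensity unit
    first (logged); a feature whose denominator is not positive is
    dropped with a warning.
    """
    if mode not in ("sum", "mean", "sumlog"):
        raise ValueError("mode must be 'sum', 'mean' or 'sumlog'")
    if subsets is None:
        subsets = {s: "all" for s in values.columns}
    floored = values.copy().astype(float)
    n_floored = int((floored < 1).to_numpy().sum())
    if n_floored:
        log.warning("floored %d values below 1 intensity unit", n_floored)
        floored = floored.clip(lower=1.0)

    out = pd.DataFrame(index=floored.index, columns=floored.columns, dtype=float)
    dropped: set = set()
    for subset in sorted(set(subsets.values())):
        cols = [c for c in floored.columns if subsets[c] == subset]
        if not cols:
            continue
        block = floored[cols]
        if mode == "sum":
            denom = np.log10(block.sum(axis=1))
        elif mode == "mean":
            denom = np.log10(block.mean(axis=1))
        else:
            denom = np.log10(block).sum(axis=1)
        bad = denom <= 0
        for f in block.index[bad]:
            log.warning("feature %s dropped: non-positive denominator", f)
            dropped.add(f)
        denom = denom.where(~bad)
        out.loc[:, cols] = (np.log10(block).div(denom, axis=0) * 1000.0).values
    return out.drop(index=sorted(dropped))
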