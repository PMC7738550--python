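"""Putative compound identification against an MSP spectral library.

Spectral similarity is a NIST-style weighted cosine (weights m^1 I^0.5)
expressed as a percent match factor; retention behaviour enters through
the Kováts/van den Dool retention index computed from alkane (or VOC
standard) anchors, with the percent RI error deciding between candidate
entries.  The alkane-anchoring procedure builds the anchors from the
samples themselves through a cascade of six filters.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnchorError
from .msio import LibraryEntry, SpectralLibrary
from .peakpick import Feature

log = logging.getLogger(__name__)

__all__ = [
    "RIAnchor",
    "Identification",
    "RankBasis",
    "match_factor",
    "compute_ri",
    "ri_error",
    "candidate_entries",
    "select_best",
    "anchor_alkanes",
]

MF_FLOOR = 80.0  # candidates must exceed this match factor
MF_WINDOW = 5.0  # and sit within this many points of the best
ENTRY_CAP = 450
RI_ERROR_MAX = 20.0  # percent
ALKANE_MF_FLOOR = 95.0
ALKANE_MF_WINDOW = 5.0
ALKANE_RT_TOL = 0.05
EPS = 1e-9  # float guard at printed decision boundaries


class RankBasis(str, enum.Enum):
    RI_AND_MF = "ri_and_mf"
    MF_ONLY = "mf_only"
    NONE = "none"


@dataclass(frozen=True)
class RIAnchor:
    """One retention-index anchor (e.g. an n-alkane: RI = 100 x carbons)."""

    label: str
    rt: float
    ri: float


@dataclass
class Identification:
    """Link between a compound and its best library entry."""

    aligned_id: str
    entry_name: str | None
    match_factor: float = 0.0
    ri_query: float | None = None
    ri_error: float | None = None
    rank_basis: RankBasis = RankBasis.NONE

    def __bool__(self) -> bool:
        return self.entry_name is not None


# ---------------------------------------------------------------------------


def match_factor(query: dict[int, float], entry: dict[int, float]) -> float:
    """Percent spectral similarity: weighted cosine with weights m * I^0.5.

    100 iff the spectra are proportional, 0 for disjoint ion sets;
    symmetric in its arguments.
    """
    if not query or not entry:
        raise ValueError("match factor is undefined for an empty spectrum")
    ions = sorted(set(query) | set(entry))
    wq = np.array([m * np.sqrt(max(query.get(m, 0.0), 0.0)) for m in ions])
    we = np.array([m * np.sqrt(max(entry.get(m, 0.0), 0.0)) for m in ions])
    nq, ne = np.linalg.norm(wq), np.linalg.norm(we)
    if nq == 0 or ne == 0:
        return 0.0
    return float(100.0 * np.dot(wq, we) / (nq * ne))


def compute_ri(rt: float, anchors: list[RIAnchor]) -> float:
    """Temperature-programmed retention index by linear interpolation.

    Uses the bracketing anchor pair; outside the anchor span the terminal
    pair is extrapolated and a warning logged.
    """
    if len(anchors) < 2:
        raise AnchorError("retention-index interpolation needs >= 2 anchors")
    anchors = sorted(anchors, key=lambda a: a.rt)
    rts = np.array([a.rt for a in anchors])
    ris = np.array([a.ri for a in anchors])
    if np.any(np.diff(rts) <= 0) or np.any(np.diff(ris) <= 0):
        raise AnchorError("anchor RTs and RIs must be strictly increasing")
    if rt < rts[0] or rt > rts[-1]:
        log.warning("rt %.3f min outside anchor span: RI extrapolated", rt)
    k = int(np.clip(np.searchsorted(rts, rt) - 1, 0, len(rts) - 2))
    frac = (rt - rts[k]) / (rts[k + 1] - rts[k])
    return float(ris[k] + (ris[k + 1] - ris[k]) * frac)


def ri_error(ri_query: float, ri_entry: float) -> float:
    """Percent RI disagreement, relative to the library entry's RI."""
    if ri_entry <= 0:
        raise ValueError("entry RI must be positive")
    return float(100.0 * abs(ri_query - ri_entry) / ri_entry)


def candidate_entries(
    query: dict[int, float],
    library: SpectralLibrary,
    mf_floor: float = MF_FLOOR,
    mf_window: float = MF_WINDOW,
    cap: int = ENTRY_CAP,
) -> list[tuple[LibraryEntry, float]]:
    """Candidate library entries for one query spectrum.

    Entries with match factor strictly above ``mf_floor`` and within
    ``mf_window`` of the best qualifying match factor, by descending
    match factor, truncated to ``cap`` entries.
    """
    scored = [
        (e, match_factor(query, e.spectrum)) for e in library.entries if e.spectrum
    ]
    scored = [(e, mf) for e, mf in scored if mf > mf_floor + EPS]
    if not scored:
        return []
    best = max(mf for _, mf in scored)
    scored = [(e, mf) for e, mf in scored if mf >= best - mf_window - EPS]
    scored.sort(key=lambda t: (-t[1], t[0].name))
    return scored[:cap]


def select_best(
    candidates: list[tuple[LibraryEntry, float]],
    ri_query: float | None = None,
    ri_error_max: float = RI_ERROR_MAX,
    aligned_id: str = "",
) -> Identification:
    """Pick the best candidate entry.

    Among candidates whose RI error is at most ``ri_error_max``, the one
    with the lowest RI error wins (higher match factor breaks ties).  If
    no candidate has a qualifying RI error — including when the query or
    every entry lacks an RI — the highest match factor wins.  Empty
    candidate lists give an explicit no-identification result.
    """
    if not candidates:
        return Identification(aligned_id, None)
    with_err: list[tuple[float, float, LibraryEntry]] = []
    if ri_query is not None:
        for entry, mf in candidates:
            if entry.retention_index is not None:
                err = ri_error(ri_query, entry.retention_index)
                if err <= ri_error_max + EPS:
                    with_err.append((err, mf, entry))
    if with_err:
        with_err.sort(key=lambda t: (t[0], -t[1], t[2].name))
        err, mf, entry = with_err[0]
        return Identification(
            aligned_id, entry.name, mf, ri_query, err, RankBasis.RI_AND_MF
        )
    entry, mf = max(candidates, key=lambda t: (t[1], t[0].name))
    err = None
    if ri_query is not None and entry.retention_index is not None:
        err = ri_error(ri_query, entry.retention_index)
    return Identification(aligned_id, entry.name, mf, ri_query, err, RankBasis.MF_ONLY)


# ---------------------------------------------------------------------------
# alkane anchoring


def _alkane_carbons(entry: LibraryEntry) -> int | None:
    if entry.molecular_weight is None:
        return None
    n, rem = divmod(entry.molecular_weight - 2, 14)
    return n if rem == 0 and n >= 1 else None


def anchor_alkanes(
    compounds,  # per-sample deconvolved compounds (iterable of DeconvCompound)
    features_by_sample: dict[str, list[Feature]],
    alkane_entries: list[LibraryEntry],
    mf_floor: float = ALKANE_MF_FLOOR,
    mf_window: float = ALKANE_MF_WINDOW,
    rt_tol: float = ALKANE_RT_TOL,
) -> tuple[list[RIAnchor], dict]:
    """Determine alkane retention times from the samples themselves.

    Six filters: (1) keep compounds whose match factor against any
    alkane entry is strictly above ``mf_floor``; (2) per alkane, keep
    combinations within ``mf_window`` points of that alkane's best match
    factor; (3) the alkane's molecular ion must be present in the
    deconvolved spectrum; (4) cross-route confirmation — a detected
    feature with m/z equal to the alkane's molecular weight within
    ``rt_tol`` of the compound RT in the same sample; (5) per alkane,
    the surviving compound with the lowest RT wins (higher match factor
    breaks ties); (6) outliers of the RT-versus-carbon-number line are
    removed by robust regression (residual beyond 3 x scaled MAD).
    Returns one anchor (RI = 100 x carbons) per surviving alkane, plus
    counting diagnostics.
    """
    alkanes = [(e, _alkane_carbons(e)) for e in alkane_entries]
    alkanes = [(e, n) for e, n in alkanes if n is not None]
    if not alkanes:
        raise AnchorError("no valid alkane entries supplied")
    compounds = list(compounds)
    diag: dict = {}

    # filter 1: high spectral similarity to any alkane
    mf_table: dict[int, dict[int, float]] = {}  # compound idx -> carbons -> MF
    for i, c in enumerate(compounds):
        row = {n: match_factor(c.spectrum, e.spectrum) for e, n in alkanes}
        if max(row.values(), default=0.0) > mf_floor + EPS:
            mf_table[i] = row
    diag["selected_compounds"] = len(mf_table)

    # filter 2: per alkane, within mf_window of that alkane's best
    combos: list[tuple[int, int, float]] = []  # (compound idx, carbons, MF)
    for _, n in alkanes:
        col = {i: row[n] for i, row in mf_table.items() if row[n] > mf_floor + EPS}
        if not col:
            continue
        best = max(col.values())
        combos.extend(
            (i, n, mf) for i, mf in col.items() if mf >= best - mf_window - EPS
        )
    diag["combinations_after_mf"] = len(combos)

    # filter 3: molecular ion present in the deconvolved spectrum
    mw_by_carbons = {n: e.molecular_weight for e, n in alkanes}
    combos = [
        (i, n, mf) for i, n, mf in combos if mw_by_carbons[n] in compounds[i].spectrum
    ]
    diag["combinations_after_molecular_ion"] = len(combos)

    # filter 4: cross-route confirmation by a feature at the molecular ion
    confirmed = []
    for i, n, mf in combos:
        comp = compounds[i]
        feats = features_by_sample.get(comp.sample_id, [])
        if any(
            f.mz == mw_by_carbons[n] and abs(f.rt - comp.rt) <= rt_tol + EPS
            for f in feats
        ):
            confirmed.append((i, n, mf))
    diag["combinations_after_feature_match"] = len(confirmed)

    # filter 5: lowest RT per alkane (match factor breaks ties)
    chosen: dict[int, tuple[float, float]] = {}  # carbons -> (rt, mf)
    for i, n, mf in confirmed:
        rt = compounds[i].rt
        if n not in chosen or (rt, -mf) < (chosen[n][0], -chosen[n][1]):
            chosen[n] = (rt, mf)
    diag["alkanes_before_outlier_removal"] = len(chosen)

    # filter 6: robust RT-vs-carbon regression, drop residuals > 3 x MAD
    ns = np.array(sorted(chosen))
    rts = np.array([chosen[n][0] for n in ns])
    keep = np.ones(len(ns), dtype=bool)
    if len(ns) >= 4:
        slope, intercept, _, _ = stats.theilslopes(rts, ns)
        res = rts - (intercept + slope * ns)
        # residual scale floored at sub-scan level so a gross outlier is
        # caught even when the remaining ladder is perfectly collinear
        mad = max(1.4826 * np.median(np.abs(res - np.median(res))), 0.002)
        keep = np.abs(res - np.median(res)) <= 3 * mad
    survivors = [(int(n), float(rt)) for n, rt, k in zip(ns, rts, keep) if k]
    diag["anchors"] = len(survivors)
    if len(survivors) < 2:
        raise AnchorError(
            f"only {len(survivors)} alkane anchors survive; identification "
            "must fall back to match factor alone"
        )
    anchors = [RIAnchor(f"C{n}", rt, 100.0 * n) for n, rt in survivors]
    return anchors, diag
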