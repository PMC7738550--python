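"""Reading and writing the open formats the workflow touches.

Raw chromatograms come in as mzML or mzXML (MS1 scans only), spectral
libraries as MSP text (the open stand-in for the NIST library dialect),
and the pipeline's tabular products go out as CSV.  Retention time is
minutes everywhere inside the package; readers convert from seconds when
the file declares seconds.
"""

from __future__ import annotations

import base64
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyLibraryError, EmptyRunError, FormatError, MSPParseError

__all__ = [
    "Subset",
    "Scan",
    "TemperatureProgram",
    "RawRun",
    "LibraryEntry",
    "SpectralLibrary",
    "read_raw_run",
    "read_msp_library",
    "write_msp_library",
    "write_feature_matrix",
    "write_mzml",
]


class Subset(str, enum.Enum):
    """Which arm of the sampling design a run belongs to."""

    MOTHER = "mother"
    CHILD = "child"
    ROOM_AIR = "room_air"
    STANDARD = "standard"


@dataclass
class Scan:
    """One MS1 scan: retention time (minutes) plus the m/z, intensity arrays."""

    rt: float
    mz: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")


@dataclass(frozen=True)
class TemperatureProgram:
    """Retention-time windows of the oven's temperature ramps.

    The default mirrors a three-ramp program: 10 min isothermal, a slow
    ramp to ~38.67 min, then a fast ramp to the end of the run at
    46.12 min.  Segment boundaries drive the segment-wise deconvolution.
    """

    segments: tuple[tuple[float, float], ...] = (
        (0.0, 10.0),
        (10.0, 38.67),
        (38.67, 46.12),
    )

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        for (a, b) in segs:
            if not b > a:
                raise ValueError("each segment must have end_rt > start_rt")
        for (_, b), (c, _) in zip(segs, segs[1:]):
            if abs(b - c) > 1e-9:
                raise ValueError("segments must be contiguous and ordered")

    @property
    def start(self) -> float:
        return self.segments[0][0]

    @property
    def end(self) -> float:
        return self.segments[-1][1]


@dataclass
class RawRun:
    """One sample's profile-mode chromatogram."""

    sample_id: str
    group_id: str
    subset: Subset
    scans: list[Scan] = field(repr=False)
    ramp_program: TemperatureProgram = field(default_factory=TemperatureProgram)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class LibraryEntry:
    """One library spectrum: name, base-peak-1000 intensities, optional RI/MW."""

    name: str
    spectrum: dict[int, float]
    retention_index: float | None = None
    molecular_weight: int | None = None

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError(f"library entry {self.name!r} has an empty spectrum")
        if any(mz <= 0 for mz in self.spectrum):
            raise ValueError(f"library entry {self.name!r} has non-positive m/z keys")
        peak = max(self.spectrum.values())
        if peak <= 0:
            raise ValueError(f"library entry {self.name!r} has no positive intensity")
        if abs(peak - 1000.0) > 1e-9:
            self.spectrum = {mz: i * 1000.0 / peak for mz, i in self.spectrum.items()}


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# raw-run reading


def _scan_rt_minutes(value, unit_hint: str | None) -> float:
    """Convert a scan-start-time value to minutes, honouring declared units."""
    unit = unit_hint or getattr(value, "unit_info", None) or "minute"
    v = float(value)
    if "second" in str(unit).lower():
        return v / 60.0
    return v


def _decode_binary(elem) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or none)."""
    import zlib

    accessions = {
        e.get("accession") for e in elem.iter() if e.tag.endswith("cvParam")
    }
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    text = ""
    for e in elem.iter():
        if e.tag.endswith("}binary") or e.tag == "binary":
            text = e.text or ""
            break
    data = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    return np.frombuffer(data, dtype=dtype).astype(float), accessions


def _read_mzml_scans(path: Path) -> list[Scan]:
    from lxml import etree

    scans: list[Scan] = []
    for _, spec in etree.iterparse(str(path), tag="{*}spectrum"):
        ms_level = 1
        rt = None
        unit = None
        mz = intensity = None
        for cv in spec.iter("{*}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif acc == "MS:1000016":
                rt = float(cv.get("value"))
                unit = cv.get("unitName") or "minute"
        if ms_level == 1:
            for arr in spec.iter("{*}binaryDataArray"):
                values, accs = _decode_binary(arr)
                if "MS:1000514" in accs:
                    mz = values
                elif "MS:1000515" in accs:
                    intensity = values
            if rt is not None and mz is not None and intensity is not None:
                scans.append(Scan(_scan_rt_minutes(rt, unit), mz, intensity))
        spec.clear()
    return scans


def read_raw_run(
    path: str | Path,
    sample_id: str,
    group_id: str = "group1",
    subset: Subset | str = Subset.MOTHER,
    ramp_program: TemperatureProgram | None = None,
) -> RawRun:
    """Read all MS1 scans of an mzML or mzXML file into a :class:`RawRun`.

    Retention times are converted to minutes regardless of the unit the
    file declares.  Raises :class:`FormatError` for unreadable files and
    :class:`EmptyRunError` when no MS1 scans are present.
    """
    path = Path(path)
    subset = Subset(subset)
    suffix = path.suffix.lower()
    scans: list[Scan] = []
    try:
        if suffix == ".mzxml":
            from pyteomics import mzxml

            with mzxml.read(str(path)) as reader:
                for spec in reader:
                    if int(spec.get("msLevel", 1)) != 1:
                        continue
                    rt = _scan_rt_minutes(spec["retentionTime"], None)
                    scans.append(Scan(rt, spec["m/z array"], spec["intensity array"]))
        else:
            scans = _read_mzml_scans(path)
    except (FormatError, EmptyRunError):
        raise
    except Exception as exc:  # malformed XML, wrong format, missing keys …
        raise FormatError(f"could not read {path} as mzML/mzXML: {exc}") from exc
    if not scans:
        raise EmptyRunError(f"{path}: no MS1 scans found")
    scans.sort(key=lambda s: s.rt)
    program = ramp_program or TemperatureProgram()
    return RawRun(sample_id, group_id, subset, scans, program)


# ---------------------------------------------------------------------------
# MSP library dialect

_RI_KEYS = {"ri", "retention_index", "retentionindex"}


def read_msp_library(path: str | Path) -> SpectralLibrary:
    """Parse an MSP text library.

    Accepts both ``RI:`` and ``Retention_index:`` headers; unknown header
    lines are ignored.  Spectra are rescaled so the base peak is 1000;
    entries lacking an RI carry ``None`` rather than 0.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    name: str | None = None
    ri: float | None = None
    mw: int | None = None
    expected_peaks: int | None = None
    peaks: dict[int, float] = {}

    def flush() -> None:
        nonlocal name, ri, mw, expected_peaks, peaks
        if name is None:
            return
        if expected_peaks is not None and len(peaks) != expected_peaks:
            raise MSPParseError(
                f"{path}: entry {name!r} declares {expected_peaks} peaks "
                f"but lists {len(peaks)}"
            )
        if not peaks:
            raise MSPParseError(f"{path}: entry {name!r} has no peaks")
        entries.append(LibraryEntry(name, peaks, ri, mw))
        name, ri, mw, expected_peaks, peaks = None, None, None, None, {}

    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            flush()
            continue
        if ":" in line and not line.split(":", 1)[0].strip().replace(".", "").isdigit():
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "_")
            value = value.strip()
            if key_norm == "name":
                flush()
                name = value
            elif key_norm in _RI_KEYS:
                ri = float(value) if value else None
            elif key_norm == "mw":
                mw = int(round(float(value))) if value else None
            elif key_norm == "num_peaks":
                expected_peaks = int(value)
            # any other header line: ignored (MSP in the wild is inconsistent)
            continue
        # peak lines: "mz intensity" pairs, possibly several per line,
        # separated by whitespace or semicolons
        for pair in line.replace(";", " ; ").split(";"):
            nums = pair.split()
            if len(nums) >= 2:
                for i in range(0, len(nums) - 1, 2):
                    mz = int(round(float(nums[i])))
                    peaks[mz] = peaks.get(mz, 0.0) + float(nums[i + 1])
    flush()
    if not entries:
        raise EmptyLibraryError(f"{path}: no library entries found")
    return SpectralLibrary(entries)


def write_msp_library(library: SpectralLibrary, path: str | Path) -> None:
    """Serialize a library back to MSP text (round-trip partner of the reader)."""
    lines: list[str] = []
    for e in library.entries:
        lines.append(f"Name: {e.name}")
        if e.molecular_weight is not None:
            lines.append(f"MW: {e.molecular_weight}")
        if e.retention_index is not None:
            lines.append(f"RI: {e.retention_index:g}")
        lines.append(f"Num Peaks: {len(e.spectrum)}")
        for mz in sorted(e.spectrum):
            lines.append(f"{mz} {e.spectrum[mz]:g}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# tabular output


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: feature id, m/z, median RT, one column
    per sample.  Values survive a round trip to 6 significant digits."""
    rows = []
    for grp in matrix.rows:
        row = {
            "feature_id": grp.group_feature_id,
            "mz": grp.mz,
            "rt_median": grp.rt_median,
        }
        for sample in matrix.columns:
            row[sample] = matrix.values.at[grp.group_feature_id, sample]
        rows.append(row)
    cols = ["feature_id", "mz", "rt_median", *matrix.columns]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# minimal mzML writer (for synthetic fixtures)


def _b64(array: np.ndarray) -> str:
    data = np.asarray(array, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


def write_mzml(run: RawRun, path: str | Path, rt_unit: str = "minute") -> None:
    """Write a RawRun as a minimal, standard-conformant mzML file.

    Scan start times are written in the requested unit (``minute`` or
    ``second``); arrays are 64-bit floats without compression.
    """
    if rt_unit not in ("minute", "second"):
        raise ValueError("rt_unit must be 'minute' or 'second'")
    unit_acc = "UO:0000031" if rt_unit == "minute" else "UO:0000010"
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" '
        f'id="{run.sample_id}">'
    )
    parts.append(
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
    )
    parts.append(f'<run id="{run.sample_id}">')
    parts.append(f'<spectrumList count="{len(run.scans)}">')
    for i, scan in enumerate(run.scans):
        rt = scan.rt * 60.0 if rt_unit == "second" else scan.rt
        mz64 = _b64(scan.mz)
        it64 = _b64(scan.intensity)
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{len(scan.mz)}">'
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt!r}" unitCvRef="UO" unitAccession="{unit_acc}" '
            f'unitName="{rt_unit}"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{mz64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(it64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{it64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts))
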