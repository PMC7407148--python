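"""EIC extraction, peak integration and single-point internal-standard
semi-quantitation.

The processing chain mirrors a targeted high-resolution LC–MS workflow with
polarity switching:

1. an extracted ion chromatogram (EIC) per analyte sums, scan by scan, all
   centroid intensity within a ppm window of each configured ion product;
2. the EIC peak is integrated at the expected retention time, allowing at most
   ±0.1 min of drift — a larger apex shift yields a "Not Found" (zero) result;
3. analyte areas are divided by the assigned internal-standard area (area
   ratios), censoring below 3× the blank-sample level;
4. accepted ratios are scaled by the spiked standard concentration (5 µM
   working solutions) and, for tissue, divided by the extracted mass (mg).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mz_targets import MzTarget

__all__ = [
    "Scan",
    "PeakArea",
    "SampleMeta",
    "QuantError",
    "read_scans_tsv",
    "write_scans_tsv",
    "read_scans_mzml",
    "validate_scan_series",
    "extract_eic",
    "integrate_peak",
    "area_ratio",
    "blank_correct",
    "to_concentration",
    "quantify_samples",
]

MZ_RANGE = (100.0, 1800.0)


class QuantError(RuntimeError):
    """Quantitation failure (e.g. missing internal standard in a sample)."""


@dataclass
class Scan:
    """One centroided mass spectrum: acquisition time (min), polarity, peaks."""

    time: float
    polarity: str  # "+ve" | "-ve"
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same length")


def validate_scan_series(scans: Sequence[Scan]) -> None:
    """Check scan-series invariants: time-ordered, in-range m/z, non-negative signal."""
    times: dict[str, float] = {}
    for scan in scans:
        prev = times.get(scan.polarity)
        if prev is not None and scan.time <= prev:
            raise ValueError(f"scan times not strictly increasing at t={scan.time}")
        times[scan.polarity] = scan.time
        if scan.mz.size and (scan.mz.min() < MZ_RANGE[0] or scan.mz.max() > MZ_RANGE[1]):
            raise ValueError(f"scan at t={scan.time} has m/z outside {MZ_RANGE}")
        if scan.intensity.size and scan.intensity.min() < 0:
            raise ValueError(f"scan at t={scan.time} has negative intensity")


def read_scans_tsv(path) -> list[Scan]:
    """Read the plain-text scan dialect: scan_time_min, polarity, mz, intensity."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"scan_time_min", "polarity", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan TSV missing column(s): {sorted(missing)}")
    scans = []
    for (time, pol), grp in df.groupby(["scan_time_min", "polarity"], sort=True):
        scans.append(Scan(float(time), str(pol), grp["mz"].to_numpy(),
                          grp["intensity"].to_numpy()))
    scans.sort(key=lambda s: s.time)
    return scans


def write_scans_tsv(scans: Sequence[Scan], path) -> None:
    """Write scans in the TSV dialect (one row per centroid peak)."""
    rows = []
    for scan in scans:
        for mz, inten in zip(scan.mz, scan.intensity):
            rows.append((scan.time, scan.polarity, mz, inten))
    pd.DataFrame(rows, columns=["scan_time_min", "polarity", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _decode_binary_array(element) -> np.ndarray:
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    payload = b""
    for child in element:
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype).astype(float)


def read_scans_mzml(path) -> list[Scan]:
    """Read centroided MS1 scans from an mzML file.

    Supports 32/64-bit float arrays, optional zlib compression, and scan start
    times in minutes or seconds.
    """
    import xml.etree.ElementTree as ET

    scans = []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if elem.tag.rsplit("}", 1)[-1] != "spectrum":
            continue
        ms_level = 1
        polarity = "+ve"
        time = None
        mz = intensity = None
        for node in elem.iter():
            tag = node.tag.rsplit("}", 1)[-1]
            if tag == "cvParam":
                acc = node.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(node.get("value", "1"))
                elif acc == "MS:1000129":
                    polarity = "-ve"
                elif acc == "MS:1000130":
                    polarity = "+ve"
                elif acc == "MS:1000016":
                    time = float(node.get("value"))
                    if node.get("unitName", "minute").startswith("second"):
                        time /= 60.0
            elif tag == "binaryDataArray":
                accessions = {
                    c.get("accession") for c in node
                    if c.tag.rsplit("}", 1)[-1] == "cvParam"
                }
                if "MS:1000514" in accessions:
                    mz = _decode_binary_array(node)
                elif "MS:1000515" in accessions:
                    intensity = _decode_binary_array(node)
        if ms_level == 1 and time is not None and mz is not None and intensity is not None:
            scans.append(Scan(time, polarity, mz, intensity))
        elem.clear()
    scans.sort(key=lambda s: s.time)
    return scans


def extract_eic(
    scans: Sequence[Scan], target: MzTarget, tol_ppm: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the summed-ion chromatogram for one target.

    Each scan whose polarity matches a product contributes the sum of centroid
    intensities within ±tol_ppm of every matching product m/z.  Returns
    (times, intensities) over the matching-polarity scans.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not target.products:
        raise ValueError("empty target product list")
    polarities = {pol for _mz, pol in target.products}
    times, trace = [], []
    for scan in scans:
        if scan.polarity not in polarities:
            continue
        total = 0.0
        if scan.mz.size:
            order = np.argsort(scan.mz)
            mz_sorted = scan.mz[order]
            int_sorted = scan.intensity[order]
            for mz, pol in target.products:
                if pol != scan.polarity:
                    continue
                tol = mz * tol_ppm * 1e-6
                lo = np.searchsorted(mz_sorted, mz - tol, side="left")
                hi = np.searchsorted(mz_sorted, mz + tol, side="right")
                total += float(int_sorted[lo:hi].sum())
        times.append(scan.time)
        trace.append(total)
    return np.asarray(times), np.asarray(trace)


@dataclass(frozen=True)
class PeakArea:
    """Integration outcome; ``found=False`` means "Not Found" (zero area)."""

    analyte_id: str
    area: float
    apex_rt: float | None
    found: bool

    def __post_init__(self) -> None:
        if not self.found and self.area != 0.0:
            raise ValueError("a not-found peak must carry zero area")


def integrate_peak(
    times: np.ndarray,
    intensities: np.ndarray,
    expected_rt: float,
    rt_tolerance: float = 0.1,
    window: float = 0.5,
    max_halfwidth: float = 0.2,
    analyte_id: str = "",
) -> PeakArea:
    """Locate and integrate the EIC peak nearest the expected retention time.

    The apex is the maximum within ``expected_rt ± window``.  An apex drifting
    more than ``rt_tolerance`` from the expectation is excluded ("Not Found").
    Integration runs between the local minima flanking the apex, clipped to
    ``apex ± max_halfwidth`` as a fallback bound, using the trapezoid rule.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    if window < rt_tolerance:
        raise ValueError("window must be >= rt_tolerance")
    not_found = PeakArea(analyte_id, 0.0, None, False)

    in_window = np.abs(times - expected_rt) <= window
    if not in_window.any():
        return not_found
    idx_window = np.nonzero(in_window)[0]
    apex = idx_window[np.argmax(intensities[idx_window])]
    if intensities[apex] <= 0:
        return not_found
    apex_rt = float(times[apex])
    if abs(apex_rt - expected_rt) > rt_tolerance:
        # a peak exists but drifted out of tolerance: record where it was seen
        return PeakArea(analyte_id, 0.0, apex_rt, False)

    lo = apex
    while lo > 0 and intensities[lo - 1] < intensities[lo] and times[lo - 1] >= apex_rt - max_halfwidth:
        lo -= 1
    hi = apex
    while hi < times.size - 1 and intensities[hi + 1] < intensities[hi] and times[hi + 1] <= apex_rt + max_halfwidth:
        hi += 1
    if hi == lo:
        return not_found
    area = float(np.trapezoid(intensities[lo : hi + 1], times[lo : hi + 1]))
    return PeakArea(analyte_id, max(area, 0.0), apex_rt, True)


def area_ratio(analyte: PeakArea, standard: PeakArea) -> float:
    """Analyte area normalised to the internal-standard area in the same run."""
    if not standard.found or standard.area <= 0:
        raise QuantError(
            f"internal standard {standard.analyte_id!r} missing or zero; cannot "
            f"quantify {analyte.analyte_id!r}"
        )
    if not analyte.found:
        return 0.0
    return analyte.area / standard.area


def blank_correct(
    values: Sequence[float],
    blank_values: Sequence[float],
    factor: float = 3.0,
    stat: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Censor values below ``factor`` × the blank level.

    Returns (corrected values, censored mask).  With no blanks the correction
    is skipped with a warning.  The blank statistic is the mean by default
    (``stat="max"`` is available).
    """
    values = np.asarray(values, dtype=float)
    blank_values = np.asarray(blank_values, dtype=float)
    if blank_values.size == 0:
        warnings.warn("no blank samples provided; blank correction skipped")
        return values.copy(), np.zeros(values.shape, dtype=bool)
    level = float(blank_values.max() if stat == "max" else blank_values.mean())
    threshold = factor * level
    censored = values < threshold
    corrected = np.where(censored, 0.0, values)
    return corrected, censored


@dataclass(frozen=True)
class SampleMeta:
    """Sample-sheet entry: id, kind, extracted amount and diet group."""

    sample_id: str
    kind: str  # "sample" | "blank" | "qc"
    tissue_mass: float | None = None  # mg
    fluid_volume: float | None = None  # µL
    group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "blank", "qc"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.kind == "sample":
            if (self.tissue_mass is None) == (self.fluid_volume is None):
                raise ValueError(
                    f"sample {self.sample_id!r}: exactly one of tissue_mass / "
                    "fluid_volume must be set"
                )
            amount = self.tissue_mass if self.tissue_mass is not None else self.fluid_volume
            if amount <= 0:
                raise ValueError(f"sample {self.sample_id!r}: extracted amount must be > 0")


def read_sample_sheet(path) -> list[SampleMeta]:
    """Read a sample sheet CSV: sample_id, kind, tissue_mass_mg, fluid_volume_ul, group."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty sample sheet: {path}")
    metas = []
    for row in df.itertuples(index=False):
        mass = getattr(row, "tissue_mass_mg", None)
        vol = getattr(row, "fluid_volume_ul", None)
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                kind=str(row.kind),
                tissue_mass=None if pd.isna(mass) else float(mass),
                fluid_volume=None if pd.isna(vol) else float(vol),
                group=str(getattr(row, "group", "")),
            )
        )
    return metas


def to_concentration(ratio: float, is_concentration: float, sample: SampleMeta) -> float:
    """Concentration from an area ratio by single-point IS scaling.

    Fluids: molar (same unit as the standard concentration).  Tissue: the molar
    value divided by the extracted tissue mass (amount per mg).
    """
    if is_concentration <= 0:
        raise ValueError("internal standard concentration must be positive")
    if sample.kind != "sample":
        raise ValueError("concentrations are computed for kind='sample' only")
    conc = ratio * is_concentration
    if sample.tissue_mass is not None:
        return conc / sample.tissue_mass
    return conc


def quantify_samples(
    scan_sets: Mapping[str, Sequence[Scan]],
    targets: Mapping[str, MzTarget],
    analyte_to_standard: Mapping[str, str],
    samples: Sequence[SampleMeta],
    is_concentration: float = 5.0,
    tol_ppm: float = 10.0,
    blank_factor: float = 3.0,
    blank_stat: str = "mean",
) -> pd.DataFrame:
    """Run the full chain over a set of runs and return a long-format table.

    ``scan_sets`` maps sample id → scan series.  ``analyte_to_standard`` assigns
    every non-standard target to its internal standard id (standards are
    integrated in every run).  Output columns: sample, analyte, area,
    area_ratio, concentration, censored, censor_rule, unit.
    """
    metas = {m.sample_id: m for m in samples}
    missing = set(scan_sets) - set(metas)
    if missing:
        raise ValueError(f"scan sets without sample-sheet entries: {sorted(missing)}")
    standard_ids = set(analyte_to_standard.values())
    analyte_ids = [a for a in targets if a not in standard_ids]

    records: list[dict] = []
    for sample_id, scans in scan_sets.items():
        meta = metas[sample_id]
        std_areas = {
            sid: integrate_peak(
                *extract_eic(scans, targets[sid], tol_ppm),
                expected_rt=targets[sid].expected_rt,
                rt_tolerance=targets[sid].rt_tolerance,
                analyte_id=sid,
            )
            for sid in standard_ids
        }
        for analyte in analyte_ids:
            target = targets[analyte]
            peak = integrate_peak(
                *extract_eic(scans, target, tol_ppm),
                expected_rt=target.expected_rt,
                rt_tolerance=target.rt_tolerance,
                analyte_id=analyte,
            )
            std = std_areas[analyte_to_standard[analyte]]
            try:
                ratio = area_ratio(peak, std)
            except QuantError:
                records.append(dict(sample=sample_id, analyte=analyte, area=peak.area,
                                    area_ratio=np.nan, concentration=np.nan,
                                    censored=True, censor_rule="missing_standard",
                                    kind=meta.kind))
                continue
            if peak.found:
                rule = ""
            elif peak.apex_rt is not None:
                rule = "rt_drift"
            else:
                rule = "not_found"
            records.append(dict(sample=sample_id, analyte=analyte, area=peak.area,
                                area_ratio=ratio, concentration=np.nan,
                                censored=not peak.found, censor_rule=rule,
                                kind=meta.kind))
    result = pd.DataFrame.from_records(records)

    # blank correction on area ratios, per analyte, then concentrations
    out_frames = []
    for analyte, grp in result.groupby("analyte", sort=False):
        grp = grp.copy()
        blanks = grp.loc[grp["kind"] == "blank", "area_ratio"].dropna().to_numpy()
        mask = (grp["kind"] == "sample") & grp["area_ratio"].notna()
        corrected, censored = blank_correct(
            grp.loc[mask, "area_ratio"].to_numpy(), blanks,
            factor=blank_factor, stat=blank_stat,
        )
        grp.loc[mask, "area_ratio"] = corrected
        newly = mask.copy()
        newly.loc[mask] = censored
        grp.loc[newly & ~grp["censored"], "censor_rule"] = "blank"
        grp.loc[newly, "censored"] = True
        out_frames.append(grp)
    result = pd.concat(out_frames, ignore_index=True)

    conc = []
    unit = []
    for row in result.itertuples(index=False):
        meta = metas[row.sample]
        if meta.kind != "sample" or not np.isfinite(row.area_ratio):
            conc.append(np.nan)
            unit.append("")
            continue
        conc.append(to_concentration(float(row.area_ratio), is_concentration, meta))
        unit.append("uM/mg" if meta.tissue_mass is not None else "uM")
    result["concentration"] = conc
    result["unit"] = unit
    result.loc[result["censored"] & (result["censor_rule"] != "missing_standard"),
               "concentration"] = 0.0
    return result.drop(columns=["kind"])
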