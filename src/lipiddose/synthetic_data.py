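"""Synthetic study data: dose–response concentration matrices, chromatographic
scan series with Gaussian peaks, and the packaged group-summary fixture.

Two generators stand in for the instrument and the animal study:

* :func:`simulate_concentrations` draws per-animal lipid concentrations from a
  linear dose trend with additive Gaussian within-group noise truncated at
  zero (group SDs in the study are often comparable to the means), with
  optional ND censoring recorded as missing, not zero.
* :func:`simulate_scans` renders polarity-switching centroid scan series in
  which each analyte contributes a Gaussian elution profile at each of its ion
  product m/z values; blanks carry only the noise floor and a configurable
  contamination fraction.

Defaults mirror the acquisition described for the study: 10-min runs with a
0.25 s scan interval per polarity, and four diet groups of nine animals at
3.6/6.3/9.0/11.7 % beef tallow.

:func:`fixture_table1` loads the packaged transcription of the study's
per-lipid group summary table (472 rows: four group means ± SD plus the
printed trendline, R², significance star, direction and bold biomarker flag),
guarded by a recorded checksum.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eic_quant import Scan

__all__ = [
    "TrendSpec",
    "PeakSpec",
    "simulate_concentrations",
    "simulate_scans",
    "simulate_blank",
    "fixture_table1",
    "write_scans_mzml",
    "TABLE1_SHA256",
    "STUDY_N_PER_GROUP",
]

#: Animals per diet group (8–9 in the study; the fixture records summaries only).
STUDY_N_PER_GROUP = 9

#: sha256 of the packaged group-summary fixture CSV.
TABLE1_SHA256 = "b6df63181720dfbf6af5e2c7df36abcee3c2914ec0ba742e812dbc4659c71380"


@dataclass(frozen=True)
class TrendSpec:
    """Generating model for one lipid: value = intercept + slope × dose + noise.

    ``noise_sd`` is either one SD for all groups or a per-group sequence
    (absolute units).  ``censor_prob`` is the per-sample probability of an ND
    (missing) observation.
    """

    lipid: str
    intercept: float
    slope: float
    noise_sd: float | Sequence[float] = 0.0
    censor_prob: float = 0.0

    def __post_init__(self) -> None:
        sds = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if (sds < 0).any():
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must lie in [0, 1]")

    def group_sd(self, group_index: int, n_groups: int) -> float:
        sds = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if sds.size == 1:
            return float(sds[0])
        if sds.size != n_groups:
            raise ValueError("per-group noise_sd length must match the dose count")
        return float(sds[group_index])


def simulate_concentrations(
    specs: Sequence[TrendSpec],
    doses: Sequence[float],
    n_per_group: int = STUDY_N_PER_GROUP,
    seed: int | None = None,
    noise: str = "normal",
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a sample × lipid concentration matrix with linear dose trends.

    Values are ``max(0, intercept + slope × dose + ε)`` with Gaussian ε
    (``noise="lognormal"`` multiplies the trend value by a log-normal factor of
    matched CV instead).  ND censoring sets entries to NaN.  Returns the matrix
    and a per-sample group-label Series; reproducible under ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    sample_ids = []
    groups = []
    for gi, dose in enumerate(doses):
        for i in range(n_per_group):
            sample_ids.append(f"g{gi + 1}_s{i + 1}")
            groups.append(f"g{gi + 1}")
    groups = pd.Series(groups, index=sample_ids, name="group")

    data = np.empty((len(sample_ids), len(specs)))
    for j, spec in enumerate(specs):
        col = []
        for gi, dose in enumerate(doses):
            mu = spec.intercept + spec.slope * dose
            sd = spec.group_sd(gi, doses.size)
            if noise == "normal":
                vals = mu + rng.normal(0.0, sd, size=n_per_group) if sd > 0 else np.full(n_per_group, mu)
            elif noise == "lognormal":
                if mu <= 0:
                    vals = np.zeros(n_per_group)
                else:
                    sigma = np.sqrt(np.log1p((sd / mu) ** 2))
                    vals = mu * rng.lognormal(-sigma**2 / 2, sigma, size=n_per_group)
            else:
                raise ValueError(f"unknown noise model {noise!r}")
            col.append(np.maximum(vals, 0.0))
        values = np.concatenate(col)
        if spec.censor_prob > 0:
            censored = rng.random(values.size) < spec.censor_prob
            values[censored] = np.nan
        data[:, j] = values
    matrix = pd.DataFrame(data, index=sample_ids, columns=[s.lipid for s in specs])
    return matrix, groups


@dataclass(frozen=True)
class PeakSpec:
    """One analyte's chromatographic ground truth for scan simulation."""

    name: str
    amount: float  # arbitrary concentration units; amplitude is proportional
    apex_rt: float  # minutes
    sigma: float  # Gaussian width, minutes
    products: tuple[tuple[float, str], ...]  # (m/z, polarity)
    response: float = 1.0e5  # counts per amount unit at the apex

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")


def simulate_scans(
    peaks: Sequence[PeakSpec],
    run_length: float = 10.0,
    scan_interval_s: float = 0.25,
    noise_floor: float = 0.0,
    seed: int | None = None,
) -> list[Scan]:
    """Render one run's centroid scan series with continuous polarity switching.

    Each polarity is sampled every ``scan_interval_s`` seconds (offset by half
    an interval from the other).  Every analyte product receives the analyte's
    Gaussian elution profile; ``noise_floor`` adds half-normal baseline counts
    at each product m/z.  Reproducible under ``seed``.
    """
    if scan_interval_s <= 0 or run_length <= 0:
        raise ValueError("run_length and scan_interval_s must be positive")
    for peak in peaks:
        if not 0.0 <= peak.apex_rt <= run_length:
            raise ValueError(f"apex RT of {peak.name!r} outside the run")
        for mz, _pol in peak.products:
            if not 100.0 <= mz <= 1800.0:
                raise ValueError(f"product m/z {mz} of {peak.name!r} out of range")
    rng = np.random.default_rng(seed)
    dt = scan_interval_s / 60.0
    scans: list[Scan] = []
    mz_by_pol: dict[str, np.ndarray] = {}
    for pol in ("+ve", "-ve"):
        mzs = sorted({mz for p in peaks for mz, pp in p.products if pp == pol})
        if mzs:
            mz_by_pol[pol] = np.asarray(mzs)
    for pol_index, (pol, mz_grid) in enumerate(sorted(mz_by_pol.items())):
        t = pol_index * dt / 2.0
        times = np.arange(t, run_length, dt)
        for time in times:
            signal = np.zeros(mz_grid.size)
            for peak in peaks:
                if peak.amount == 0:
                    continue
                profile = peak.amount * peak.response * np.exp(
                    -0.5 * ((time - peak.apex_rt) / peak.sigma) ** 2
                )
                for mz, pp in peak.products:
                    if pp != pol:
                        continue
                    signal[np.searchsorted(mz_grid, mz)] += profile
            if noise_floor > 0:
                signal = signal + np.abs(rng.normal(0.0, noise_floor, size=signal.size))
            scans.append(Scan(float(time), pol, mz_grid.copy(), signal))
    scans.sort(key=lambda s: s.time)
    return scans


def simulate_blank(
    peaks: Sequence[PeakSpec],
    contamination: float = 0.0,
    run_length: float = 10.0,
    scan_interval_s: float = 0.25,
    noise_floor: float = 0.0,
    seed: int | None = None,
) -> list[Scan]:
    """A blank injection: analyte amounts scaled down to the contamination level.

    Internal standards are spiked into blanks as in practice, so peaks whose
    name starts with ``IS_`` keep their full amount.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must lie in [0, 1]")
    blank_peaks = [
        p if p.name.startswith("IS_")
        else PeakSpec(p.name, p.amount * contamination, p.apex_rt, p.sigma,
                      p.products, p.response)
        for p in peaks
    ]
    return simulate_scans(blank_peaks, run_length, scan_interval_s, noise_floor, seed)


def fixture_table1(path=None, verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged per-lipid group-summary fixture.

    Returns a DataFrame indexed by lipid with float columns mean1/sd1 …
    mean4/sd4 (NaN encodes ND), printed_slope, printed_intercept, printed_r2,
    and boolean printed_sig / printed_flag plus the printed_direction string.
    """
    if path is None:
        ref = resources.files("lipiddose.data").joinpath("table1.csv")
        raw = ref.read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise ValueError(
                "group-summary fixture checksum mismatch: "
                f"expected {TABLE1_SHA256}, got {digest}"
            )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    df = df.set_index("lipid")
    for col in df.columns:
        if col.startswith(("mean", "sd")) or col.startswith("printed_") and col not in (
            "printed_direction", "printed_sig", "printed_flag"
        ):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["printed_sig"] = df["printed_sig"].astype(bool)
    df["printed_flag"] = df["printed_flag"].astype(bool)
    df["printed_direction"] = df["printed_direction"].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# minimal mzML writer (centroid MS1 spectra only), for fixtures and round-trips

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray) -> str:
    import base64
    import struct

    packed = struct.pack(f"<{values.size}d", *map(float, values))
    return base64.b64encode(packed).decode("ascii")


def write_scans_mzml(scans: Sequence[Scan], path) -> None:
    """Write scans as a minimal centroided mzML file (64-bit, uncompressed)."""
    parts = [_MZML_HEADER.format(count=len(scans))]
    for i, scan in enumerate(scans):
        pol_acc, pol_name = (
            ("MS:1000130", "positive scan") if scan.polarity == "+ve"
            else ("MS:1000129", "negative scan")
        )
        mz_b64 = _encode_array(scan.mz)
        int_b64 = _encode_array(scan.intensity)
        parts.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.time!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    parts.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))
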