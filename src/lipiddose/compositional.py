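"""Relative (Mol%) compositions, odd/even-chain aggregation, and the closure
artifact.

Expressing lipid concentrations as relative compositions (Mol%) closes each
sample to a constant sum, making the components interdependent: a real decrease
in one part mechanically inflates the relative share of the others.  For a
two-part closure (odd-chain vs even-chain totals) the fitted Mol% dose trends
are forced to be equal in magnitude and opposite in sign, with identical R² and
p — so a Mol% "increase" in odd-chain lipids can be entirely an artifact of a
genuine decrease in the even-chain pool.  This module computes both absolute
and Mol% trends side by side to expose that contrast.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import RegressionFit, fit_trend
from .lipid_model import chain_parity, parse_lipid_name

__all__ = ["mol_percent", "aggregate_parity", "artifact_report"]


def mol_percent(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Close each sample row to 100 (entry = 100 × value / row sum).

    Raises on an all-zero (or negative-sum) sample, naming it.
    """
    values = concentrations.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative concentrations cannot be closed to Mol%")
    row_sums = values.sum(axis=1)
    bad = np.nonzero(row_sums <= 0)[0]
    if bad.size:
        names = [str(concentrations.index[i]) for i in bad]
        raise ValueError(f"sample row(s) with zero total: {names}")
    out = concentrations.div(row_sums, axis=0) * 100.0
    out.attrs["closure"] = "mol_percent"
    return out


def aggregate_parity(
    concentrations: pd.DataFrame,
    parity: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample totals of odd-chain, even-chain and all lipids.

    ``parity`` maps lipid name → "odd"/"even"; by default it is derived by
    parsing the column names.  Columns: total_odd, total_even, total_all.
    """
    if parity is None:
        parity = {
            name: chain_parity(parse_lipid_name(name)) for name in concentrations.columns
        }
    odd_cols = [c for c in concentrations.columns if parity[c] == "odd"]
    even_cols = [c for c in concentrations.columns if parity[c] == "even"]
    unknown = set(concentrations.columns) - set(odd_cols) - set(even_cols)
    if unknown:
        raise ValueError(f"lipids without parity classification: {sorted(unknown)}")
    out = pd.DataFrame(
        {
            "total_odd": concentrations[odd_cols].sum(axis=1),
            "total_even": concentrations[even_cols].sum(axis=1),
        },
        index=concentrations.index,
    )
    out["total_all"] = out["total_odd"] + out["total_even"]
    return out


def artifact_report(
    parity_totals: pd.DataFrame,
    doses: Sequence[float],
    groups: Sequence | None = None,
) -> dict[str, dict[str, RegressionFit]]:
    """Fit dose trends for parity totals in absolute and Mol% space.

    With ``groups=None``, ``parity_totals`` holds one row per dose group
    (ordered as ``doses``).  With per-sample input, ``groups`` assigns each row
    to a dose group (groups pair with ``doses`` in order of first appearance) and
    the Mol% shares are closed per sample before group averaging.  The Mol%
    series use the two-part odd+even closure, whose shares sum to 100 by
    construction.  Returns {"absolute": {odd, even, all}, "molpct": {odd, even}}.
    """
    doses = np.asarray(doses, dtype=float)
    odd_s = parity_totals["total_odd"].to_numpy(dtype=float)
    even_s = parity_totals["total_even"].to_numpy(dtype=float)
    if groups is None:
        if len(parity_totals) != doses.size:
            raise ValueError("one row per dose group required")
        odd, even = odd_s, even_s
        molpct_odd = 100.0 * odd / (odd + even)
    else:
        groups = np.asarray(groups)
        labels = pd.unique(groups)
        if labels.size != doses.size:
            raise ValueError("number of groups must match number of doses")
        share = 100.0 * odd_s / (odd_s + even_s)  # per-sample two-part closure
        odd = np.array([odd_s[groups == g].mean() for g in labels])
        even = np.array([even_s[groups == g].mean() for g in labels])
        molpct_odd = np.array([share[groups == g].mean() for g in labels])
    total = odd + even
    absolute = {
        "odd": fit_trend(doses, odd),
        "even": fit_trend(doses, even),
        "all": fit_trend(doses, total),
    }
    molpct = {
        "odd": fit_trend(doses, molpct_odd),
        "even": fit_trend(doses, 100.0 - molpct_odd),
    }
    return {"absolute": absolute, "molpct": molpct}
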