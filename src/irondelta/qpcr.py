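"""qRT-PCR relative expression (delta-Ct) and ChIP-qPCR percent-input.

Relative expression follows the delta-Ct convention with *ACT2*-style
reference normalization: per sample, dCt(target) = mean Ct(target) -
mean Ct(reference); expression = 2^(-dCt); reported values are ratios to
a calibrator sample (wild type, +Fe in the study's figures), so the
calibrator is 1 by construction. Amplification efficiency is fixed at 2
per cycle (100%); technical-replicate Ct values are averaged
arithmetically before dCt.

ChIP enrichment is expressed as percent of input chromatin: the input Ct
is first adjusted for the input dilution (10% of input by default,
subtracting log2(1/fraction) cycles), then
percent = 100 * 2^(adjusted input Ct - IP Ct). Relative enrichment
divides by a calibrator sample per region, optionally after IgG
background subtraction (floored at 0) and/or H3 normalization.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def relative_expression(wells: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Per-(sample, target) expression ratio relative to the calibrator.

    ``wells`` needs columns sample_id, target, ct, is_reference; multiple
    wells per (sample, target) are averaged. Every sample must contain a
    reference-target well and the calibrator must cover every target.
    Returns a DataFrame (sample_id, target, delta_ct, rel_expression).
    """
    required = {"sample_id", "target", "ct", "is_reference"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells table needs columns {sorted(required)}")
    if not np.isfinite(wells["ct"]).all():
        raise ValueError("non-finite Ct value in wells table")

    ref_ct = (
        wells[wells["is_reference"].astype(bool)]
        .groupby("sample_id")["ct"]
        .mean()
    )
    for s in wells["sample_id"].unique():
        if s not in ref_ct.index:
            raise ValueError(f"sample {s!r} has no reference-target well")

    targets = wells[~wells["is_reference"].astype(bool)]
    mean_ct = targets.groupby(["sample_id", "target"])["ct"].mean().reset_index()
    mean_ct["delta_ct"] = mean_ct["ct"] - mean_ct["sample_id"].map(ref_ct)
    mean_ct["expression"] = 2.0 ** (-mean_ct["delta_ct"])

    calib = mean_ct[mean_ct["sample_id"] == calibrator_sample].set_index("target")[
        "expression"
    ]
    missing = set(mean_ct["target"]) - set(calib.index)
    if calib.empty or missing:
        raise ValueError(
            f"calibrator sample {calibrator_sample!r} missing target(s): "
            f"{sorted(missing) if missing else 'all'}"
        )
    mean_ct["rel_expression"] = mean_ct["expression"] / mean_ct["target"].map(calib)
    return mean_ct[["sample_id", "target", "delta_ct", "rel_expression"]]


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.10) -> float:
    """ChIP signal as percent of dilution-adjusted input.

    adjusted input Ct = ct_input - log2(1/input_fraction);
    percent = 100 * 2^(adjusted - ct_ip).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def relative_enrichment(
    records: pd.DataFrame,
    calibrator_sample: str,
    antibody: str = "H3K27me3",
    subtract_igg: bool = False,
    divide_h3: bool = False,
) -> pd.DataFrame:
    """Per-(sample, region) ChIP enrichment relative to a calibrator sample.

    ``records`` needs columns sample_id, region, antibody, ct_ip, ct_input
    and optionally input_fraction (default 0.10). Enrichment is the
    percent-input of ``antibody`` divided by the calibrator's percent-input
    for the same region. IgG subtraction (floored at 0, logged) and H3
    normalization are off by default.
    """
    rec = records.copy()
    if "input_fraction" not in rec.columns:
        rec["input_fraction"] = 0.10
    rec["input_fraction"] = rec["input_fraction"].fillna(0.10)
    rec["percent_input"] = [
        percent_input(r.ct_ip, r.ct_input, r.input_fraction) for r in rec.itertuples()
    ]

    def pct(ab: str) -> pd.Series:
        sub = rec[rec["antibody"] == ab]
        return sub.groupby(["sample_id", "region"])["percent_input"].mean()

    signal = pct(antibody)
    if subtract_igg:
        igg = pct("IgG").reindex(signal.index).fillna(0.0)
        floored = (signal - igg).clip(lower=0.0)
        if (signal - igg < 0).any():
            logger.warning("IgG subtraction produced negative values; floored at 0")
        signal = floored
    if divide_h3:
        h3 = pct("H3").reindex(signal.index)
        if h3.isna().any():
            raise ValueError("H3 percent-input missing for some (sample, region)")
        signal = signal / h3

    out = signal.rename("enrichment").reset_index()
    calib = out[out["sample_id"] == calibrator_sample].set_index("region")["enrichment"]
    missing = set(out["region"]) - set(calib.index)
    if calib.empty or missing:
        raise ValueError(
            f"calibrator sample {calibrator_sample!r} missing region(s): "
            f"{sorted(missing) if missing else 'all'}"
        )
    out["rel_enrichment"] = out["enrichment"] / out["region"].map(calib)
    return out
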