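"""Assay arithmetic: 2^-ddCt relative quantification and dual-luciferase
ratio normalization.

Inference on the resulting values (ANOVA, t-tests) is deliberately left to
the user; the module emits per-group means and standard deviations only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_RANGE = (0.0, 45.0)


def _check_ct(values: pd.Series) -> None:
    bad = values[(values <= CT_RANGE[0]) | (values >= CT_RANGE[1])]
    if len(bad):
        raise ValueError(f"Ct values outside (0, 45): {bad.tolist()[:5]}")


def ddct(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method.

    ``records`` is long-format with columns sample, group, gene, role
    ('target' or 'reference') and ct (one row per technical replicate).
    Per sample: dCt = mean(Ct_target) - mean(Ct_reference); ddCt subtracts
    the calibrator group's mean dCt; RQ = 2^-ddCt. With several reference
    genes one RQ row is emitted per (target, reference) combination.
    """
    required = {"sample", "group", "gene", "role", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("empty Ct record table")
    _check_ct(records["ct"])
    bad_roles = set(records["role"]) - {"target", "reference"}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    if calibrator not in set(records["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")

    means = (
        records.groupby(["sample", "group", "gene", "role"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    targets = means[means["role"] == "target"]
    references = means[means["role"] == "reference"]
    if targets.empty or references.empty:
        raise ValueError("need Ct replicates for both a target and a reference gene")

    rows = []
    merged = targets.merge(
        references, on=["sample", "group"], suffixes=("_target", "_reference")
    )
    merged["delta_ct"] = merged["ct_target"] - merged["ct_reference"]
    for (target, reference), sub in merged.groupby(["gene_target", "gene_reference"], sort=True):
        cal = sub[sub["group"] == calibrator]
        if cal.empty:
            raise ValueError(
                f"calibrator group {calibrator!r} has no records for "
                f"target {target!r} vs reference {reference!r}"
            )
        cal_mean = cal["delta_ct"].mean()
        for rec in sub.itertuples(index=False):
            ddct_value = rec.delta_ct - cal_mean
            rows.append(
                {
                    "sample": rec.sample,
                    "group": rec.group,
                    "target": target,
                    "reference": reference,
                    "delta_ct": rec.delta_ct,
                    "delta_delta_ct": ddct_value,
                    "rq": 2.0 ** (-ddct_value),
                }
            )
    out = pd.DataFrame(rows).sort_values(["target", "reference", "group", "sample"])
    return out.reset_index(drop=True)


def ddct_group_summary(quant: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of RQ per (target, reference, group)."""
    return (
        quant.groupby(["target", "reference", "group"], sort=True)["rq"]
        .agg(mean_rq="mean", sd_rq=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )


def luc_ratio(records: pd.DataFrame, nc_label: str = "NC") -> pd.DataFrame:
    """Dual-luciferase ratios normalized to the negative-control treatment.

    ``records`` columns: construct, treatment, hluc, hrluc. ratio =
    hluc / hrluc; normalized activity = ratio / mean NC ratio of the same
    construct. The NC treatment must be present for every construct.
    """
    required = {"construct", "treatment", "hluc", "hrluc"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("empty luciferase record table")
    bad = records[records["hrluc"] <= 0]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"hRluc <= 0 for construct {first['construct']!r}, "
            f"treatment {first['treatment']!r}"
        )

    out = records.copy()
    out["ratio"] = out["hluc"] / out["hrluc"]
    nc_means = (
        out[out["treatment"] == nc_label].groupby("construct", sort=True)["ratio"].mean()
    )
    missing_nc = sorted(set(out["construct"]) - set(nc_means.index))
    if missing_nc:
        raise ValueError(f"no {nc_label!r} treatment for construct(s): {missing_nc}")
    out["normalized_activity"] = out["ratio"] / out["construct"].map(nc_means)
    return out.sort_values(["construct", "treatment"]).reset_index(drop=True)


def luc_group_summary(activities: pd.DataFrame) -> pd.DataFrame:
    return (
        activities.groupby(["construct", "treatment"], sort=True)["normalized_activity"]
        .agg(
            mean_activity="mean",
            sd_activity=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        )
        .reset_index()
    )
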