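"""qPCR relative expression (2^-dCt) and array concordance.

Relative expression per sample and assay is ``2 ** -(Ct_target - Ct_ref)``:
for mRNA assays the reference is the arithmetic mean Ct of the housekeeping
assays (equivalently the geometric mean of their linear abundances); for
miRNA assays it is the exogenous spike-in Ct.  Direction concordance then
compares the IUGR-vs-AGA fold direction of each assay's group means against
the array DE call for the mapped probe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["relative_expression", "concordance"]


def relative_expression(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative expression for each target assay.

    ``ct_table`` columns: sample_id, assay_id, ct, assay_class (one of
    target_mRNA, target_miRNA, housekeeping, spike_in).  Samples missing
    the needed reference are skipped with a warning.
    """
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    rows = []
    for sample, sub in ct_table.groupby("sample_id", sort=True):
        hk = sub.loc[sub["assay_class"] == "housekeeping", "ct"]
        spike = sub.loc[sub["assay_class"] == "spike_in", "ct"]
        refs = {
            "target_mRNA": hk.mean() if len(hk) else None,
            "target_miRNA": spike.mean() if len(spike) else None,
        }
        for row in sub.itertuples(index=False):
            if row.assay_class not in refs:
                continue
            ref = refs[row.assay_class]
            if ref is None:
                warnings.warn(
                    f"sample {sample}: no reference for {row.assay_class}; "
                    f"assay {row.assay_id} skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "assay_id": row.assay_id,
                    "rel": float(2.0 ** -(row.ct - ref)),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "rel"])


def concordance(
    rel_table: pd.DataFrame,
    sample_groups: pd.DataFrame,
    assay_map: pd.DataFrame,
    de_tables: dict,
) -> pd.DataFrame:
    """Direction agreement between qPCR fold changes and array DE calls.

    ``sample_groups``: columns fetus_id, group; ``assay_map``: columns
    assay_id, probe_id, track; ``de_tables``: {"miRNA": table, "mRNA":
    table} of DE results.  Returns a per-assay report; assays with equal
    group means are flagged "no direction" and excluded from the summary
    fraction, which is attached as ``frame.attrs["fraction_concordant"]``.
    """
    groups = dict(zip(sample_groups["fetus_id"], sample_groups["group"]))
    merged = rel_table.copy()
    merged["group"] = merged["sample_id"].map(groups)
    if merged["group"].isna().any():
        missing = sorted(merged.loc[merged["group"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without group labels: {missing}")

    rows = []
    n_used = n_agree = 0
    for row in assay_map.itertuples(index=False):
        sub = merged.loc[merged["assay_id"] == row.assay_id]
        if not len(sub):
            raise ValueError(f"assay {row.assay_id} absent from the Ct data")
        de = de_tables.get(row.track)
        if de is None or row.probe_id not in set(de["probe_id"]):
            raise ValueError(
                f"assay {row.assay_id} maps to probe {row.probe_id} which is "
                f"not in the {row.track} DE table"
            )
        mean_iugr = sub.loc[sub["group"] == "IUGR", "rel"].mean()
        mean_aga = sub.loc[sub["group"] == "AGA", "rel"].mean()
        if mean_iugr > mean_aga:
            direction = "up"
        elif mean_iugr < mean_aga:
            direction = "down"
        else:
            direction = "no direction"
        array_dir = de.loc[de["probe_id"] == row.probe_id, "direction"].iloc[0]
        agrees = direction == array_dir if direction != "no direction" else None
        if agrees is not None:
            n_used += 1
            n_agree += int(agrees)
        rows.append(
            {
                "assay_id": row.assay_id,
                "probe_id": row.probe_id,
                "track": row.track,
                "mean_rel_iugr": mean_iugr,
                "mean_rel_aga": mean_aga,
                "qpcr_direction": direction,
                "array_direction": array_dir,
                "concordant": agrees,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["fraction_concordant"] = n_agree / n_used if n_used else float("nan")
    return report
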