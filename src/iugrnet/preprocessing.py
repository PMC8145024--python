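"""Probe-level quality filtering of normalized expression matrices.

The pipeline consumes RMA-normalized log2 matrices together with a boolean
present-call mask (detection-above-background flags produced upstream).  Two
filters are applied before differential expression:

* presence: probes detected in less than 80% of samples are excluded;
* miRNA length: annotated miRNA probes whose mature sequence is 30 nt or
  longer are excluded (such records are typically precursors, not mature
  miRNAs).

Both filters are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "validate_annotation",
    "filter_by_presence",
    "filter_mirna_by_length",
    "quantile_normalize_log2",
]

_RNA = set("ACGU")


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression values plus a present-call mask."""

    values: pd.DataFrame
    present: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.present is None:
            self.present = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.is_unique:
            raise ValueError("probe_ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample_ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression values must not contain missing entries")
        if self.present.shape != self.values.shape or not (
            self.present.index.equals(self.values.index)
            and self.present.columns.equals(self.values.columns)
        ):
            raise ValueError("present mask must align with values")
        self.present = self.present.astype(bool)

    @property
    def probe_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probes].copy(), self.present.loc[probes].copy()
        )


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a probe annotation table (probe_id, probe_class, gene_symbol, mature_sequence)."""
    required = {"probe_id", "probe_class"}
    if missing := required - set(annotation.columns):
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if not annotation["probe_id"].is_unique:
        raise ValueError("annotation probe_ids must be unique")
    bad_class = set(annotation["probe_class"]) - {"miRNA", "mRNA"}
    if bad_class:
        raise ValueError(f"unknown probe classes: {sorted(bad_class)}")
    mirna = annotation[annotation["probe_class"] == "miRNA"]
    if len(mirna):
        seqs = mirna.get("mature_sequence")
        if seqs is None or seqs.isna().any() or (seqs == "").any():
            raise ValueError("every miRNA probe needs a mature_sequence")
        for probe, seq in zip(mirna["probe_id"], seqs):
            if set(seq) - _RNA:
                raise ValueError(
                    f"miRNA probe {probe}: sequence must be over A/C/G/U, got {seq!r}"
                )
    return annotation


def filter_by_presence(matrix: ExpressionMatrix, min_fraction: float = 0.80):
    """Retain probes present in at least ``min_fraction`` of samples.

    Probes present in *less than* the threshold fraction are excluded,
    matching the upstream array QC convention.  Returns
    ``(filtered_matrix, report)`` where the report lists every probe with its
    presence fraction and drop reason (empty string if retained).
    """
    if matrix.values.size == 0:
        raise ValueError("cannot filter an empty expression matrix")
    frac = matrix.present.mean(axis=1)
    keep = frac >= min_fraction
    report = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "presence_fraction": frac.to_numpy(),
            "reason_dropped": np.where(
                keep, "", f"present in < {min_fraction:.0%} of samples"
            ),
        }
    )
    return matrix.subset(matrix.probe_ids[keep]), report


def filter_mirna_by_length(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    max_len_exclusive: int = 30,
):
    """Drop miRNA probes whose mature sequence is >= ``max_len_exclusive`` nt.

    mRNA probes are untouched.  Returns ``(filtered_matrix, report)``.
    """
    ann = annotation.set_index("probe_id")
    drop = []
    for probe in matrix.probe_ids:
        if probe not in ann.index or ann.at[probe, "probe_class"] != "miRNA":
            continue
        seq = ann.at[probe, "mature_sequence"]
        if not isinstance(seq, str) or not seq:
            raise ValueError(f"miRNA probe {probe} lacks a mature sequence")
        if len(seq) >= max_len_exclusive:
            drop.append(probe)
    keep = matrix.probe_ids[~matrix.probe_ids.isin(drop)]
    report = pd.DataFrame(
        {
            "probe_id": drop,
            "reason_dropped": [
                f"mature sequence >= {max_len_exclusive} nt" for _ in drop
            ],
        }
    )
    return matrix.subset(keep), report


def quantile_normalize_log2(raw: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize raw intensities across samples, then log2.

    Convenience for synthetic raw intensities only; the reference pipeline
    consumes matrices normalized upstream.
    """
    if (raw <= 0).any().any():
        raise ValueError("raw intensities must be positive")
    ranks = raw.rank(method="first").astype(int) - 1
    mean_by_rank = np.sort(raw.to_numpy(), axis=0).mean(axis=1)
    out = pd.DataFrame(
        mean_by_rank[ranks.to_numpy()], index=raw.index, columns=raw.columns
    )
    return np.log2(out)
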