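"""Per-probe mixed-model differential expression (IUGR vs AGA).

Each probe's log2 expression is modeled with fixed effects for weight group
and sex and a random intercept for dam (litter), estimated by REML.  The
group contrast is reported as IUGR - AGA, so positive effects mean "up in
IUGR".  With a two-level group factor, the Type-3 F test for group is the
square of the Wald t for the group coefficient, and the post hoc
Tukey-Kramer comparison reduces to that same single contrast (asserted in
the test suite), so one F/p per probe is reported.

Denominator degrees of freedom use the containment method: group and sex
vary within litters, so they are tested in the within-litter stratum with
``ddf = n_samples - rank([X | dam indicators])``.  When the REML estimate of
the dam variance is zero (a boundary fit), results fall back to the ordinary
two-way fixed-effects model so that the degenerate case is deterministic.

Significance policy: the miRNA track uses raw p < alpha (no miRNA survives
FDR control in this design's small arrays); the mRNA track controls FDR with
Benjamini-Hochberg at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .phenotype import AGA, IUGR

__all__ = ["ProbeFit", "fit_probe_model", "bh_adjust", "run_de"]

MIRNA_TRACK = "miRNA"
MRNA_TRACK = "mRNA"


@dataclass(frozen=True)
class ProbeFit:
    """Group-contrast results for one probe."""

    effect: float  # log2(IUGR) - log2(AGA)
    F: float
    p: float
    ddf: float
    var_dam: float
    var_resid: float
    used_ols: bool  # boundary fallback (dam variance estimated at zero)


def _design(pheno: pd.DataFrame):
    """Build the fixed design matrix (intercept, group, sex) and dam codes."""
    group = (pheno["group"] == IUGR).to_numpy(float)
    if len(set(pheno["group"])) != 2 or set(pheno["group"]) != {IUGR, AGA}:
        raise ValueError("phenotype must contain exactly the two groups IUGR and AGA")
    sex = (pheno["sex"] == "male").to_numpy(float)
    X = np.column_stack([np.ones(len(pheno)), group, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design: sex is confounded with group (group and sex "
            "columns are collinear)"
        )
    for g in (IUGR, AGA):
        if (pheno["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g}")
    dams, dam_codes = np.unique(pheno["dam"].astype(str), return_inverse=True)
    return X, dam_codes, len(dams)


def fit_probe_model(y, pheno: pd.DataFrame) -> ProbeFit:
    """REML mixed model for one probe; see module docstring for conventions.

    ``y`` is the per-sample expression vector ordered like ``pheno`` rows;
    ``pheno`` needs columns group ("IUGR"/"AGA"), sex ("male"/"female"), dam.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(pheno):
        raise ValueError("y length must match phenotype rows")
    X, dam_codes, n_dams = _design(pheno)
    n = y.shape[0]

    if np.ptp(y) == 0.0:  # constant probe: no contrast information
        return ProbeFit(0.0, 0.0, 1.0, float(n - X.shape[1]), 0.0, 0.0, True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(y, X, groups=dam_codes).fit(reml=True)
    var_dam = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)

    # optimizer reports boundary solutions as tiny positives; treat anything
    # below 1e-6 of the residual variance as a zero dam-variance estimate
    if var_dam <= 1e-6 * max(var_resid, 1e-12):
        return _ols_fit(y, X)

    # Group varies within litters, so its containment-stratum F comes from
    # the dam-absorbed regression (dam indicators + group + sex): the
    # within-litter contrast eliminates the dam effect, making the F test
    # exact under the mixed model whatever the true dam variance.
    Z = np.zeros((n, n_dams))
    Z[np.arange(n), dam_codes] = 1.0
    XD = np.column_stack([Z, X[:, 1:]])
    ddf_contain = float(n - np.linalg.matrix_rank(XD))
    within = sm.OLS(y, XD).fit()
    effect = float(within.params[n_dams])
    t = float(within.tvalues[n_dams])
    F = t * t
    p = float(stats.f.sf(F, 1, ddf_contain))
    return ProbeFit(effect, F, p, ddf_contain, var_dam, var_resid, False)


def _ols_fit(y, X) -> ProbeFit:
    """Ordinary two-way fixed-effects model (boundary / degenerate path)."""
    ols = sm.OLS(y, X).fit()
    effect = float(ols.params[1])
    t = float(ols.tvalues[1])
    ddf = float(ols.df_resid)
    if not np.isfinite(t):  # saturated or zero-residual corner
        return ProbeFit(effect, 0.0, 1.0, ddf, 0.0, float(ols.scale), True)
    F = t * t
    p = float(stats.f.sf(F, 1, ddf))
    return ProbeFit(effect, F, p, ddf, 0.0, float(ols.scale), True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_de(
    matrix,
    pheno: pd.DataFrame,
    track: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression over all probes of a filtered matrix.

    ``track`` selects the significance policy: ``"miRNA"`` flags raw
    p < alpha (p_adj is a copy of p); ``"mRNA"`` flags BH-adjusted
    p_adj < alpha.  Phenotype rows are aligned to matrix columns by
    fetus_id, so statistics are invariant to sample order.
    """
    if track not in (MIRNA_TRACK, MRNA_TRACK):
        raise ValueError(f"track must be {MIRNA_TRACK!r} or {MRNA_TRACK!r}")
    ph = pheno.set_index("fetus_id").loc[list(matrix.sample_ids)].reset_index()
    rows = []
    for probe in matrix.probe_ids:
        fit = fit_probe_model(matrix.values.loc[probe].to_numpy(), ph)
        rows.append((probe, fit.effect, fit.F, fit.p))
    table = pd.DataFrame(rows, columns=["probe_id", "effect", "F", "p"])
    if track == MRNA_TRACK:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    else:
        table["p_adj"] = table["p"]
    table["direction"] = np.select(
        [table["effect"] > 0, table["effect"] < 0], ["up", "down"], default="none"
    )
    table["significant"] = table["p_adj"] < alpha
    return table
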