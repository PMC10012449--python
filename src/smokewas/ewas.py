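"""Per-CpG interaction EWAS: OLS fits, BH FDR, significance tiers, plot tables.

For each CpG the model is ordinary least squares on the M-value scale:

    DNAm = b0 + b1 IC50 + b2 Smoking + b3 IC50*Smoking + b4 Age
              + b5 PC1 + b6 PC2 + b7 PC3 + e

where Smoking is the raw lifetime cigarette count, IC50 the ex-vivo
half-maximal inhibitory concentration in uM, and PC1-PC3 reference-free
cell-composition components.  The tested effects are the two main effects
(b1, b2) and the interaction (b3), each with a two-sided t-test on n - p
residual degrees of freedom.  Multiple testing is controlled per effect by
Benjamini-Hochberg, optionally against a total test count ``m_total`` larger
than the list being adjusted (so a printed top list can be adjusted against
the full epigenome-wide count).  Significance tiers: genome-wide iff
FDR < 0.05, else suggestive iff p < 1e-5.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cellcomp import CompositionComponents
from .preprocess import MethylationMatrix

EFFECTS = ("ic50_main", "smoking_main", "interaction")

#: Column index of each tested effect in the design built by build_design.
_EFFECT_COLS = {"ic50_main": 1, "smoking_main": 2, "interaction": 3}

GENOME_WIDE_FDR = 0.05
SUGGESTIVE_P = 1e-5


def build_design(
    samples: pd.DataFrame,
    components: Optional[CompositionComponents] = None,
    center: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, IC50, Smoking, IC50*Smoking, Age, PC1..PCk].

    ``center=False`` (default) keeps covariates on their raw scale; with
    ``center=True`` IC50, Smoking and Age are mean-centered before the
    interaction is formed, which improves conditioning without changing the
    interaction test.
    """
    ic50 = samples["ic50"].to_numpy(float)
    smoking = samples["cigarettes_total"].to_numpy(float)
    age = samples["age"].to_numpy(float)
    if center:
        ic50 = ic50 - ic50.mean()
        smoking = smoking - smoking.mean()
        age = age - age.mean()
    cols = [np.ones(len(samples)), ic50, smoking, ic50 * smoking, age]
    names = ["intercept", "ic50", "smoking", "ic50_x_smoking", "age"]
    if components is not None:
        comp = components.components
        if list(comp.index) != list(samples["sample_id"]):
            comp = comp.loc[samples["sample_id"]]
        for name in comp.columns:
            cols.append(comp[name].to_numpy(float))
            names.append(name)
    return np.column_stack(cols), names


def _ols_stats(x: np.ndarray, y: np.ndarray):
    """QR-based OLS of every column of ``y`` (n x m) on ``x`` (n x p).

    Returns (coefficients p x m, t-values, p-values, df_resid).  Probes with
    numerically zero residual variance get t = 0 and p = 1 for every
    coefficient by convention.
    """
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than predictors ({p})")
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * diag.max()).any():
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta
    df = n - p
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    rinv = np.linalg.solve(r, np.eye(p))
    xtx_inv_diag = (rinv ** 2).sum(axis=1)
    scale = (y ** 2).mean(axis=0) + 1.0
    degenerate = sigma2 <= np.finfo(float).eps * scale
    safe_sigma2 = np.where(degenerate, 1.0, sigma2)
    se = np.sqrt(np.outer(xtx_inv_diag, safe_sigma2))
    t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    t[:, degenerate] = 0.0
    pvals[:, degenerate] = 1.0
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return beta, t, pvals, df


def fit_interaction_model(
    y: Sequence[float] | pd.Series,
    samples: pd.DataFrame,
    components: Optional[CompositionComponents] = None,
    center: bool = False,
) -> dict[str, tuple[float, float, float]]:
    """Fit the interaction model for one probe.

    ``y`` is the probe's M-values aligned to ``samples`` (a Series indexed by
    sample_id is re-ordered; a bare array is taken as already aligned).
    Returns {effect: (coefficient, t, p)} for the three tested effects.
    Raises ``numpy.linalg.LinAlgError`` on a rank-deficient design (e.g. an
    all-zero smoking column) so callers can skip the probe with a diagnostic.
    """
    if isinstance(y, pd.Series):
        y = y.loc[samples["sample_id"]]
    yv = np.asarray(y, float).reshape(-1, 1)
    if len(yv) != len(samples):
        raise ValueError("y length does not match the sample table")
    x, _ = build_design(samples, components, center=center)
    beta, t, p, _ = _ols_stats(x, yv)
    return {eff: (float(beta[c, 0]), float(t[c, 0]), float(p[c, 0]))
            for eff, c in _EFFECT_COLS.items()}


def bh_fdr(pvalues: Sequence[float], m_total: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``m_total`` is the number of tests used in the adjustment and may exceed
    the length of ``pvalues`` — the standard situation when adjusting a
    printed top list against the full number of tests performed:
    adjusted_i = min over ranks j >= i of min(1, m_total * p_(j) / j).
    """
    p = np.asarray(pvalues, float)
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError("m_total cannot be smaller than the number of p-values")
    if len(p) == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def classify_significance(
    p,
    fdr,
    fdr_threshold: float = GENOME_WIDE_FDR,
    suggestive_p: float = SUGGESTIVE_P,
):
    """Tier labels: 'genome_wide' iff fdr < threshold, else 'suggestive' iff
    p < suggestive cut-off, else 'none'.  Accepts scalars or arrays."""
    p_arr = np.asarray(p, float)
    f_arr = np.asarray(fdr, float)
    tiers = np.where(f_arr < fdr_threshold, "genome_wide",
                     np.where(p_arr < suggestive_p, "suggestive", "none"))
    if np.isscalar(p) or p_arr.ndim == 0:
        return str(tiers)
    return tiers


def run_ewas(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    components: Optional[CompositionComponents] = None,
    annotation: Optional[pd.DataFrame] = None,
    m_total: Optional[int] = None,
    center: bool = False,
) -> pd.DataFrame:
    """Fit the interaction model for every probe and attach FDR per effect.

    Returns one row per probe with, for each tested effect,
    ``{effect}_coef``, ``{effect}_t``, ``{effect}_p``, ``{effect}_fdr`` and
    ``{effect}_tier`` columns, plus chromosome/position/gene if an
    annotation table is supplied.  ``m_total`` defaults to the number of
    probes tested.
    """
    if matrix.scale != "mvalue":
        raise ValueError("run_ewas expects an mvalue-scale matrix")
    sample_ids = list(samples["sample_id"])
    if set(sample_ids) != set(matrix.sample_ids):
        raise ValueError("sample mismatch between matrix and covariates")
    y = matrix.values[sample_ids].to_numpy(float).T      # n x m
    x, _ = build_design(samples, components, center=center)
    beta, t, p, _ = _ols_stats(x, y)

    out = pd.DataFrame({"probe_id": matrix.probe_ids})
    for eff, c in _EFFECT_COLS.items():
        out[f"{eff}_coef"] = beta[c]
        out[f"{eff}_t"] = t[c]
        out[f"{eff}_p"] = p[c]
        out[f"{eff}_fdr"] = bh_fdr(p[c], m_total=m_total)
        out[f"{eff}_tier"] = classify_significance(out[f"{eff}_p"], out[f"{eff}_fdr"])
    if annotation is not None:
        ann = annotation.set_index("probe_id").loc[out["probe_id"]]
        for col in ("chromosome", "position", "gene"):
            if col in ann:
                out[col] = ann[col].to_numpy()
    return out


def effect_size_for_t(
    samples: pd.DataFrame,
    target_t: float,
    noise_sd: float,
    term: str = "interaction",
    components: Optional[CompositionComponents] = None,
) -> float:
    """Effect size (M-value units per covariate unit) whose expected t-statistic
    under Gaussian noise of the given sd equals ``target_t`` for this design."""
    x, _ = build_design(samples, components)
    xtx_inv = np.linalg.inv(x.T @ x)
    c = _EFFECT_COLS[term]
    return float(target_t * noise_sd * np.sqrt(xtx_inv[c, c]))


def plot_tables(
    results: pd.DataFrame,
    effect: str = "interaction",
    fdr_threshold: float = GENOME_WIDE_FDR,
    suggestive_p: float = SUGGESTIVE_P,
) -> dict[str, pd.DataFrame]:
    """Export Manhattan, QQ and volcano data tables for one effect.

    * manhattan: chromosome, position, neg_log10_p;
    * qq: expected quantile -log10(i/(m+1)) vs observed -log10 p, ascending;
    * volcano: coefficient, neg_log10_p, tier.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    p = results[f"{effect}_p"].to_numpy(float)
    neglog = -np.log10(p)
    tables: dict[str, pd.DataFrame] = {}
    if {"chromosome", "position"}.issubset(results.columns):
        tables["manhattan"] = pd.DataFrame({
            "probe_id": results["probe_id"],
            "chromosome": results["chromosome"],
            "position": results["position"],
            "neg_log10_p": neglog,
        })
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    tables["qq"] = pd.DataFrame({
        "expected_neg_log10_p": -np.log10(np.arange(1, m + 1) / (m + 1)),
        "observed_neg_log10_p": neglog[order],
    })
    tables["volcano"] = pd.DataFrame({
        "probe_id": results["probe_id"],
        "coefficient": results[f"{effect}_coef"],
        "neg_log10_p": neglog,
        "tier": classify_significance(p, results[f"{effect}_fdr"].to_numpy(float),
                                      fdr_threshold, suggestive_p),
    })
    return tables
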