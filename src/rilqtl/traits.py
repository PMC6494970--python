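"""Trait-level descriptive analyses.

Percent response to the non-irrigated scenario, per-scenario Pearson
correlation matrices, PCA of corrected trait data, and the Van Soest
fiber-fraction arithmetic deriving cellulose and hemicellulose contents from
NDF/ADF/ADL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "percent_response",
    "signed_response",
    "response_table",
    "correlation_matrix",
    "PCAResult",
    "pca_traits",
    "vansoest_derived",
]


def percent_response(mean_I: float, mean_NI: float, ndigits: int | None = None):
    """Percent response to water deficit: 100 * |NI - I| / I.

    The magnitude of the relative change of the trait mean between the
    irrigated and non-irrigated scenarios; always >= 0.  Rounded to
    ``ndigits`` decimals when requested (trait tables print one decimal).
    """
    if mean_I == 0:
        raise ValueError("percent response undefined for a zero irrigated mean")
    val = 100.0 * abs(mean_NI - mean_I) / mean_I
    return round(val, ndigits) if ndigits is not None else val


def signed_response(mean_I: float, mean_NI: float, ndigits: int | None = None):
    """Direction-aware variant: 100 * (NI - I) / I (negative = decrease)."""
    if mean_I == 0:
        raise ValueError("response undefined for a zero irrigated mean")
    val = 100.0 * (mean_NI - mean_I) / mean_I
    return round(val, ndigits) if ndigits is not None else val


def response_table(means_I: pd.Series, means_NI: pd.Series,
                   ndigits: int | None = 1) -> pd.DataFrame:
    """Per-group response summary from aligned I and NI trait means."""
    idx = means_I.index.intersection(means_NI.index)
    rows = []
    for k in idx:
        mi, mn = float(means_I[k]), float(means_NI[k])
        rows.append((k, mi, mn,
                     percent_response(mi, mn, ndigits),
                     signed_response(mi, mn, ndigits)))
    return pd.DataFrame(
        rows, columns=["group", "mean_I", "mean_NI",
                       "percent_response", "signed_response"])


# ----------------------------------------------------------------------
def correlation_matrix(data: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait columns.

    Zero-variance traits get NaN rows/columns; the defined diagonal is
    exactly 1.  Requires >= 3 complete observations per pair.
    """
    cols = list(traits) if traits is not None else list(data.columns)
    sub = data[cols].astype(float)
    corr = sub.corr(method="pearson", min_periods=3)
    const = sub.std(ddof=1) == 0
    for c in corr.columns[const.reindex(corr.columns, fill_value=False)]:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    for c in corr.columns:
        if not const.get(c, False):
            corr.loc[c, c] = 1.0
    return corr


# ----------------------------------------------------------------------
@dataclass
class PCAResult:
    """PCA of centered unit-variance trait data (correlation-matrix eigen)."""

    loadings: pd.DataFrame          # traits x components
    scores: pd.DataFrame            # observations x components
    percent_variance: pd.Series     # per component, sums to 100
    groups: pd.Series | None = None

    def summary(self) -> str:
        top = ", ".join(f"{c} {v:.2f}%"
                        for c, v in list(self.percent_variance.items())[:3])
        return (f"PCA of {self.loadings.shape[0]} traits, "
                f"{self.scores.shape[0]} observations; first components: {top}")


def pca_traits(data: pd.DataFrame, traits=None,
               groups: pd.Series | None = None) -> PCAResult:
    """PCA on centered, unit-variance-scaled trait columns.

    Eigen-decomposition of the correlation matrix; scores are the scaled data
    projected on the loadings; percent variance = 100 * eigenvalue / number of
    traits.  Sign convention: each component's largest-magnitude loading is
    positive.  Rows with any missing trait are dropped.
    """
    cols = list(traits) if traits is not None else list(data.columns)
    if len(cols) < 2:
        raise ValueError("PCA needs at least two traits")
    sub = data[cols].astype(float).dropna()
    if len(sub) <= len(cols):
        raise ValueError("need more complete observations than traits")
    sd = sub.std(ddof=1)
    const = sd[sd == 0]
    if len(const):
        raise ValueError(f"constant trait column(s): {list(const.index)}")
    scaled = (sub - sub.mean()) / sd
    corr = np.corrcoef(scaled.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # fix the sign so the dominant loading of each component is positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(len(cols))]
    loadings = pd.DataFrame(evecs, index=cols, columns=comp_names)
    scores = pd.DataFrame(scaled.to_numpy() @ evecs, index=sub.index,
                          columns=comp_names)
    pv = pd.Series(100.0 * np.clip(evals, 0, None) / len(cols),
                   index=comp_names, name="percent_variance")
    grp = groups.reindex(sub.index) if groups is not None else None
    return PCAResult(loadings=loadings, scores=scores, percent_variance=pv,
                     groups=grp)


# ----------------------------------------------------------------------
def vansoest_derived(NDF, ADF, ADL):
    """Cellulose and hemicellulose from sequential Van Soest fiber fractions.

    CL.NDF = 100 * (ADF - ADL) / NDF and HC.NDF = 100 * (NDF - ADF) / NDF,
    both as percent of NDF.  Inputs must satisfy NDF >= ADF >= ADL >= 0 with
    NDF > 0 (the fractions are nested by construction of the assay).
    """
    NDF = np.asarray(NDF, dtype=float)
    ADF = np.asarray(ADF, dtype=float)
    ADL = np.asarray(ADL, dtype=float)
    if np.any(NDF <= 0):
        raise ValueError("NDF must be positive")
    if np.any(ADL < 0) or np.any(ADF < ADL) or np.any(NDF < ADF):
        raise ValueError("require NDF >= ADF >= ADL >= 0 (nested fiber fractions)")
    cl = 100.0 * (ADF - ADL) / NDF
    hc = 100.0 * (NDF - ADF) / NDF
    if cl.ndim == 0:
        return float(cl), float(hc)
    return cl, hc
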