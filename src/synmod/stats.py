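"""Shared statistical primitives.

Benjamini-Hochberg FDR adjustment, Dunnett many-to-one post-hoc comparisons,
comparative 2^-ddCt relative expression for qPCR, and standard-curve
interpolation for plate assays (ELISA, enzymatic cholesterol). These are used
throughout the screen, proteomics and imaging modules and are also part of the
public API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "DunnettResult",
    "dunnett_adjust",
    "ddct_relative_expression",
    "StandardCurve",
    "standard_curve_interpolate",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Values are capped at 1 and returned in the original order.

    Parameters
    ----------
    pvalues : sequence of float
        Raw p-values, each in [0, 1].

    Returns
    -------
    numpy.ndarray
        Adjusted p-values, ``padj[i] >= p[i]`` elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DunnettResult:
    """Per-treatment many-to-one comparison against a shared control."""

    statistic: np.ndarray  # t statistic per treatment group
    p_raw: np.ndarray  # unadjusted two-sided t p-value
    p_adjusted: np.ndarray  # Dunnett-adjusted p-value
    df: int  # pooled residual degrees of freedom

    def as_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        idx = list(labels) if labels is not None else range(len(self.statistic))
        return pd.DataFrame(
            {"t": self.statistic, "p": self.p_raw, "p_dunnett": self.p_adjusted},
            index=idx,
        )


def dunnett_adjust(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparisons via Monte Carlo.

    Each treatment group is compared against the shared control using the
    pooled-variance t statistic; adjusted p-values are tail probabilities of
    the max-|t| statistic under the joint multivariate-t distribution with the
    many-to-one correlation structure (``rho_ij = lam_i * lam_j``,
    ``lam_i = sqrt(n_i / (n_i + n_0))``), evaluated by Monte Carlo. Handles
    unbalanced group sizes.

    Parameters
    ----------
    control : array-like
        Observations in the control group.
    treatments : sequence of array-like
        One array of observations per treatment group (k >= 1).
    n_draws : int
        Monte Carlo draws for the max-|t| null distribution.
    seed : int
        Seed for the Monte Carlo sampler.
    """
    x0 = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if len(groups) == 0:
        raise ValueError("at least one treatment group is required")
    if x0.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")

    n0 = x0.size
    ns = np.array([g.size for g in groups])
    k = len(groups)
    n_total = n0 + ns.sum()
    df = int(n_total - (k + 1))
    # pooled within-group variance
    sse = np.sum((x0 - x0.mean()) ** 2) + sum(
        np.sum((g - g.mean()) ** 2) for g in groups
    )
    s2 = sse / df
    if s2 == 0:
        # degenerate: identical values everywhere -> no evidence of difference
        t_obs = np.zeros(k)
    else:
        t_obs = np.array(
            [(g.mean() - x0.mean()) / np.sqrt(s2 * (1 / g.size + 1 / n0)) for g in groups]
        )
    p_raw = 2 * sps.t.sf(np.abs(t_obs), df)

    # Monte Carlo of max |T| under H0: T_i = (lam_i Z0 + sqrt(1-lam_i^2) Z_i)/W
    lam = np.sqrt(ns / (ns + n0))
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws)
    zi = rng.standard_normal((n_draws, k))
    w = np.sqrt(rng.chisquare(df, n_draws) / df)
    t_null = (lam * z0[:, None] + np.sqrt(1 - lam**2) * zi) / w[:, None]
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    # adjusted p can never fall below the raw p
    p_adj = np.maximum(p_adj, p_raw)
    return DunnettResult(statistic=t_obs, p_raw=p_raw, p_adjusted=np.minimum(p_adj, 1.0), df=df)


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    references: Sequence[str],
    calibrator_sample: str,
) -> pd.Series:
    """Comparative 2^-ddCt relative expression per sample.

    Technical replicates are averaged on the Ct (cycle) scale first. The
    target Ct is normalized to the mean Ct of the reference (housekeeping)
    genes, then expressed relative to the calibrator sample:

    ``dCt = Ct_target - mean(Ct_references)``;
    ``ddCt = dCt_sample - dCt_calibrator``; result ``2 ** -ddCt``.

    Parameters
    ----------
    ct : pandas.DataFrame
        Tidy table with columns ``sample``, ``gene``, ``ct`` (one row per
        technical replicate).
    target : str
        Target gene name.
    references : sequence of str
        Reference gene names (>= 1).
    calibrator_sample : str
        Sample against which expression is calibrated (value 1.0).
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if len(references) == 0:
        raise ValueError("at least one reference gene is required")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    missing = [g for g in [target, *references] if g not in mean_ct.columns]
    if missing:
        raise ValueError(f"genes missing from Ct table: {missing}")
    if mean_ct[[target, *references]].isna().any().any():
        bad = mean_ct.index[mean_ct[[target, *references]].isna().any(axis=1)]
        raise ValueError(f"samples with missing gene measurements: {list(bad)}")
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not found")

    dct = mean_ct[target] - mean_ct[list(references)].mean(axis=1)
    ddct = dct - dct.loc[calibrator_sample]
    out = np.power(2.0, -ddct)
    out.name = "relative_expression"
    return out


@dataclass(frozen=True)
class StandardCurve:
    """Assay standard curve: paired (reading, concentration) standards.

    Readings must be strictly monotone in concentration so interpolation is
    well defined.
    """

    readings: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.readings, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if r.size != c.size or r.size < 2:
            raise ValueError("need >= 2 (reading, concentration) standards")
        order = np.argsort(c)
        r, c = r[order], c[order]
        dr = np.diff(r)
        if not (np.all(dr > 0) or np.all(dr < 0)):
            raise ValueError("readings must be strictly monotone in concentration")
        object.__setattr__(self, "readings", r)
        object.__setattr__(self, "concentrations", c)


def standard_curve_interpolate(
    curve: StandardCurve,
    reading: float | Sequence[float],
    dilution_factor: float = 1.0,
    kind: str = "linear",
) -> np.ndarray:
    """Concentration from a plate reading via an interpolated standard curve.

    No extrapolation: readings outside the standards' range raise. The result
    is multiplied by ``dilution_factor`` to undo sample dilution (e.g. 25 for
    a 1:25 dilution).

    Parameters
    ----------
    kind : {"linear", "pchip"}
        Piecewise-linear (default) or monotone-cubic interpolation.
    """
    x = np.atleast_1d(np.asarray(reading, dtype=float))
    r, c = curve.readings, curve.concentrations
    lo, hi = min(r[0], r[-1]), max(r[0], r[-1])
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(
            f"reading outside standard-curve range [{lo}, {hi}]; refusing to extrapolate"
        )
    if kind == "linear":
        if r[0] < r[-1]:
            conc = np.interp(x, r, c)
        else:
            conc = np.interp(x, r[::-1], c[::-1])
    elif kind == "pchip":
        from scipy.interpolate import PchipInterpolator

        order = np.argsort(r)
        conc = PchipInterpolator(r[order], c[order])(x)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    out = conc * dilution_factor
    return out if np.ndim(reading) else float(out[0])
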