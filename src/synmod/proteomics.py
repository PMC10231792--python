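"""Differential protein abundance for TMT proteomics designs.

Two designs from the fly aSyn studies are supported: a cross-sectional
discovery design (two genotypes, n replicates each, one age) analysed with a
negative-binomial Wald test on rounded reporter intensities after
median-of-ratios normalization, and a longitudinal replication design
(replicates x ages) analysed with Gaussian linear models on log-normalized
abundance, testing genotype by likelihood ratio against an age-only base
model. Both paths apply Benjamini-Hochberg FDR control.

Preprocessing follows the deposited datasets' conventions: proteins with any
missing value are excluded and rows mapping to the same FlyBase gene id are
summed. Analyses can be restricted to a homolog set (e.g. fly homologs of
human lysosomal-storage-disorder genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps
import statsmodels.api as sm

from .stats import bh_adjust

__all__ = [
    "ProteinMatrix",
    "preprocess",
    "size_factors",
    "nb_wald_de",
    "ttest_de",
    "longitudinal_lrt",
    "restrict_to_homologs",
    "read_abundance",
    "read_sample_metadata",
    "n_unique_proteins",
]

log = logging.getLogger(__name__)


@dataclass
class ProteinMatrix:
    """Protein x sample abundance matrix with sample metadata.

    ``abundance``: DataFrame indexed by protein id, one column per sample
    (non-negative reporter intensities). ``meta``: DataFrame with columns
    ``sample``, ``genotype`` (control / asyn), ``age_days``, ``replicate``.
    ``flybase``: optional Series mapping protein id -> FlyBase gene id.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    flybase: pd.Series | None = None

    def __post_init__(self):
        if "sample" not in self.meta.columns or "genotype" not in self.meta.columns:
            raise ValueError("meta needs 'sample' and 'genotype' columns")
        missing = set(self.abundance.columns) - set(self.meta["sample"])
        orphans = set(self.meta["sample"]) - set(self.abundance.columns)
        if missing or orphans:
            raise ValueError(
                f"sample/metadata mismatch: no metadata for {sorted(missing)}; "
                f"metadata without columns {sorted(orphans)}"
            )
        self.meta = self.meta.set_index("sample", drop=False).loc[list(self.abundance.columns)]

    def genotype_indicator(self, level: str = "asyn") -> np.ndarray:
        return (self.meta["genotype"] == level).to_numpy(dtype=float)


def preprocess(pm: ProteinMatrix) -> ProteinMatrix:
    """Drop proteins with missing values; sum rows sharing a FlyBase id.

    Raises when nothing survives.
    """
    ab = pm.abundance
    kept = ab.dropna(axis=0, how="any")
    n_dropped = len(ab) - len(kept)
    if n_dropped:
        log.info("dropped %d proteins with missing values", n_dropped)
    if pm.flybase is not None:
        fb = pm.flybase.reindex(kept.index)
        fb = fb.fillna(pd.Series(kept.index, index=kept.index))  # unmapped keep own id
        summed = kept.groupby(fb.to_numpy()).sum()
        summed.index.name = ab.index.name
        kept = summed
        flybase = pd.Series(kept.index, index=kept.index)
    else:
        if kept.index.duplicated().any():
            kept = kept.groupby(level=0).sum()
        flybase = None
    if kept.empty:
        raise ValueError("no proteins left after missing-value filtering")
    return ProteinMatrix(kept, pm.meta.reset_index(drop=True), flybase)


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    The reference is the per-protein geometric mean over samples; proteins
    with any zero are excluded from the reference. Each sample's factor is
    the median over proteins of abundance / reference.
    """
    x = matrix.to_numpy(dtype=float)
    allpos = np.all(x > 0, axis=1)
    if not allpos.any():
        raise ValueError("no protein with all-positive abundances; cannot normalize")
    ref = np.exp(np.mean(np.log(x[allpos]), axis=1))
    ratios = x[allpos] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=matrix.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative-binomial log likelihood (variance mu + alpha mu^2)."""
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _ml_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray | None = None,
    lo: float = 1e-8,
    hi: float = 20.0,
) -> float:
    """Per-protein maximum-likelihood dispersion given fitted means.

    When a design matrix is supplied the likelihood carries a Cox-Reid
    adjustment (-0.5 log det X'WX, W = diag(mu / (1 + alpha mu))) that
    corrects the downward bias from estimating the mean coefficients.
    """

    def nll(la):
        alpha = np.exp(la)
        ll = _nb_loglik(y, mu, alpha)
        if X is not None:
            w = mu / (1.0 + alpha * mu)
            _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            ll -= 0.5 * logdet
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(np.log(lo), np.log(hi)), method="bounded")
    return float(np.exp(res.x))


def nb_wald_de(
    pm: ProteinMatrix,
    contrast_level: str = "asyn",
    trend_weight: float = 0.5,
    padj_threshold: float = 0.05,
    wald_reference: str = "t",
) -> pd.DataFrame:
    """Negative-binomial Wald differential abundance (asyn vs control).

    Intensities are rounded to integers for the count model. Per protein a
    NB GLM with log link, design intercept + genotype and log size-factor
    offsets is fitted; dispersion is estimated by per-protein Cox-Reid
    adjusted maximum likelihood and moderated toward a log-linear
    mean-dispersion trend (``log disp ~ log mean``) by a weighted average on
    the log scale (``trend_weight`` toward the trend). The Wald statistic
    beta / SE is referred by default to a t distribution with the residual
    degrees of freedom (small-sample correction for the modest replicate
    numbers of TMT designs; ``wald_reference='normal'`` for the asymptotic
    reference), two-sided, with Benjamini-Hochberg adjustment.

    Proteins with all-zero counts are excluded (logged). Returns a table
    with protein, base_mean, log2fc, stat, p, padj, direction.
    """
    counts = np.round(pm.abundance.to_numpy(dtype=float))
    ids = pm.abundance.index.to_numpy()
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("excluding %d all-zero proteins", int((~nonzero).sum()))
    counts, ids = counts[nonzero], ids[nonzero]
    if counts.shape[0] == 0:
        raise ValueError("no non-zero proteins to test")
    sf = size_factors(pd.DataFrame(counts, columns=pm.abundance.columns)).to_numpy()
    offset = np.log(sf)
    g = pm.genotype_indicator(contrast_level)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need >= 2 samples per genotype")
    X = np.column_stack([np.ones_like(g), g])

    n = counts.shape[0]
    disp_mle = np.empty(n)
    base_mean = np.empty(n)
    coefs = np.empty(n)
    for i in range(n):
        y = counts[i]
        base_mean[i] = np.mean(y / sf)
        try:
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=0.05), offset=offset
            ).fit()
            mu = np.clip(fit.fittedvalues, 1e-8, None)
        except Exception:  # pragma: no cover - pathological rows
            mu = np.clip(np.full_like(y, y.mean(), dtype=float) * sf, 1e-8, None)
        disp_mle[i] = _ml_dispersion(y, mu, X=X)
        coefs[i] = 0.0

    # log-linear mean-dispersion trend; moderate each MLE toward it
    interior = (disp_mle > 2e-8) & (disp_mle < 19.0) & (base_mean > 0)
    if interior.sum() >= 10:
        A = np.column_stack([np.ones(interior.sum()), np.log(base_mean[interior])])
        b, *_ = np.linalg.lstsq(A, np.log(disp_mle[interior]), rcond=None)
        trend = np.exp(b[0] + b[1] * np.log(np.clip(base_mean, 1e-8, None)))
    else:
        trend = np.full(n, np.exp(np.mean(np.log(np.clip(disp_mle, 1e-8, None)))))
    disp_mod = np.exp(
        (1.0 - trend_weight) * np.log(np.clip(disp_mle, 1e-10, None))
        + trend_weight * np.log(np.clip(trend, 1e-10, None))
    )

    if wald_reference not in ("t", "normal"):
        raise ValueError("wald_reference must be 't' or 'normal'")
    df_resid = counts.shape[1] - X.shape[1]
    stat = np.full(n, np.nan)
    pval = np.ones(n)
    for i in range(n):
        try:
            fit = sm.GLM(
                counts[i], X, family=sm.families.NegativeBinomial(alpha=disp_mod[i]),
                offset=offset,
            ).fit()
            coefs[i] = fit.params[1]
            stat[i] = fit.params[1] / fit.bse[1]
            if wald_reference == "t":
                pval[i] = 2 * sps.t.sf(abs(stat[i]), df=df_resid)
            else:
                pval[i] = 2 * sps.norm.sf(abs(stat[i]))
        except Exception:  # pragma: no cover
            log.warning("NB fit failed for protein %s; p set to 1", ids[i])
            coefs[i], stat[i], pval[i] = 0.0, 0.0, 1.0

    out = pd.DataFrame(
        {
            "protein": ids,
            "base_mean": base_mean,
            "log2fc": coefs / np.log(2.0),
            "dispersion": disp_mod,
            "stat": stat,
            "p": pval,
            "padj": bh_adjust(pval),
        }
    )
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = out["padj"] < padj_threshold
    return out


def ttest_de(pm: ProteinMatrix, contrast_level: str = "asyn") -> pd.DataFrame:
    """Two-sided unpaired t-tests on normalized abundance per protein.

    Used for display-style mean comparisons. Zero within-group variance in
    both groups with equal means yields p = 1 by convention (logged).
    """
    sf = size_factors(pm.abundance).to_numpy()
    norm = pm.abundance.to_numpy(dtype=float) / sf
    g = pm.genotype_indicator(contrast_level).astype(bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    a, b = norm[:, g], norm[:, ~g]
    t, p = sps.ttest_ind(a, b, axis=1)
    degenerate = np.isnan(t)
    if degenerate.any():
        log.info("%d proteins with zero variance in both groups; p set to 1", degenerate.sum())
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "protein": pm.abundance.index,
            "mean_asyn": a.mean(axis=1),
            "mean_control": b.mean(axis=1),
            "t": t,
            "p": p,
        }
    ).reset_index(drop=True)


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def longitudinal_lrt(
    pm: ProteinMatrix,
    contrast_level: str = "asyn",
    pseudocount: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genotype likelihood-ratio test in the longitudinal design.

    Per protein, Gaussian linear models on log2(normalized + pseudocount)
    abundance: full ``expression ~ genotype + age`` against base
    ``expression ~ age``; the statistic is twice the log-likelihood
    difference, compared to chi-square with 1 df. The genotype coefficient
    (log2 units) is reported as the effect. Constant expression gives
    statistic 0, p = 1.
    """
    ages = pm.meta["age_days"].to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("ages do not vary; longitudinal test undefined")
    g = pm.genotype_indicator(contrast_level)
    for level in (0.0, 1.0):
        if np.unique(ages[g == level]).size < 2:
            raise ValueError("both genotypes must be observed at >= 2 ages")
    sf = size_factors(pm.abundance).to_numpy()
    Y = np.log2(pm.abundance.to_numpy(dtype=float) / sf + pseudocount)
    n = Y.shape[1]
    X_full = np.column_stack([np.ones(n), g, ages])
    X_base = np.column_stack([np.ones(n), ages])

    stats_, effects, pvals = np.empty(len(Y)), np.empty(len(Y)), np.empty(len(Y))
    for i, y in enumerate(Y):
        if np.allclose(y, y[0]):
            stats_[i], effects[i], pvals[i] = 0.0, 0.0, 1.0
            continue
        beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        sse_f = float(np.sum((y - X_full @ beta_f) ** 2))
        beta_b, *_ = np.linalg.lstsq(X_base, y, rcond=None)
        sse_b = float(np.sum((y - X_base @ beta_b) ** 2))
        lrt = max(2.0 * (_gaussian_loglik(sse_f, n) - _gaussian_loglik(sse_b, n)), 0.0)
        stats_[i] = lrt
        effects[i] = beta_f[1]
        pvals[i] = sps.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
    out = pd.DataFrame(
        {
            "protein": pm.abundance.index,
            "log2fc": effects,
            "stat": stats_,
            "p": pvals,
            "padj": bh_adjust(pvals),
        }
    ).reset_index(drop=True)
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = out["padj"] < padj_threshold
    return out


def restrict_to_homologs(pm: ProteinMatrix, homolog_table: pd.DataFrame) -> ProteinMatrix:
    """Keep proteins whose fly id appears in a homolog table.

    The table needs a ``fly_id`` column (duplicate entries are ignored —
    set semantics). Raises on an empty table or zero overlap.
    """
    if "fly_id" not in homolog_table.columns:
        raise ValueError("homolog table needs a 'fly_id' column")
    wanted = set(homolog_table["fly_id"].dropna().astype(str))
    if not wanted:
        raise ValueError("homolog table is empty")
    if pm.flybase is not None:
        keep = pm.flybase.astype(str).isin(wanted)
        keep = keep.reindex(pm.abundance.index, fill_value=False)
    else:
        keep = pd.Series(pm.abundance.index.astype(str).isin(wanted), index=pm.abundance.index)
    if not keep.any():
        raise ValueError("no overlap between matrix ids and the homolog table")
    ab = pm.abundance.loc[keep.to_numpy()]
    fb = pm.flybase.loc[ab.index] if pm.flybase is not None else None
    return ProteinMatrix(ab, pm.meta.reset_index(drop=True), fb)


def read_abundance(path, sep: str = "\t") -> pd.DataFrame:
    """Read an abundance table: first column protein id, rest sample columns."""
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    return df


def read_sample_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata (sample, genotype, age_days, replicate)."""
    meta = pd.read_csv(path, sep=sep)
    if "sample" not in meta.columns:
        raise ValueError("metadata needs a 'sample' column")
    return meta


def n_unique_proteins(matrix: pd.DataFrame) -> int:
    """Number of distinct protein ids quantified in a dataset."""
    return int(matrix.index.nunique())
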