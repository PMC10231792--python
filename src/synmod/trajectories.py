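"""Nested longitudinal models of climbing-speed trajectories.

For a pair of genotypes measured longitudinally on the same tray, three
nested fixed-effect structures of increasing complexity are fitted to
replicate-level mean speeds:

    (i)   speed ~ genotype
    (ii)  speed ~ genotype + S(age)
    (iii) speed ~ genotype + S(age) + genotype : S(age)

where S(age) is a cubic B-spline basis in age. Each model contributes one
focal test: the genotype main effect in (i) and (ii) (sequential, Type-I)
and the genotype x spline interaction block in (iii). The reported result
for a pair is the most complex model whose focal p-value meets the
significance threshold (default alpha = 5e-5).

Two engines are available: ``ols`` (fixed-effects least squares on
replicate-level records, F tests) and ``random_intercept`` (per-replicate
random intercept fitted by profiled maximum likelihood with a 1-D search
over the variance ratio; focal tests are likelihood-ratio chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.interpolate import BSpline

__all__ = [
    "TrayMismatchError",
    "SingularDesignError",
    "DegenerateContrastError",
    "aggregate_technical",
    "SplineBasis",
    "bspline_basis",
    "SplineConfig",
    "ModelFit",
    "NestedContrast",
    "fit_nested_contrast",
    "select_reported_model",
    "fitted_curves",
    "MODEL_LABELS",
]

MODEL_LABELS = ("genotype", "genotype+time", "genotype*time")


class TrayMismatchError(ValueError):
    """The two genotypes were never assayed on a common tray."""


class SingularDesignError(ValueError):
    """The model matrix is rank deficient."""


class DegenerateContrastError(ValueError):
    """Residual variation is zero; F / likelihood-ratio tests are undefined."""


def aggregate_technical(panel: pd.DataFrame) -> pd.DataFrame:
    """Average technical trials within each (genotype, replicate, age).

    Returns one record per biological replicate per timepoint; the trial
    column is removed. Missing trials are tolerated (plain mean over whatever
    trials are present). Panel metadata (``attrs``) is preserved.
    """
    if "trial" not in panel.columns:
        raise ValueError("panel has no 'trial' column; already aggregated?")
    keys = [c for c in ("genotype", "tray", "replicate", "age_days") if c in panel.columns]
    out = panel.groupby(keys, as_index=False, sort=True)["speed"].mean()
    out.attrs.update(panel.attrs)
    return out


@dataclass(frozen=True)
class SplineBasis:
    """A B-spline basis over an observed age range (Cox-de Boor, open knots).

    Interior knots sit at empirical quantiles of the observed ages; boundary
    knots at the age range limits, each repeated ``degree + 1`` times so the
    basis forms a partition of unity on [min age, max age] (closed at the
    right boundary).
    """

    degree: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    @property
    def knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.r_[
            [lo] * (self.degree + 1), list(self.interior_knots), [hi] * (self.degree + 1)
        ]

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    def design(self, ages: Sequence[float]) -> np.ndarray:
        """Evaluate the basis at ``ages`` (rows sum to 1 on the knot span)."""
        x = np.asarray(ages, dtype=float)
        lo, hi = self.boundary_knots
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"ages outside basis range [{lo}, {hi}]")
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()


def bspline_basis(
    ages: Sequence[float], n_interior_knots: int = 3, degree: int = 3
) -> SplineBasis:
    """Build a B-spline basis from observed ages.

    Interior knots are placed at empirical quantiles ``i / (k + 1)`` of the
    observed age vector. Requires at least ``degree + n_interior_knots + 1``
    distinct ages so the design can be full rank.
    """
    x = np.asarray(ages, dtype=float)
    distinct = np.unique(x)
    needed = degree + n_interior_knots + 1
    if distinct.size < needed:
        raise ValueError(
            f"need >= {needed} distinct ages for degree {degree} with "
            f"{n_interior_knots} interior knots; got {distinct.size}"
        )
    qs = [(i + 1) / (n_interior_knots + 1) for i in range(n_interior_knots)]
    interior = tuple(float(np.quantile(x, q)) for q in qs)
    lo, hi = float(distinct[0]), float(distinct[-1])
    if any(not (lo < k < hi) for k in interior):
        raise ValueError("interior knots collide with the boundary; too few distinct ages")
    return SplineBasis(degree=degree, interior_knots=interior, boundary_knots=(lo, hi))


@dataclass(frozen=True)
class SplineConfig:
    """Requested spline complexity; adapted down when few distinct ages exist."""

    n_interior_knots: int = 3
    degree: int = 3


@dataclass
class ModelFit:
    """One nested model's fit and its focal-term test."""

    label: str
    sse: float
    df_resid: int
    focal_stat: float | None  # F (ols) or LR chi-square (random_intercept)
    focal_df: int | None
    focal_p: float | None
    loglik: float | None = None


@dataclass
class NestedContrast:
    """Three nested-model fits for one genotype pair on one tray."""

    genotype_a: str
    genotype_b: str
    tray: str
    alpha: float
    engine: str
    models: dict  # label -> ModelFit
    ages: np.ndarray  # observed-age grid (sorted unique)
    curves: pd.DataFrame  # fitted model (iii) mean per genotype on the age grid
    basis: SplineBasis | None = None
    _beta3: np.ndarray | None = field(default=None, repr=False)

    def predict(self, grid: Sequence[float]) -> pd.DataFrame:
        """Model (iii) fixed-effect mean speed per genotype on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.ages.min(), self.ages.max()
        if np.any(grid < lo) or np.any(grid > hi):
            raise ValueError(
                f"grid extends outside the observed age range [{lo}, {hi}]; "
                "extrapolation is not supported"
            )
        out = {}
        for name, gval in ((self.genotype_a, 0.0), (self.genotype_b, 1.0)):
            X = _design(grid, np.full(grid.size, gval), self.basis, "genotype*time")
            out[name] = X @ self._beta3
        return pd.DataFrame({"age_days": grid, **out})


def _design(ages, g, basis: SplineBasis | None, label: str) -> np.ndarray:
    """Model matrix for one nested model.

    The first spline column is dropped (the basis sums to one, so keeping all
    columns would be collinear with the intercept).
    """
    n = len(ages)
    cols = [np.ones(n), np.asarray(g, dtype=float)]
    if label in ("genotype+time", "genotype*time"):
        S = basis.design(ages)[:, 1:]
        cols.append(S)
    if label == "genotype*time":
        cols.append(S * np.asarray(g, dtype=float)[:, None])
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit; returns (beta, sse, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def _profiled_ml(X: np.ndarray, y: np.ndarray, block_ids: np.ndarray):
    """Random-intercept linear model by profiled maximum likelihood.

    Profiles the fixed effects and residual variance analytically and
    searches the variance ratio lambda = sigma_b^2 / sigma_eps^2 on a 1-D
    grid + bounded refinement. Exploits the block structure of
    V = I + lambda Z Z' (Z = block indicators): within a block of size m the
    GLS transform subtracts ``theta = 1 - 1/sqrt(1 + lambda m)`` times the
    block mean from every row.

    Returns (loglik, beta, lambda_hat, sigma2_hat).
    """
    n = y.size
    blocks = pd.Series(np.arange(n)).groupby(block_ids, sort=False).indices
    sizes = {b: len(ix) for b, ix in blocks.items()}

    def transform(lam):
        Xt, yt = X.copy(), y.copy()
        logdet = 0.0
        for b, ix in blocks.items():
            m = sizes[b]
            theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * m)
            Xt[ix] -= theta * Xt[ix].mean(axis=0)
            yt[ix] -= theta * yt[ix].mean()
            logdet += np.log1p(lam * m)
        return Xt, yt, logdet

    def negll(log_lam):
        lam = np.exp(log_lam)
        Xt, yt, logdet = transform(lam)
        _, sse, _ = _ols(Xt, yt)
        sigma2 = max(sse / n, 1e-300)
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(-12.0, 8.0), method="bounded")
    lam_hat, ll_hat = float(np.exp(res.x)), -float(res.fun)
    # boundary: no replicate variance at all
    _, sse0, _ = _ols(X, y)
    sigma2_0 = max(sse0 / n, 1e-300)
    ll0 = -0.5 * n * (np.log(2 * np.pi * sigma2_0) + 1.0)
    if ll0 >= ll_hat:
        lam_hat, ll_hat = 0.0, ll0
    Xt, yt, _ = transform(lam_hat)
    beta, sse, _ = _ols(Xt, yt)
    return ll_hat, beta, lam_hat, sse / n


def fit_nested_contrast(
    panel: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    spline: SplineConfig | None = None,
    alpha: float = 5e-5,
    engine: str = "ols",
) -> NestedContrast:
    """Fit the three nested models for one genotype pair.

    ``genotype_a`` is the reference level. The panel must already be
    aggregated over technical trials; the two genotypes must share a tray
    (within-tray analysis) — records from the shared tray(s) are used. When
    fewer than 3 distinct ages are observed, models (ii)/(iii) are disabled
    (their focal p is ``None``) and model selection falls back to (i).
    """
    if engine not in ("ols", "random_intercept"):
        raise ValueError("engine must be 'ols' or 'random_intercept'")
    spline = spline or SplineConfig()
    required = {"genotype", "tray", "replicate", "age_days", "speed"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    if "trial" in panel.columns and panel["trial"].nunique() > 1:
        raise ValueError("aggregate technical trials first (aggregate_technical)")

    trays_a = set(panel.loc[panel["genotype"] == genotype_a, "tray"])
    trays_b = set(panel.loc[panel["genotype"] == genotype_b, "tray"])
    if not trays_a or not trays_b:
        raise ValueError(f"genotype missing from panel: {genotype_a!r} or {genotype_b!r}")
    shared = trays_a & trays_b
    if not shared:
        raise TrayMismatchError(
            f"{genotype_a!r} (trays {sorted(trays_a)}) and {genotype_b!r} "
            f"(trays {sorted(trays_b)}) share no tray; within-tray analysis required"
        )
    tray = sorted(shared)[0]
    sub = panel[
        panel["tray"].isin(shared) & panel["genotype"].isin([genotype_a, genotype_b])
    ].copy()
    dup = sub.duplicated(subset=["genotype", "replicate", "age_days"])
    if dup.any():
        raise ValueError("duplicated (genotype, replicate, age) records after aggregation")

    y = sub["speed"].to_numpy(dtype=float)
    g = (sub["genotype"] == genotype_b).to_numpy(dtype=float)
    ages = sub["age_days"].to_numpy(dtype=float)
    grid = np.unique(ages)

    # Adapt spline complexity to the number of distinct ages so the design
    # stays full rank on small panels.
    n_distinct = grid.size
    basis = None
    if n_distinct >= 3:
        degree = min(spline.degree, n_distinct - 1)
        n_int = max(0, min(spline.n_interior_knots, n_distinct - degree - 1))
        basis = bspline_basis(ages, n_interior_knots=n_int, degree=degree)

    labels = ["genotype"] + (["genotype+time", "genotype*time"] if basis is not None else [])
    X0 = np.ones((y.size, 1))
    designs = {lab: _design(ages, g, basis, lab) for lab in labels}
    for lab, X in designs.items():
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise SingularDesignError(
                f"model {lab!r} design is singular: rank {rank} < {X.shape[1]} columns"
            )

    _, sse_null, _ = _ols(X0, y)
    fits: dict[str, ModelFit] = {}
    ols_beta = {}
    for lab, X in designs.items():
        beta, sse, rank = _ols(X, y)
        ols_beta[lab] = beta
        fits[lab] = ModelFit(lab, sse, int(y.size - rank), None, None, None)
    if fits[labels[-1]].sse <= 1e-12 * max(1.0, float(y @ y)) or fits[labels[-1]].df_resid <= 0:
        raise DegenerateContrastError(
            "zero residual variation: the contrast carries no noise to test against"
        )

    if engine == "ols":
        # Sequential (Type-I) F tests: genotype SS within each model's ANOVA
        # table; denominator is that model's own residual mean square.
        ss_g = sse_null - fits["genotype"].sse
        for lab in labels:
            fit = fits[lab]
            if lab in ("genotype", "genotype+time"):
                num, df_num = ss_g, 1
            else:
                num = fits["genotype+time"].sse - fit.sse
                df_num = designs["genotype*time"].shape[1] - designs["genotype+time"].shape[1]
            mse = fit.sse / fit.df_resid
            F = (num / df_num) / mse
            fit.focal_stat, fit.focal_df = float(F), df_num
            fit.focal_p = float(sps.f.sf(F, df_num, fit.df_resid))
            n = y.size
            fit.loglik = -0.5 * n * (np.log(2 * np.pi * fit.sse / n) + 1.0)
        beta3 = ols_beta[labels[-1]]
    else:
        block = (sub["genotype"].astype(str) + "//" + sub["replicate"].astype(str)).to_numpy()
        ll = {}
        ll["null"], *_ = _profiled_ml(X0, y, block)
        for lab, X in designs.items():
            ll_lab, beta, _, _ = _profiled_ml(X, y, block)
            ll[lab] = ll_lab
            ols_beta[lab] = beta
        if basis is not None:
            X_s = np.column_stack([np.ones(y.size), basis.design(ages)[:, 1:]])
            ll["spline_only"], *_ = _profiled_ml(X_s, y, block)
        for lab in labels:
            fit = fits[lab]
            if lab == "genotype":
                stat, df_num = 2 * (ll[lab] - ll["null"]), 1
            elif lab == "genotype+time":
                stat, df_num = 2 * (ll[lab] - ll["spline_only"]), 1
            else:
                stat = 2 * (ll[lab] - ll["genotype+time"])
                df_num = designs["genotype*time"].shape[1] - designs["genotype+time"].shape[1]
            stat = max(float(stat), 0.0)
            fit.focal_stat, fit.focal_df = stat, df_num
            fit.focal_p = float(sps.chi2.sf(stat, df_num))
            fit.loglik = float(ll[lab])
        beta3 = ols_beta[labels[-1]]

    top = labels[-1]
    contrast = NestedContrast(
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        tray=tray,
        alpha=alpha,
        engine=engine,
        models=fits,
        ages=grid,
        curves=pd.DataFrame(),
        basis=basis,
        _beta3=beta3,
    )
    if basis is not None:
        contrast.curves = contrast.predict(grid)
    else:
        # no time structure: flat fitted means per genotype
        b = ols_beta["genotype"]
        contrast.curves = pd.DataFrame(
            {
                "age_days": grid,
                genotype_a: np.full(grid.size, b[0]),
                genotype_b: np.full(grid.size, b[0] + b[1]),
            }
        )
    return contrast


def select_reported_model(contrast: NestedContrast) -> tuple[str | None, float | None]:
    """Most complex model whose focal p meets the threshold, with its p.

    Returns ``(None, None)`` when no model qualifies.
    """
    for lab in reversed(MODEL_LABELS):
        fit = contrast.models.get(lab)
        if fit is None or fit.focal_p is None:
            continue
        if fit.focal_p <= contrast.alpha:
            return lab, fit.focal_p
    return None, None


def fitted_curves(contrast: NestedContrast, grid: Sequence[float]) -> pd.DataFrame:
    """Model (iii) fixed-effect mean speed per genotype on an age grid.

    The grid must lie within the observed age range (no extrapolation).
    """
    if contrast.basis is None:
        grid = np.asarray(grid, dtype=float)
        lo, hi = contrast.ages.min(), contrast.ages.max()
        if np.any(grid < lo) or np.any(grid > hi):
            raise ValueError("grid extends outside the observed age range")
        base = contrast.curves
        return pd.DataFrame(
            {
                "age_days": grid,
                contrast.genotype_a: np.full(grid.size, base[contrast.genotype_a].iloc[0]),
                contrast.genotype_b: np.full(grid.size, base[contrast.genotype_b].iloc[0]),
            }
        )
    return contrast.predict(grid)
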