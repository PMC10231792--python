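"""Allele- and gene-level modifier calling for the locomotor screen.

An allele is evaluated by two within-tray contrasts: modifier + aSyn versus
aSyn alone (does the manipulation enhance or suppress the aSyn climbing
deficit, ``p_enh``) and modifier alone versus the driver-only control (does
it impair climbing by itself, ``p_alone``). Standalone toxicity is graded
no/mild (not significant), moderate (significant but less extreme than the
aSyn trajectory) or severe (the standalone trajectory crosses below the aSyn
trajectory).

A gene is called a modifier only with consistent evidence from at least two
independent alleles (same direction); modifier genes are classed synergistic
when at least one supporting allele shows no standalone impairment, additive
when all supporting alleles do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectories import (
    DegenerateContrastError,
    NestedContrast,
    SplineConfig,
    fit_nested_contrast,
    select_reported_model,
)

__all__ = [
    "AlleleResult",
    "GeneCall",
    "call_allele",
    "classify_severity",
    "call_gene",
    "screen_summary",
    "conservation_summary",
    "run_screen",
    "ScreenResult",
]

SEVERITIES = ("no_mild", "moderate", "severe")
CROSSING_RULES = ("consecutive", "any", "terminal")


@dataclass
class AlleleResult:
    """Modifier-screen outcome for one allele."""

    allele: str
    gene: str
    p_enh: float  # modifier+aSyn vs aSyn, reported-model p
    direction: str  # enhancer | suppressor | none
    p_alone: float  # modifier alone vs driver-only control, reported-model p
    severity: str  # no_mild | moderate | severe
    alpha: float
    curves: pd.DataFrame | None = None  # common-grid fitted curves (4 genotypes)
    reported_model_enh: str | None = None
    reported_model_alone: str | None = None
    degenerate: bool = False


@dataclass
class GeneCall:
    """Gene-level modifier decision."""

    gene: str
    modifier: bool
    direction: str  # enhancer | suppressor | none
    gene_class: str  # synergistic | additive | unclassified
    supporting_alleles: list = field(default_factory=list)
    n_alleles: int = 0


def _reported_p(contrast: NestedContrast) -> tuple[float, str | None]:
    label, p = select_reported_model(contrast)
    if label is not None:
        return p, label
    ps = [m.focal_p for m in contrast.models.values() if m.focal_p is not None]
    return (min(ps) if ps else 1.0), None


def classify_severity(
    alone_curve: Sequence[float],
    control_curve: Sequence[float],
    asyn_curve: Sequence[float],
    p_alone: float | None,
    alpha: float = 5e-5,
    crossing_rule: str = "consecutive",
) -> str:
    """Grade the standalone toxicity of a genetic manipulation.

    ``no_mild`` when the manipulation is not significantly different from
    control (``p_alone > alpha``). Otherwise ``severe`` when the standalone
    trajectory crosses below the aSyn trajectory (default rule: at >= 2
    consecutive grid ages; alternatives: ``any`` single age, ``terminal``
    age only), else ``moderate``. Curves must share one observed-age grid.
    """
    alone = np.asarray(alone_curve, dtype=float)
    control = np.asarray(control_curve, dtype=float)
    asyn = np.asarray(asyn_curve, dtype=float)
    if not (alone.shape == control.shape == asyn.shape):
        raise ValueError("curves must be evaluated on a common age grid")
    if crossing_rule not in CROSSING_RULES:
        raise ValueError(f"crossing_rule must be one of {CROSSING_RULES}")
    if p_alone is None or p_alone > alpha:
        return "no_mild"
    below = alone < asyn
    if crossing_rule == "any":
        crossed = bool(below.any())
    elif crossing_rule == "terminal":
        crossed = bool(below[-1])
    else:  # >= 2 consecutive ages; single-point dips are treated as noise
        crossed = bool(np.any(below[1:] & below[:-1]))
    return "severe" if crossed else "moderate"


def call_allele(
    panel: pd.DataFrame,
    allele: str,
    gene: str,
    with_asyn: str,
    alone: str,
    asyn_only: str = "asyn",
    control: str = "control",
    spline: SplineConfig | None = None,
    alpha: float = 5e-5,
    engine: str = "ols",
    crossing_rule: str = "consecutive",
) -> AlleleResult:
    """Evaluate one allele's interaction with aSyn and standalone toxicity.

    All four genotypes must be present on a shared tray. A contrast with zero
    residual variation (e.g. literally duplicated records) is flagged
    degenerate and called non-significant rather than fitted.
    """
    for name in (with_asyn, alone, asyn_only, control):
        if name not in set(panel["genotype"]):
            raise ValueError(f"genotype {name!r} missing from panel")
    try:
        c_enh = fit_nested_contrast(panel, asyn_only, with_asyn, spline, alpha, engine)
        c_alone = fit_nested_contrast(panel, control, alone, spline, alpha, engine)
    except DegenerateContrastError:
        return AlleleResult(
            allele, gene, p_enh=1.0, direction="none", p_alone=1.0,
            severity="no_mild", alpha=alpha, degenerate=True,
        )
    p_enh, model_enh = _reported_p(c_enh)
    p_alone, model_alone = _reported_p(c_alone)

    if not np.array_equal(c_enh.ages, c_alone.ages):
        raise ValueError("the two contrasts observe different age grids")
    grid = c_enh.ages
    asyn_curve = c_enh.curves[asyn_only].to_numpy()
    with_curve = c_enh.curves[with_asyn].to_numpy()
    control_curve = c_alone.curves[control].to_numpy()
    alone_curve = c_alone.curves[alone].to_numpy()

    if p_enh > alpha:
        direction = "none"
    else:
        # unweighted mean fitted difference over the observed-age grid
        direction = "enhancer" if (with_curve - asyn_curve).mean() < 0 else "suppressor"
    severity = classify_severity(
        alone_curve, control_curve, asyn_curve, p_alone, alpha, crossing_rule
    )
    curves = pd.DataFrame(
        {
            "age_days": grid,
            "control": control_curve,
            "asyn": asyn_curve,
            "alone": alone_curve,
            "with_asyn": with_curve,
        }
    )
    return AlleleResult(
        allele, gene, p_enh=p_enh, direction=direction, p_alone=p_alone,
        severity=severity, alpha=alpha, curves=curves,
        reported_model_enh=model_enh, reported_model_alone=model_alone,
    )


def call_gene(allele_results: Sequence[AlleleResult]) -> GeneCall:
    """Combine allele results into a gene-level modifier call.

    A gene is a modifier only when >= 2 alleles are significant with the same
    direction (the two-strain consistency rule); opposite-direction
    significances do not combine. The call is invariant to allele order.
    """
    if len(allele_results) == 0:
        raise ValueError("at least one allele result is required")
    genes = {r.gene for r in allele_results}
    if len(genes) != 1:
        raise ValueError(f"allele results span multiple genes: {sorted(genes)}")
    gene = genes.pop()
    results = sorted(allele_results, key=lambda r: r.allele)
    by_dir = {"enhancer": [], "suppressor": []}
    for r in results:
        if r.direction in by_dir and r.p_enh <= r.alpha:
            by_dir[r.direction].append(r)
    direction, supporting = max(
        by_dir.items(), key=lambda kv: (len(kv[1]), kv[0] == "enhancer")
    )
    if len(supporting) < 2:
        return GeneCall(gene, False, "none", "unclassified", [], len(results))
    severities = [r.severity for r in supporting]
    gene_class = "synergistic" if "no_mild" in severities else "additive"
    return GeneCall(
        gene, True, direction, gene_class, [r.allele for r in supporting], len(results)
    )


def screen_summary(gene_calls: Sequence[GeneCall]) -> tuple[pd.DataFrame, dict]:
    """One row per gene plus headline counts of the screen outcome."""
    genes = [c.gene for c in gene_calls]
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene ids in gene calls: {dups}")
    table = pd.DataFrame(
        {
            "gene": genes,
            "modifier": [c.modifier for c in gene_calls],
            "direction": [c.direction for c in gene_calls],
            "class": [c.gene_class for c in gene_calls],
            "supporting_alleles": [",".join(c.supporting_alleles) for c in gene_calls],
            "n_alleles": [c.n_alleles for c in gene_calls],
        }
    ).sort_values("gene", ignore_index=True)
    counts = {
        "n_genes": len(gene_calls),
        "n_modifiers": int(table["modifier"].sum()),
        "n_enhancers": int((table["direction"] == "enhancer").sum()),
        "n_suppressors": int((table["direction"] == "suppressor").sum()),
        "n_synergistic": int((table["class"] == "synergistic").sum()),
        "n_additive": int((table["class"] == "additive").sum()),
    }
    return table, counts


def conservation_summary(homolog_table: pd.DataFrame) -> dict:
    """Screen-design conservation summary from a homolog table.

    The table has one row per human gene with either a ``conserved`` boolean
    column or a ``fly_gene`` column (empty/NaN when not conserved; multiple
    fly homologs separated by ``;``). Reports the number of human genes, how
    many are conserved in the fly, the conservation percentage (rounded to
    the integer printed in screen-design summaries), and the count of
    distinct fly homologs.
    """
    df = homolog_table
    if "human_gene" not in df.columns:
        raise ValueError("homolog table needs a 'human_gene' column")
    n_human = int(df["human_gene"].nunique())
    if "conserved" in df.columns:
        conserved_mask = df["conserved"].astype(bool)
    elif "fly_gene" in df.columns:
        conserved_mask = df["fly_gene"].notna() & (df["fly_gene"].astype(str).str.strip() != "")
    else:
        raise ValueError("homolog table needs a 'conserved' or 'fly_gene' column")
    conserved_genes = df.loc[conserved_mask, "human_gene"].nunique()
    out = {
        "n_human_genes": n_human,
        "n_conserved": int(conserved_genes),
        "pct_conserved": int(round(100.0 * conserved_genes / n_human)),
    }
    if "fly_gene" in df.columns:
        fly = (
            df.loc[conserved_mask, "fly_gene"]
            .astype(str)
            .str.split(";")
            .explode()
            .str.strip()
        )
        out["n_fly_homologs"] = int(fly[fly != ""].nunique())
    return out


@dataclass
class ScreenResult:
    """Full screen outcome: per-allele results, gene calls, and tables."""

    allele_results: list
    gene_calls: list
    stats_table: pd.DataFrame  # per-contrast statistics (S5-style)
    gene_table: pd.DataFrame
    counts: dict


def run_screen(
    panel: pd.DataFrame,
    allele_table: pd.DataFrame,
    asyn_only: str = "asyn",
    control: str = "control",
    spline: SplineConfig | None = None,
    alpha: float = 5e-5,
    engine: str = "ols",
    crossing_rule: str = "consecutive",
) -> ScreenResult:
    """Call every allele and gene in an aggregated trajectory panel.

    ``allele_table`` has columns ``allele`` and ``gene`` and optionally
    ``genotype_with_asyn`` / ``genotype_alone`` (defaulting to
    ``{allele}_asyn`` / ``{allele}_alone``).
    """
    for col in ("allele", "gene"):
        if col not in allele_table.columns:
            raise ValueError(f"allele table needs a {col!r} column")
    allele_results: list[AlleleResult] = []
    rows = []
    for _, row in allele_table.iterrows():
        with_asyn = row.get("genotype_with_asyn", f"{row['allele']}_asyn")
        alone = row.get("genotype_alone", f"{row['allele']}_alone")
        res = call_allele(
            panel, str(row["allele"]), str(row["gene"]), with_asyn, alone,
            asyn_only=asyn_only, control=control, spline=spline, alpha=alpha,
            engine=engine, crossing_rule=crossing_rule,
        )
        allele_results.append(res)
        rows.append(
            {
                "allele": res.allele,
                "gene": res.gene,
                "p_enh": res.p_enh,
                "reported_model_enh": res.reported_model_enh,
                "direction": res.direction,
                "p_alone": res.p_alone,
                "reported_model_alone": res.reported_model_alone,
                "severity": res.severity,
                "degenerate": res.degenerate,
            }
        )
    gene_calls = [
        call_gene([r for r in allele_results if r.gene == gene])
        for gene in sorted({r.gene for r in allele_results})
    ]
    gene_table, counts = screen_summary(gene_calls)
    return ScreenResult(allele_results, gene_calls, pd.DataFrame(rows), gene_table, counts)
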