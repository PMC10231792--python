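"""Synthetic-data generators with known ground truth.

Everything downstream (trajectory models, modifier calling, proteomics DE,
vacuole quantification) is exercised on data from these generators, whose
parameters define the study conditions: 6-8 biological replicates of 15
animals, 5 technical trials per timepoint, >= 11 timepoints over 30 days of
aging, genotype classes {control, aSyn, modifier alone, modifier + aSyn}
arranged in trays; 8-vs-8 cross-sectional and 5-replicate x 6-timepoint
longitudinal proteomes; retina sections with disk-shaped vacuoles.

The trajectory model: climbing speed declines linearly with age in controls;
pan-neuronal aSyn adds a logistic (sigmoidal in age) deficit; a modifier can
add a standalone deficit (additive toxicity, amplitude ``beta_tox``) and/or
multiplicatively scale the aSyn deficit when co-expressed (``beta_int``,
synergistic interaction). Replicates carry a persistent random intercept
(the same vial of flies is tracked over ages) and each technical trial adds
independent residual noise. Speeds are truncated at zero.

Seeds are mandatory; identical (config, seed) gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSpec",
    "ScreenSimConfig",
    "SimTruth",
    "simulate_screen_trajectories",
    "make_screen_config",
    "CrossSectionalDesign",
    "LongitudinalDesign",
    "simulate_proteome",
    "simulate_retina_image",
]

DEFAULT_TIMEPOINTS = (1.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0)


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype in a tray.

    ``beta_tox`` is the standalone additive deficit amplitude (speed units at
    full expression of the aging sigmoid); ``beta_int`` scales the aSyn
    deficit multiplicatively when aSyn is present (0 = plain aSyn toxicity).
    """

    name: str
    asyn: bool = False
    beta_tox: float = 0.0
    beta_int: float = 0.0


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generating parameters of the locomotor screen simulator.

    Defaults emulate the screen's replicate structure (8 biological
    replicates of 15 flies, 5 technical trials, 11 timepoints over 30 days)
    and a progressive aSyn climbing deficit reaching ~4 speed units by day 30
    on a baseline of 10.
    """

    trays: Mapping[str, Sequence[GenotypeSpec]]
    seed: int
    n_bio_replicates: int = 8
    n_flies_per_replicate: int = 15
    n_tech_trials: int = 5
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    baseline_speed: float = 10.0  # speed units at age 0
    aging_slope: float = 0.1  # speed units lost per day, all genotypes
    deficit_amplitude: float = 4.0  # aSyn deficit plateau, speed units
    deficit_midpoint: float = 12.0  # day at which half the deficit is reached
    deficit_steepness: float = 3.0  # days; logistic scale parameter
    replicate_intercept_sd: float = 0.25  # sigma_b, speed units
    residual_sd: float = 0.5  # sigma_eps per technical trial, speed units
    speed_unit: str = "speed units"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is required")
        for n in (self.n_bio_replicates, self.n_flies_per_replicate, self.n_tech_trials):
            if n < 1:
                raise ValueError("all counts must be >= 1")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be positive and strictly increasing")
        if self.replicate_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.deficit_steepness <= 0:
            raise ValueError("deficit_steepness must be > 0")

    def aging_sigmoid(self, t):
        """Unit logistic ramp u(t) in (0, 1), non-decreasing in age."""
        t = np.asarray(t, dtype=float)
        return 1.0 / (1.0 + np.exp(-(t - self.deficit_midpoint) / self.deficit_steepness))

    def asyn_deficit(self, t):
        """aSyn climbing deficit delta(t) = amplitude * u(t)."""
        return self.deficit_amplitude * self.aging_sigmoid(t)

    def mean_curve(self, spec: GenotypeSpec, t):
        """True mean climbing speed of a genotype at ages ``t`` (untruncated)."""
        t = np.asarray(t, dtype=float)
        mu = self.baseline_speed - self.aging_slope * t
        mu = mu - spec.beta_tox * self.aging_sigmoid(t)
        if spec.asyn:
            mu = mu - (1.0 + spec.beta_int) * self.asyn_deficit(t)
        return mu


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    mean_curves: dict = field(default_factory=dict)  # genotype -> array over timepoints
    gene_labels: dict = field(default_factory=dict)  # gene -> {null, additive, synergistic}
    protein_effects: dict = field(default_factory=dict)  # protein -> (log2fc, age_slope)
    vacuoles: list = field(default_factory=list)  # (cx_px, cy_px, radius_um, area_um2)

    def to_json_dict(self) -> dict:
        return {
            "mean_curves": {g: list(np.asarray(v)) for g, v in self.mean_curves.items()},
            "gene_labels": dict(self.gene_labels),
            "protein_effects": {k: list(v) for k, v in self.protein_effects.items()},
            "vacuoles": [list(v) for v in self.vacuoles],
        }


def simulate_screen_trajectories(config: ScreenSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a locomotor-screen trajectory panel.

    Returns one record per (genotype, biological replicate, technical trial,
    timepoint): ``speed = mu_g(t) + b_r + eps`` with
    ``b_r ~ N(0, sigma_b^2)`` constant within a replicate across ages and
    trials, ``eps ~ N(0, sigma_eps^2)`` independent per record, truncated
    at 0.
    """
    rng = np.random.default_rng(config.seed)
    ages = np.asarray(config.timepoints, dtype=float)
    truth = SimTruth()
    rows = []
    for tray, specs in config.trays.items():
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate genotype names in tray {tray!r}")
        for spec in specs:
            mu = config.mean_curve(spec, ages)
            truth.mean_curves[spec.name] = mu
            for rep in range(1, config.n_bio_replicates + 1):
                b = rng.normal(0.0, config.replicate_intercept_sd)
                eps = rng.normal(
                    0.0, config.residual_sd, size=(config.n_tech_trials, ages.size)
                )
                speed = np.clip(mu[None, :] + b + eps, 0.0, None)
                for trial in range(1, config.n_tech_trials + 1):
                    for j, age in enumerate(ages):
                        rows.append(
                            (spec.name, tray, f"r{rep}", f"t{trial}", age, speed[trial - 1, j])
                        )
    panel = pd.DataFrame(
        rows, columns=["genotype", "tray", "replicate", "trial", "age_days", "speed"]
    )
    panel.attrs["speed_unit"] = config.speed_unit
    panel.attrs["n_flies_per_replicate"] = config.n_flies_per_replicate
    return panel, truth


@dataclass(frozen=True)
class ModifierGeneSpec:
    """A candidate modifier gene with per-allele interaction/toxicity effects."""

    gene: str
    alleles: Sequence[str]
    beta_int: Sequence[float]  # per-allele multiplicative scaling of the aSyn deficit
    beta_tox: Sequence[float]  # per-allele standalone deficit amplitude


def make_screen_config(
    genes: Sequence[ModifierGeneSpec],
    seed: int,
    control_name: str = "control",
    asyn_name: str = "asyn",
    **overrides,
) -> tuple[ScreenSimConfig, dict]:
    """Build a tray-per-gene screen configuration.

    Each gene occupies one tray containing the driver-only control, the aSyn
    reference, and for every allele the modifier-alone and modifier+aSyn
    genotypes — matching the within-tray contrast requirement. Returns the
    config and the true gene labels ({null, additive, synergistic}: a gene is
    a true modifier if any allele has ``beta_int > 0``; synergistic if at
    least one modifying allele has ``beta_tox == 0``).
    """
    trays = {}
    labels = {}
    for g in genes:
        specs = [
            GenotypeSpec(control_name, asyn=False),
            GenotypeSpec(asyn_name, asyn=True),
        ]
        modifying_tox = []
        for allele, bi, bt in zip(g.alleles, g.beta_int, g.beta_tox):
            specs.append(GenotypeSpec(f"{allele}_alone", asyn=False, beta_tox=bt))
            specs.append(GenotypeSpec(f"{allele}_asyn", asyn=True, beta_int=bi, beta_tox=bt))
            if bi > 0:
                modifying_tox.append(bt)
        trays[f"tray_{g.gene}"] = specs
        if len(modifying_tox) >= 2:
            labels[g.gene] = "synergistic" if any(bt == 0 for bt in modifying_tox) else "additive"
        else:
            labels[g.gene] = "null"
    return ScreenSimConfig(trays=trays, seed=seed, **overrides), labels


def default_recovery_genes(
    n_synergistic: int = 5,
    n_additive: int = 5,
    n_null: int = 10,
    beta_int: float = 0.5,
    beta_tox: float = 1.5,
) -> tuple[list[ModifierGeneSpec], pd.DataFrame]:
    """Canonical recovery-benchmark gene set (2 alleles per gene).

    Synergistic genes scale the aSyn deficit (``beta_int``) without
    standalone toxicity; additive genes carry both; null genes neither.
    Returns the gene specs and the matching allele->gene table.
    """
    specs = []
    for prefix, n, bi, bt in (
        ("syn", n_synergistic, beta_int, 0.0),
        ("add", n_additive, beta_int, beta_tox),
        ("null", n_null, 0.0, 0.0),
    ):
        for i in range(n):
            gene = f"{prefix}{i + 1}"
            specs.append(
                ModifierGeneSpec(
                    gene, [f"{gene}a1", f"{gene}a2"], beta_int=[bi, bi], beta_tox=[bt, bt]
                )
            )
    alleles = pd.DataFrame(
        [{"allele": a, "gene": g.gene} for g in specs for a in g.alleles]
    )
    return specs, alleles


# ---------------------------------------------------------------------------
# Proteome simulation


@dataclass(frozen=True)
class CrossSectionalDesign:
    """Single-age two-genotype design (discovery-style: 8 vs 8 at day 10)."""

    n_per_genotype: int = 8
    age_days: float = 10.0


@dataclass(frozen=True)
class LongitudinalDesign:
    """Replicates x ages two-genotype design (replication-style: 5 x 6 ages)."""

    n_replicates: int = 5
    ages: Sequence[float] = (2.0, 5.0, 9.0, 13.0, 17.0, 21.0)


def simulate_proteome(
    n_proteins: int,
    design: CrossSectionalDesign | LongitudinalDesign,
    effects: Mapping[int, tuple[float, float]] | None,
    dispersion: float | Sequence[float],
    seed: int,
    base_log2_mean_range: tuple[float, float] = (7.0, 13.0),
):
    """Simulate a TMT-style protein abundance matrix with known truth.

    Counts are negative-binomial with mean
    ``exp(beta0 + log2FC * ln2 * [genotype == asyn] + slope * age)`` and the
    stated per-protein dispersion (variance ``mu + disp * mu^2``; dispersion 0
    falls back to Poisson). ``effects`` maps protein index -> (log2FC,
    age_slope); unlisted proteins are null.

    Returns ``(matrix, meta, truth)``: matrix is proteins x samples
    (DataFrame), meta has columns sample, genotype, age_days, replicate.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if seed is None:
        raise ValueError("seed is required")
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_proteins,)).copy()
    if np.any(disp < 0):
        raise ValueError("dispersion must be >= 0")
    effects = dict(effects or {})

    if isinstance(design, CrossSectionalDesign):
        genotypes = ["control"] * design.n_per_genotype + ["asyn"] * design.n_per_genotype
        ages = [design.age_days] * len(genotypes)
        reps = list(range(1, design.n_per_genotype + 1)) * 2
    else:
        genotypes, ages, reps = [], [], []
        for g in ("control", "asyn"):
            for age in design.ages:
                for r in range(1, design.n_replicates + 1):
                    genotypes.append(g)
                    ages.append(float(age))
                    reps.append(r)
    samples = [f"s{i + 1:02d}" for i in range(len(genotypes))]
    meta = pd.DataFrame(
        {"sample": samples, "genotype": genotypes, "age_days": ages, "replicate": reps}
    )

    rng = np.random.default_rng(seed)
    beta0 = rng.uniform(*base_log2_mean_range, size=n_proteins) * np.log(2.0)
    is_asyn = (meta["genotype"] == "asyn").to_numpy().astype(float)
    age = meta["age_days"].to_numpy()
    age_c = age - age.mean()  # center so beta0 is the grand log-mean

    truth = SimTruth()
    counts = np.zeros((n_proteins, len(samples)))
    for i in range(n_proteins):
        lfc, slope = effects.get(i, (0.0, 0.0))
        mu = np.exp(beta0[i] + lfc * np.log(2.0) * is_asyn + slope * age_c)
        if disp[i] > 0:
            n_nb = 1.0 / disp[i]
            counts[i] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
        else:
            counts[i] = rng.poisson(mu)
        truth.protein_effects[f"P{i + 1:05d}"] = (lfc, slope)
    matrix = pd.DataFrame(counts, index=[f"P{i + 1:05d}" for i in range(n_proteins)], columns=samples)
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Retina image simulation


def simulate_retina_image(
    width: int,
    height: int,
    pixel_size_um: float,
    vacuoles: Sequence[tuple[float, float, float]],
    tissue_mask: str | np.ndarray = "full",
    noise_sd: float = 0.0,
    seed: int = 0,
    background: int = 20000,
    foreground: int = 50000,
):
    """Render a synthetic retinal section with disk-shaped vacuoles.

    Vacuoles are given as ``(cx_px, cy_px, radius_um)`` and rendered as
    high-intensity disks on a darker tissue background (vacuoles appear pale
    in H&E sections), returned as a 16-bit grayscale array. ``tissue_mask``
    is ``"full"``, ``"ellipse"`` (inscribed in the frame), or a boolean
    array. Truth stores the analytic disk areas in um^2.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if isinstance(tissue_mask, str):
        if tissue_mask == "full":
            mask = np.ones((height, width), dtype=bool)
        elif tissue_mask == "ellipse":
            yy, xx = np.mgrid[0:height, 0:width]
            cy, cx = (height - 1) / 2, (width - 1) / 2
            mask = ((xx - cx) / (width / 2)) ** 2 + ((yy - cy) / (height / 2)) ** 2 <= 1.0
        else:
            raise ValueError("tissue_mask must be 'full', 'ellipse' or a boolean array")
    else:
        mask = np.asarray(tissue_mask, dtype=bool)
        if mask.shape != (height, width):
            raise ValueError("tissue_mask shape must match (height, width)")

    yy, xx = np.mgrid[0:height, 0:width]
    img = np.full((height, width), float(background))
    truth = SimTruth()
    for cx, cy, r_um in vacuoles:
        if r_um <= 0:
            raise ValueError("vacuole radii must be > 0")
        r_px = r_um / pixel_size_um
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < height and 0 <= ix < width) or not mask[iy, ix]:
            raise ValueError(f"vacuole center ({cx}, {cy}) lies outside the tissue mask")
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        img[disk & mask] = float(foreground)
        truth.vacuoles.append((float(cx), float(cy), float(r_um), float(np.pi * r_um**2)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    img[~mask] = 0
    return img, mask, truth
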