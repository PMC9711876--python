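"""Synthetic cohorts with planted, recoverable structure.

Every generator is a pure function of its config (which carries the seed),
so fixtures regenerate bit-identically. The generators emulate the
statistical structure the analysis assumes — an AR-high subpopulation whose
panel genes rank high, treatment-induced AR downregulation in all samples,
MYC suppression that switches on above the biomarker cutoff, stratum-
dependent survival, and two-stain slides with known compartment
concentrations — not the gene-level values of any real cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clinical_stats
from .ar_activity import score_cohort
from .expression import ExpressionMatrix, GenePanel, default_panel
from .ihc_quant import (
    CompartmentMasks,
    IhcImage,
    StainModel,
    default_stain_model,
    od_to_rgb,
    recompose_stains,
)

logger = logging.getLogger(__name__)

#: transcripts co-regulated with MYC through the shared 8q24 enhancer domain
COREGULATED_GENES = ("PCAT1", "PVT1")
SPECIAL_GENES = ("AR", "MYC") + COREGULATED_GENES


@dataclass(frozen=True)
class CohortSimConfig:
    """Expression / treatment / survival simulation parameters.

    Defaults encode the emulated study conditions: a 5,000-gene transcriptome,
    a biomarker-positive fraction near the reported 36.5% prevalence, a
    2 log2-unit panel up-shift in AR-high samples, halving of AR mRNA on
    treatment, hinge-type MYC suppression above score 0.6, and a three-fold
    survival hazard advantage for the high-activity stratum.
    """

    n_genes: int = 5000
    n_samples: int = 50
    fraction_ar_high: float = 0.365
    panel_shift: float = 2.0  # delta, log2 units
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    ar_downregulation_factor: float = 0.5  # on/pre AR mRNA ratio
    myc_suppression_slope: float = 5.0  # beta, log2 units per score unit
    myc_noise_sd: float = 0.3  # log2 units
    score_cutoff: float = 0.6
    baseline_hazard: float = 0.058  # per month (~12-month median)
    hazard_ratio: float = 3.0  # hazard(low stratum) / hazard(high stratum)
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_ar_high", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not np.isfinite([self.panel_shift, self.myc_suppression_slope]).all():
            raise ValueError("panel_shift and myc_suppression_slope must be finite")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class IhcSimConfig:
    """Two-stain slide simulation parameters (concentrations in OD units)."""

    shape: tuple[int, int] = (160, 160)
    n_nuclei: int = 20
    nucleus_radius: tuple[int, int] = (5, 8)  # inclusive uniform range, px
    cytoplasm_width: int = 4
    hematoxylin_nuclear: float = 0.7
    hematoxylin_cytoplasmic: float = 0.1
    dab_nuclear: float = 0.6
    dab_cytoplasmic: float = 0.3
    dab_nuclear_classes: tuple[float, ...] | None = None  # per-cell draw set
    noise_sd: float = 0.01  # intensity noise, fraction of I0
    white_level: float = 255.0
    max_placement_tries: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius[0] <= 0:
            raise ValueError("nucleus radii must be positive")
        for name in ("hematoxylin_nuclear", "hematoxylin_cytoplasmic",
                     "dab_nuclear", "dab_cytoplasmic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _gene_names(n_genes: int, panel: GenePanel) -> list[str]:
    names = list(panel) + [g for g in SPECIAL_GENES if g not in set(panel)]
    if n_genes < len(names) + 1:
        raise ValueError("n_genes too small for panel plus marker genes")
    names += [f"GENE{i:05d}" for i in range(n_genes - len(names))]
    return names


def generate_expression_cohort(
    config: CohortSimConfig, panel: GenePanel | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal TPM cohort with the panel up-shifted in AR-high samples.

    Returns the matrix and a truth table (sample_id, ar_high).
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes, panel)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    log2x = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                       size=(config.n_genes, config.n_samples))
    n_high = int(round(config.fraction_ar_high * config.n_samples))
    high_idx = rng.permutation(config.n_samples)[:n_high]
    panel_rows = [genes.index(g) for g in panel]
    log2x[np.ix_(panel_rows, high_idx)] += config.panel_shift
    matrix = ExpressionMatrix(pd.DataFrame(2.0 ** log2x, index=genes, columns=samples))
    truth = pd.DataFrame({
        "sample_id": samples,
        "ar_high": np.isin(np.arange(config.n_samples), high_idx),
    })
    return matrix, truth


def generate_paired_cohort(
    config: CohortSimConfig, panel: GenePanel | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Pre/on-treatment pair with planted treatment effects.

    On treatment: AR mRNA is multiplied by the downregulation factor in all
    samples; the MYC log2 change is -beta * max(0, score - cutoff) plus
    noise; the 8q24 co-regulated transcripts (PCAT1, PVT1) carry the same
    deterministic suppression signal plus their own independent noise, so
    their change tracks the MYC change exactly when suppression is planted
    and is uncorrelated with it under beta = 0.
    """
    panel = panel or default_panel()
    pre, truth = generate_expression_cohort(config, panel)
    rng = np.random.default_rng([config.seed, 1])
    scores = np.array([s.score for s in score_cohort(pre, panel, cutoff=config.score_cutoff)])
    hinge = np.maximum(0.0, scores - config.score_cutoff)
    signal = -config.myc_suppression_slope * hinge
    on = pre.data.copy()
    on.loc["AR"] *= config.ar_downregulation_factor
    deltas = {"MYC": signal + rng.normal(0.0, config.myc_noise_sd, scores.size)}
    for gene in COREGULATED_GENES:
        deltas[gene] = signal + rng.normal(0.0, config.myc_noise_sd, scores.size)
    for gene, d in deltas.items():
        on.loc[gene] *= 2.0 ** d
    truth = truth.assign(
        score_pre=scores,
        hinge=hinge,
        delta_myc_log2=deltas["MYC"],
        **{f"delta_{g.lower()}_log2": deltas[g] for g in COREGULATED_GENES},
    )
    return pre, ExpressionMatrix(on), truth


def generate_survival(
    ar_high: np.ndarray, config: CohortSimConfig, *, endpoint_seed: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with stratum hazards; independent exponential
    censoring tuned so the expected censored fraction equals the configured
    rate. Returns (observed times, event indicators)."""
    if config.baseline_hazard <= 0 or config.hazard_ratio <= 0:
        raise ValueError("hazards must be positive")
    ar_high = np.asarray(ar_high, dtype=bool)
    rng = np.random.default_rng([config.seed, endpoint_seed])
    hazard = np.where(ar_high, config.baseline_hazard / config.hazard_ratio,
                      config.baseline_hazard)
    event_times = rng.exponential(1.0 / hazard)
    if config.censoring_rate <= 0:
        return event_times, np.ones(ar_high.size, dtype=bool)
    # P(censor first) = hc / (hc + h) = rate  =>  hc = h * rate / (1 - rate)
    censor_hazard = hazard * config.censoring_rate / (1.0 - config.censoring_rate)
    censor_times = rng.exponential(1.0 / censor_hazard)
    observed = np.minimum(event_times, censor_times)
    return observed, event_times <= censor_times


def generate_clinical_table(
    truth: pd.DataFrame, config: CohortSimConfig
) -> pd.DataFrame:
    """Per-patient endpoint table consistent with the planted strata.

    AR-high patients mostly respond (deep PSA and volume declines, MYC and
    Ki-67 H-score suppression); AR-low patients mostly progress. Survival
    times come from :func:`generate_survival` per endpoint.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = len(truth)
    ar_high = truth["ar_high"].to_numpy(dtype=bool)
    psa_pre = np.exp(rng.normal(3.0, 1.0, n)) + 1.0
    psa_pct = np.where(ar_high, rng.normal(-70, 15, n), rng.normal(10, 30, n))
    psa_pct = np.clip(psa_pct, -99.5, None)
    vol_pre = np.exp(rng.normal(8.0, 0.7, n))
    vol_pct = np.where(ar_high, rng.normal(-45, 12, n), rng.normal(5, 18, n))
    vol_pct = np.clip(vol_pct, -99.5, None)
    myc_pre = np.clip(rng.normal(220, 40, n), 0, 300)
    myc_on = np.clip(myc_pre * np.where(ar_high, rng.uniform(0.05, 0.4, n),
                                        rng.uniform(0.8, 1.1, n)), 0, 300)
    ki67_pre = np.clip(rng.normal(150, 40, n), 0, 300)
    ki67_on = np.clip(ki67_pre * np.where(ar_high, rng.uniform(0.1, 0.5, n),
                                          rng.uniform(0.8, 1.15, n)), 0, 300)
    rpfs_t, rpfs_e = generate_survival(ar_high, config, endpoint_seed=4)
    os_t, os_e = generate_survival(ar_high, config, endpoint_seed=5)
    frame = pd.DataFrame({
        "patient_id": truth["sample_id"],
        "psa_pre": psa_pre,
        "psa_on": psa_pre * (1.0 + psa_pct / 100.0),
        "tumor_volume_pre": vol_pre,
        "tumor_volume_on": vol_pre * (1.0 + vol_pct / 100.0),
        "rpfs_months": rpfs_t,
        "rpfs_event": rpfs_e.astype(int),
        "os_months": os_t * 2.0,  # OS runs longer than rPFS
        "os_event": os_e.astype(int),
        "myc_hscore_pre": myc_pre,
        "myc_hscore_on": myc_on,
        "ki67_hscore_pre": ki67_pre,
        "ki67_hscore_on": ki67_on,
    })
    return frame


# ---------------------------------------------------------------------------
# IHC slides


def generate_ihc_image(
    config: IhcSimConfig, stain_model: StainModel | None = None
) -> tuple[IhcImage, CompartmentMasks, dict]:
    """Render a two-stain slide of non-overlapping nuclei with cytoplasm
    annuli and known per-compartment stain concentrations.

    Per-cell nuclear DAB is ``dab_nuclear`` unless ``dab_nuclear_classes``
    is given, in which case each cell draws uniformly from those values
    (used to plant H-score bin fractions). Returns the image, ground-truth
    masks, and a truth dict with the concentration maps and per-cell DAB.
    """
    model = stain_model or default_stain_model()
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    labels = np.zeros((h, w), dtype=np.uint8)
    cell_ids = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    centers: list[tuple[int, int, int]] = []
    margin = config.nucleus_radius[1] + config.cytoplasm_width + 1
    tries = 0
    while len(centers) < config.n_nuclei:
        if tries >= config.max_placement_tries:
            raise RuntimeError(
                f"placed only {len(centers)}/{config.n_nuclei} nuclei "
                f"after {tries} tries"
            )
        tries += 1
        r = int(rng.integers(config.nucleus_radius[0], config.nucleus_radius[1] + 1))
        y = int(rng.integers(margin, h - margin))
        x = int(rng.integers(margin, w - margin))
        outer = r + config.cytoplasm_width
        if any((y - yc) ** 2 + (x - xc) ** 2 < (outer + rc + config.cytoplasm_width + 1) ** 2
               for yc, xc, rc in centers):
            continue
        centers.append((y, x, r))
        dist2 = (rr - y) ** 2 + (cc - x) ** 2
        labels[dist2 <= r**2] = 1
        ring = (dist2 > r**2) & (dist2 <= outer**2)
        labels[ring] = 2
        cell_ids[dist2 <= outer**2] = len(centers)
    if config.dab_nuclear_classes is not None:
        per_cell_dab = rng.choice(np.asarray(config.dab_nuclear_classes, float),
                                  size=len(centers))
    else:
        per_cell_dab = np.full(len(centers), config.dab_nuclear)
    conc = np.zeros((h, w, len(model.names)), dtype=float)
    hem, dab = model.stain_index("hematoxylin"), model.stain_index("dab")
    nucleus, cytoplasm = labels == 1, labels == 2
    conc[nucleus, hem] = config.hematoxylin_nuclear
    conc[cytoplasm, hem] = config.hematoxylin_cytoplasmic
    dab_map = np.zeros((h, w))
    for i in range(len(centers)):
        dab_map[(cell_ids == i + 1) & nucleus] = per_cell_dab[i]
    dab_map[cytoplasm] = config.dab_cytoplasmic
    conc[..., dab] = dab_map
    od = recompose_stains(conc, model)
    i0 = np.full(3, config.white_level)
    pixels = od_to_rgb(od, i0)
    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd * config.white_level,
                                     pixels.shape)
    pixels = np.clip(pixels, 0.0, config.white_level)
    image = IhcImage(pixels=pixels, white_reference=i0)
    masks = CompartmentMasks(labels)
    truth = {
        "concentrations": conc,
        "per_cell_dab": per_cell_dab,
        "cell_ids": cell_ids,
        "stain_model": model,
    }
    return image, masks, truth


# ---------------------------------------------------------------------------
# PDX caliper series


@dataclass(frozen=True)
class PdxSimConfig:
    """Xenograft growth simulation: exponential phases per treatment arm."""

    n_per_arm: int = 4
    initial_volume_mm3: float = 200.0
    growth_rate: float = 0.03  # per day
    regression_rate: float = 0.04  # per day (magnitude)
    enza_rate: float = 0.002  # slow drift during AR-inhibitor phases
    resistance_onset_day: float = 150.0  # ~5 months of continuous SPA
    switch_interval_days: float = 21.0
    duration_days: float = 200.0
    measurement_interval_days: float = 3.5
    rate_jitter: float = 0.1  # animal-level multiplicative rate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.switch_interval_days <= 0:
            raise ValueError("switch interval must be positive")
        rates = [self.growth_rate, self.regression_rate, self.enza_rate]
        if not np.isfinite(rates).all():
            raise ValueError("rates must be finite")


def _arm_rate(arm: str, day: float, config: PdxSimConfig) -> float:
    if arm == "control":
        return config.growth_rate
    if arm == "spa":
        if day < config.resistance_onset_day:
            return -config.regression_rate
        return config.growth_rate  # acquired resistance: regrowth
    if arm == "spa_enza":
        phase = int(day // config.switch_interval_days) % 2
        return -config.regression_rate if phase == 0 else -config.enza_rate
    raise ValueError(f"unknown arm {arm!r}")


def generate_pdx_growth(config: PdxSimConfig) -> pd.DataFrame:
    """Caliper time series (L, W, H, volume) for control, continuous-SPA,
    and alternating SPA/enzalutamide arms.

    The control arm grows exponentially; the SPA arm regresses until the
    resistance-onset day then regrows; the alternating arm stays suppressed.
    Dimensions are the isotropic calipers of the ellipsoid volume formula.
    """
    rng = np.random.default_rng(config.seed)
    days = np.arange(0.0, config.duration_days + 1e-9, config.measurement_interval_days)
    rows = []
    for arm in ("control", "spa", "spa_enza"):
        for animal in range(config.n_per_arm):
            jitter = 1.0 + rng.uniform(-config.rate_jitter, config.rate_jitter)
            volume = config.initial_volume_mm3 * (1.0 + 0.1 * rng.standard_normal())
            volume = max(volume, 20.0)
            prev_day = 0.0
            for day in days:
                rate = _arm_rate(arm, day, config) * jitter
                volume *= np.exp(rate * (day - prev_day))
                prev_day = day
                dim = (volume / 0.5236) ** (1.0 / 3.0)
                rows.append({
                    "arm": arm, "animal": f"{arm}_{animal}", "day": day,
                    "length_mm": dim, "width_mm": dim, "height_mm": dim,
                    "volume_mm3": clinical_stats.tumor_volume(dim, dim, dim),
                })
    return pd.DataFrame(rows)
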