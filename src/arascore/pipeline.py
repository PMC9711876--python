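"""End-to-end orchestration: score -> stratify -> endpoints -> report.

`run_analysis` is the single entry point the CLI `run` verb calls; it reads
the expression matrix, panel, and clinical table named in a RunConfig,
scores the cohort, stratifies at the cutoff, computes endpoint statistics
and paired-change correlations, and writes deterministic (timestamp-free,
key-sorted) report files. `make_fixtures` regenerates the canonical
synthetic bundle the test suite and worked examples use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import clinical_stats
from .ar_activity import DEFAULT_CUTOFF, score_cohort, scores_to_frame
from .expression import default_panel, read_expression_matrix, read_gene_panel, write_expression_matrix
from .ihc_quant import DEFAULT_HSCORE_THRESHOLDS
from .synthetic_data import (
    CohortSimConfig,
    IhcSimConfig,
    PdxSimConfig,
    generate_clinical_table,
    generate_ihc_image,
    generate_paired_cohort,
    generate_pdx_growth,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    matrix: Path
    clinical: Path
    out_dir: Path
    panel: Path | None = None  # None -> shipped default panel
    cutoff: float = DEFAULT_CUTOFF
    min_tpm: float | None = None
    hscore_thresholds: tuple[float, float, float] = DEFAULT_HSCORE_THRESHOLDS
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")
        for name in ("matrix", "clinical"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.panel is not None:
            self.panel = Path(self.panel)
            if not self.panel.exists():
                raise FileNotFoundError(f"panel file not found: {self.panel}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config; relative paths resolve against the YAML's directory."""
        path = Path(path)
        blob = yaml.safe_load(path.read_text())
        if "hscore_thresholds" in blob:
            blob["hscore_thresholds"] = tuple(blob["hscore_thresholds"])
        for key in ("matrix", "clinical", "panel", "out_dir"):
            if blob.get(key) is not None and not Path(blob[key]).is_absolute():
                blob[key] = path.parent / blob[key]
        return cls(**blob)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _paired_correlations(clinical: pd.DataFrame) -> dict:
    """Pearson correlations of paired percent changes (where columns exist)."""
    out = {}
    pairs = [
        ("myc_vs_ki67", ("myc_hscore_pre", "myc_hscore_on"),
         ("ki67_hscore_pre", "ki67_hscore_on")),
        ("ar_rna_vs_protein", ("ar_rna_pre", "ar_rna_on"), ("ar_od_pre", "ar_od_on")),
    ]
    for name, (xa, xb), (ya, yb) in pairs:
        cols = {xa, xb, ya, yb}
        if not cols <= set(clinical.columns):
            continue
        sub = clinical.dropna(subset=list(cols))
        if len(sub) < 3:
            continue
        dx = [clinical_stats.percent_change(p, o) for p, o in zip(sub[xa], sub[xb])]
        dy = [clinical_stats.percent_change(p, o) for p, o in zip(sub[ya], sub[yb])]
        r, p = clinical_stats.pearson_correlation(dx, dy)
        out[name] = {"r": r, "p": p, "n": len(sub)}
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle; returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_matrix(config.matrix)
    panel = read_gene_panel(config.panel) if config.panel else default_panel()
    scores = score_cohort(matrix, panel, cutoff=config.cutoff, min_tpm=config.min_tpm)
    score_frame = scores_to_frame(scores)
    score_frame.to_csv(out / "scores.tsv", sep="\t", index=False)
    clinical = clinical_stats.read_clinical_table(config.clinical)
    merged = clinical.merge(
        score_frame[["sample_id", "score"]].rename(
            columns={"sample_id": "patient_id", "score": "arawm_score"}),
        on="patient_id", how="inner",
    )
    if len(merged) < len(clinical):
        logger.warning("%d clinical records had no matching sample and were dropped",
                       len(clinical) - len(merged))
    responders = []
    for _, row in merged.iterrows():
        resp, vol_used = clinical_stats.classify_response(
            row["psa_pre"], row["psa_on"],
            row.get("tumor_volume_pre"), row.get("tumor_volume_on"))
        responders.append({"patient_id": row["patient_id"], "responder": resp,
                           "volume_used": vol_used,
                           "psa_pct_change": clinical_stats.percent_change(
                               row["psa_pre"], row["psa_on"])})
    responder_frame = pd.DataFrame(responders)
    per_patient = merged.merge(responder_frame, on="patient_id")
    per_patient.to_csv(out / "per_patient.tsv", sep="\t", index=False)
    strat = clinical_stats.stratify_by_biomarker(merged, cutoff=config.cutoff)
    for endpoint, curves in strat.km.items():
        for name, curve in curves.items():
            pd.DataFrame({"time": curve.times, "survival": curve.survival,
                          "at_risk": curve.at_risk, "events": curve.events}
                         ).to_csv(out / f"km_{endpoint}_{name}.csv", index=False)
    n_pos = int((score_frame["score"] > config.cutoff).sum())
    prevalence_pct = 100.0 * n_pos / len(score_frame)
    cond_pct = 100.0 * strat.responder_proportions.get("high", float("nan"))
    predicted = (clinical_stats.predicted_population_response(prevalence_pct, cond_pct)
                 if not np.isnan(cond_pct) else None)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "cutoff": config.cutoff,
            "min_tpm": config.min_tpm,
            "seed": config.seed,
            "panel_size": len(panel),
        },
        "cohort": {
            "n_samples_scored": len(score_frame),
            "n_patients": len(merged),
            "biomarker_positive": n_pos,
            "prevalence_pct": prevalence_pct,
        },
        "response": {
            "responder_proportions": strat.responder_proportions,
            "chi2": (list(strat.response_chi2) if strat.response_chi2 else None),
            "predicted_population_response_pct": predicted,
        },
        "survival": {
            endpoint: {"logrank_statistic": stat, "logrank_p": p}
            for endpoint, (stat, p) in strat.logrank.items()
        },
        "correlations": _paired_correlations(merged),
        "warnings": strat.warnings,
    }
    (out / "report.json").write_text(
        json.dumps(_json_ready(report), sort_keys=True, indent=2) + "\n")
    return report


# ---------------------------------------------------------------------------
# fixture bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, str]:
    """Write the canonical synthetic bundle; returns {relative path: sha256}.

    The bundle contains a paired expression cohort (pre/on TSV), the default
    panel, a clinical table, an IHC slide (PNG) with its label masks, and a
    PDX caliper series — everything the analysis readers consume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = CohortSimConfig(seed=seed)
    pre, on, truth = generate_paired_cohort(cohort_cfg)
    write_expression_matrix(pre, out / "expression_pre.tsv")
    write_expression_matrix(on, out / "expression_on.tsv")
    truth.to_csv(out / "cohort_truth.csv", index=False)
    panel = default_panel()
    (out / "panel.txt").write_text("\n".join(panel.genes) + "\n")
    clinical = generate_clinical_table(truth, cohort_cfg)
    clinical.to_csv(out / "clinical.csv", index=False)
    image, masks, _ = generate_ihc_image(IhcSimConfig(seed=seed))
    iio.imwrite(out / "ihc_slide.png", np.round(image.pixels).astype(np.uint8))
    iio.imwrite(out / "ihc_slide_labels.png", masks.labels)
    pdx = generate_pdx_growth(PdxSimConfig(seed=seed))
    pdx.to_csv(out / "pdx_growth.csv", index=False)
    # paths relative to the bundle dir, so the bundle is relocatable and
    # regenerates with identical checksums anywhere
    run_cfg = {
        "matrix": "expression_pre.tsv",
        "clinical": "clinical.csv",
        "panel": "panel.txt",
        "out_dir": "results",
        "seed": seed,
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    checksums = {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
                 and p.name != "checksums.json"}
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
    return checksums
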