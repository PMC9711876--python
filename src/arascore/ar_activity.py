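"""Single-sample AR-activity scoring (ARA-MW) and panel diagnostics.

The score for a sample is the normalised Mann-Whitney U statistic comparing
the expression ranks of a signature gene panel against all remaining
(background) genes of the same sample:

    s = U / (m' * n),   U = sum over (panel i, background j) of
                            1[rank_i > rank_j] + 0.5 * 1[rank_i == rank_j]

with m' matched panel genes and n background genes. Equivalently, s is the
probability that a randomly chosen panel gene outranks a randomly chosen
background gene, so s is in [0, 1] with null centre 0.5. Because only
within-sample ranks enter, the score needs no reference cohort and is
invariant to sequencing depth and to any strictly monotone transform of the
abundances.

Samples are called biomarker positive when s strictly exceeds the cutoff
(default 0.6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .expression import ExpressionMatrix, GenePanel

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.6


@dataclass(frozen=True)
class ActivityScore:
    """Per-sample ARA-MW score with its context.

    ``n_panel_used`` is the number of panel genes found in the matrix (m'),
    ``n_background`` the number of non-panel genes entering the ranking (n).
    """

    sample_id: str
    score: float
    n_panel_used: int
    n_background: int
    biomarker_positive: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score out of [0,1]: {self.score}")


def rank_sample(matrix: ExpressionMatrix, sample_id: str) -> pd.Series:
    """Within-sample expression ranks, ascending, ties averaged (midranks)."""
    values = matrix.sample_values(sample_id)
    return pd.Series(rankdata(values.to_numpy()), index=values.index, name=sample_id)


def _matched_panel(matrix: ExpressionMatrix, panel: GenePanel) -> list[str]:
    matched, unmatched = matrix.resolve_genes(panel)
    if unmatched:
        logger.warning(
            "panel genes not in matrix (dropped): %s (%d/%d matched)",
            unmatched, len(matched), len(panel),
        )
    if not matched:
        raise ValueError("no panel gene found in the expression matrix")
    return matched


def _score_from_ranks(ranks: np.ndarray, panel_mask: np.ndarray) -> float:
    # With midranks, U = R_panel - m(m+1)/2 reproduces the 0.5-per-tie credit.
    m = int(panel_mask.sum())
    n = ranks.size - m
    u = ranks[panel_mask].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _kept_values(values: np.ndarray, panel_mask: np.ndarray, min_tpm: float | None) -> np.ndarray:
    if min_tpm is None:
        return np.ones(values.size, dtype=bool)
    keep = (values >= min_tpm) | panel_mask  # panel genes always retained
    return keep


def arawm_score(
    matrix: ExpressionMatrix,
    sample_id: str,
    panel: GenePanel,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    min_tpm: float | None = None,
) -> ActivityScore:
    """Score one sample against a gene panel.

    ``min_tpm`` optionally removes background genes below an abundance floor
    before ranking (panel genes are always retained); default is no filter.
    """
    matched = _matched_panel(matrix, panel)
    values = matrix.sample_values(sample_id).to_numpy(dtype=float)
    panel_mask = np.zeros(values.size, dtype=bool)
    panel_mask[matrix.data.index.get_indexer(matched)] = True
    keep = _kept_values(values, panel_mask, min_tpm)
    values, panel_mask = values[keep], panel_mask[keep]
    n_background = int((~panel_mask).sum())
    if n_background < 1:
        raise ValueError(f"sample {sample_id!r}: empty background (need >=1 non-panel gene)")
    score = _score_from_ranks(rankdata(values), panel_mask)
    return ActivityScore(
        sample_id=sample_id,
        score=score,
        n_panel_used=len(matched),
        n_background=n_background,
        biomarker_positive=bool(score > cutoff),
    )


def score_cohort(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    min_tpm: float | None = None,
) -> list[ActivityScore]:
    """Score every sample of the matrix; order follows ``matrix.sample_ids``."""
    if matrix.n_samples == 0:
        return []
    matched = _matched_panel(matrix, panel)
    panel_mask = np.zeros(matrix.n_genes, dtype=bool)
    panel_mask[matrix.data.index.get_indexer(matched)] = True
    out: list[ActivityScore] = []
    if min_tpm is None:
        # one vectorised ranking pass over the whole matrix
        ranks = rankdata(matrix.data.to_numpy(dtype=float), axis=0)
        n = matrix.n_genes - len(matched)
        if n < 1:
            raise ValueError("empty background: matrix has no non-panel genes")
        for j, sample_id in enumerate(matrix.sample_ids):
            s = _score_from_ranks(ranks[:, j], panel_mask)
            out.append(
                ActivityScore(sample_id, s, len(matched), n, bool(s > cutoff))
            )
        return out
    for sample_id in matrix.sample_ids:
        try:
            out.append(arawm_score(matrix, sample_id, panel, cutoff=cutoff, min_tpm=min_tpm))
        except ValueError as exc:
            raise ValueError(f"sample {sample_id!r}: {exc}") from exc
    return out


def scores_to_frame(scores: list[ActivityScore]) -> pd.DataFrame:
    """Tabulate ActivityScore records (sample_id, score, m', n, call)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score": [s.score for s in scores],
            "n_panel_used": [s.n_panel_used for s in scores],
            "n_background": [s.n_background for s in scores],
            "biomarker_positive": [s.biomarker_positive for s in scores],
        }
    )


def panel_diagnostics(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    *,
    covariate: pd.Series | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Dominance, colinearity and covariate diagnostics for a panel.

    Returns a dict with

    - ``loo_scores``: samples x omitted-gene frame of leave-one-gene-out
      scores (the omitted gene rejoins the background), probing whether a
      single dominant gene drives the score;
    - ``panel_correlation``: Pearson correlation matrix of matched panel-gene
      expression across samples (colinearity check);
    - ``covariate_correlation``: ``(r, p)`` of score vs a per-sample
      covariate (e.g. AR protein OD), or None if not supplied;
    - ``fraction_matched``: m'/m.
    """
    matched = _matched_panel(matrix, panel)
    if len(matched) < 2:
        raise ValueError("panel diagnostics need >=2 matched panel genes")
    if matrix.n_samples < 3:
        raise ValueError("panel diagnostics need >=3 samples")
    scores = scores_to_frame(score_cohort(matrix, panel, cutoff=cutoff)).set_index("sample_id")
    ranks = rankdata(matrix.data.to_numpy(dtype=float), axis=0)
    loo = {}
    for omitted in matched:
        # the omitted gene rejoins the background; panels of any size allowed here
        mask = np.zeros(matrix.n_genes, dtype=bool)
        kept = [g for g in matched if g != omitted]
        mask[matrix.data.index.get_indexer(kept)] = True
        loo[omitted] = pd.Series(
            [_score_from_ranks(ranks[:, j], mask) for j in range(matrix.n_samples)],
            index=matrix.sample_ids,
        )
    loo_frame = pd.DataFrame(loo).loc[matrix.sample_ids]
    corr = matrix.data.loc[matched].T.corr(method="pearson")
    cov_corr = None
    if covariate is not None:
        aligned = covariate.reindex(scores.index)
        if aligned.isna().any():
            raise ValueError("covariate missing for some samples")
        r, p = pearsonr(scores["score"].to_numpy(), aligned.to_numpy(dtype=float))
        cov_corr = (float(r), float(p))
    return {
        "loo_scores": loo_frame,
        "panel_correlation": corr,
        "covariate_correlation": cov_corr,
        "fraction_matched": len(matched) / len(panel),
    }
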