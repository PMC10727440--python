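"""Questionnaire reliability and sampling adequacy.

Two headline statistics per questionnaire block:

* **Cronbach's alpha** — internal consistency,
  ``alpha = k/(k-1) * (1 - sum(item variances) / var(total score))``.
* **Kaiser-Meyer-Olkin (KMO)** — sampling adequacy for factor analysis,
  ``KMO = sum(r_ij^2) / (sum(r_ij^2) + sum(p_ij^2))`` over off-diagonal
  pairs, where ``p_ij`` are the anti-image partial correlations obtained from
  the scaled inverse of the correlation matrix.

Answer levels are coded 1..5 for the coefficient computations (Dislike = 1 …
Like it = 5); alpha depends on the coding only through its equal spacing, and
KMO is invariant to any item-wise affine recoding.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .kano import ANSWER_LEVELS
from .registry import ATTRIBUTE_IDS

#: Likert coding of the five answer levels (Dislike = 1 ... Like it = 5).
LEVEL_SCORES = {lvl.value: 5 - i for i, lvl in enumerate(ANSWER_LEVELS)}


class SingularCorrelationError(ValueError):
    """Correlation matrix is (numerically) singular; KMO is undefined."""


def _as_matrix(m) -> np.ndarray:
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError("item matrix must be 2-D (respondents x items)")
    if x.shape[1] < 2:
        raise ValueError("at least 2 items are required")
    if x.shape[0] < 3:
        raise ValueError("at least 3 respondents are required")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing cells; apply listwise deletion first")
    return x


def cronbach_alpha(m) -> float:
    """Cronbach's alpha of a respondents-by-items score matrix."""
    x = _as_matrix(m)
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def kmo(m) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1]."""
    x = _as_matrix(m)
    r = np.corrcoef(x, rowvar=False)
    if np.isnan(r).any():
        raise SingularCorrelationError("constant item yields undefined correlations")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < np.log(np.finfo(float).tiny):
        raise SingularCorrelationError("correlation matrix is singular")
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    if r2 + p2 == 0:
        return 0.0
    return float(r2 / (r2 + p2))


def score_answers(frame: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Code answer-level columns 1..5 and listwise-delete incomplete rows."""
    scores = frame[list(columns)].apply(
        lambda col: col.map(lambda v: LEVEL_SCORES.get(v, np.nan))
    )
    scores = scores.dropna(axis=0, how="any")
    return scores.to_numpy(dtype=float)


def block_matrix(frame: pd.DataFrame, block: str) -> np.ndarray:
    """Extract one questionnaire block as a scored item matrix.

    ``block`` is ``"functional"`` or ``"dysfunctional"`` (the 18 Kano answer
    columns, coded 1..5) or ``"intention"`` (the 1-5 intention score together
    with any numeric ``influence_*`` covariates present).
    """
    if block == "functional":
        return score_answers(frame, [f"F{aid:02d}" for aid in ATTRIBUTE_IDS])
    if block == "dysfunctional":
        return score_answers(frame, [f"D{aid:02d}" for aid in ATTRIBUTE_IDS])
    if block == "intention":
        cols = ["intention"] + sorted(
            c for c in frame.columns if c.startswith("influence_")
        )
        if len(cols) < 2:
            raise ValueError("intention block needs at least one influence_* item")
        return frame[cols].apply(pd.to_numeric).dropna(axis=0).to_numpy(dtype=float)
    raise ValueError(f"unknown block {block!r}")


def block_report(frame: pd.DataFrame, blocks: Sequence[str] = (
    "intention", "functional", "dysfunctional"
)) -> pd.DataFrame:
    """Alpha and KMO per questionnaire block (KMO NaN when singular)."""
    rows = []
    for block in blocks:
        x = block_matrix(frame, block)
        try:
            k = kmo(x)
        except SingularCorrelationError:
            k = np.nan
        rows.append(
            {
                "block": block,
                "n_respondents": x.shape[0],
                "n_items": x.shape[1],
                "cronbach_alpha": cronbach_alpha(x),
                "kmo": k,
            }
        )
    return pd.DataFrame(rows).set_index("block")
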