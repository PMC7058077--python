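"""Two-stage testing controlling the overall false discovery rate (OFDR).

Screening stage: a per-gene global p-value (typically from a global Wald
test) is BH-adjusted across genes at level alpha_I; R genes pass. Confirmation
stage: for each passing gene, its individual hypotheses (e.g. the pairwise
lineage comparisons) are tested with Holm's procedure at the adjusted level

    alpha_II = (R / G) * alpha_I,

which controls the expected fraction of genes with at least one falsely
rejected hypothesis among the genes declared significant at level alpha_I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .testing import adjust_bh

__all__ = ["StageWiseResult", "stagewise_test"]


@dataclass
class StageWiseResult:
    screen: pd.DataFrame       # gene_id, screen_p, screen_q, screen_pass
    confirm: pd.DataFrame      # gene_id, hypothesis, confirm_p, confirm_pass
    alpha_I: float
    alpha_II: float
    R: int
    G: int


def _holm_reject(p_row: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejections for one gene's hypothesis family."""
    reject = np.zeros(p_row.shape, dtype=bool)
    ok = np.isfinite(p_row)
    m = int(ok.sum())
    if m == 0 or alpha <= 0:
        return reject
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(p_row[idx], kind="stable")]
    for j, i in enumerate(order):
        if p_row[i] <= alpha / (m - j):
            reject[i] = True
        else:
            break
    return reject


def stagewise_test(
    screen_p,
    confirm_p,
    alpha_I: float = 0.05,
    gene_ids=None,
    hypothesis_names=None,
) -> StageWiseResult:
    """Screen genes with BH, then confirm per-gene hypotheses with Holm.

    Parameters
    ----------
    screen_p : (G,) per-gene screening p-values (NaN = not assessed).
    confirm_p : (G, H) per-gene, per-hypothesis confirmation p-values.
    alpha_I : target OFDR level in (0, 1).
    """
    if not (0.0 < alpha_I < 1.0):
        raise ValueError("alpha_I must lie in (0, 1)")
    screen_p = np.asarray(screen_p, dtype=float).ravel()
    confirm_p = np.atleast_2d(np.asarray(confirm_p, dtype=float))
    if confirm_p.shape[0] != screen_p.shape[0]:
        raise ValueError(
            f"gene axis mismatch: {screen_p.shape[0]} screening p-values but "
            f"{confirm_p.shape[0]} confirmation rows"
        )
    G = int(np.isfinite(screen_p).sum())
    if gene_ids is None:
        gene_ids = np.array([f"gene{i}" for i in range(screen_p.size)], dtype=object)
    if hypothesis_names is None:
        hypothesis_names = [f"hypothesis{j + 1}" for j in range(confirm_p.shape[1])]

    screen_q = adjust_bh(screen_p)
    screen_pass = np.isfinite(screen_q) & (screen_q <= alpha_I)
    R = int(screen_pass.sum())
    alpha_II = (R / G) * alpha_I if G > 0 else 0.0

    confirm_pass = np.zeros(confirm_p.shape, dtype=bool)
    for g in np.flatnonzero(screen_pass):
        confirm_pass[g] = _holm_reject(confirm_p[g], alpha_II)

    screen_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "screen_p": screen_p,
            "screen_q": screen_q,
            "screen_pass": screen_pass,
        }
    )
    confirm_df = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, confirm_p.shape[1]),
            "hypothesis": np.tile(hypothesis_names, screen_p.size),
            "confirm_p": confirm_p.ravel(),
            "confirm_pass": confirm_pass.ravel(),
        }
    )
    return StageWiseResult(
        screen=screen_df,
        confirm=confirm_df,
        alpha_I=float(alpha_I),
        alpha_II=float(alpha_II),
        R=R,
        G=G,
    )
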