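"""Cell-type level summaries of per-cell calls.

For a known cell type, let p+ be the proportion of its cells called
significantly positively associated, and p_a the same proportion over all
cells (the background).  The enrichment is the natural-log odds ratio

    rho+ = log[ (p+ / (1 - p+)) / (p_a / (1 - p_a)) ],

and rho- analogously for negative calls.  A type is summarized as
positively associated if rho+ >= 1 and rho- < 1, negatively associated if
rho- >= 1 and rho+ < 1, and inconclusive otherwise.  Types below 1% of the
cell population are not called (insufficient power).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["log_odds_enrichment", "summarize_type", "summarize_cell_types"]

MIN_POPULATION_FRACTION = 0.01


def log_odds_enrichment(p_group: float, p_background: float) -> float:
    """Natural-log odds ratio of a group proportion versus the background."""
    for name, p in (("p_group", p_group), ("p_background", p_background)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if p_group in (0.0, 1.0) or p_background in (0.0, 1.0):
        raise ValueError(
            "degenerate proportion; apply a continuity correction to the counts"
        )
    return float(
        np.log((p_group / (1 - p_group)) / (p_background / (1 - p_background)))
    )


def _corrected_proportion(hits: int, total: int) -> float:
    """Haldane–Anscombe correction: add 0.5 to both cells of the margin when
    either is zero, so the log odds stays finite."""
    if total == 0:
        return 0.5  # no information at all; odds 1
    if hits == 0 or hits == total:
        return (hits + 0.5) / (total + 1.0)
    return hits / total


def _enrichment(hits_group: int, n_group: int, hits_all: int, n_all: int) -> float:
    """Log odds ratio of the group call rate vs the background call rate.

    Identical raw rates (including the common zero/zero case) mean no
    enrichment: log odds ratio 0 by definition.  Otherwise degenerate
    margins get the continuity correction.  Without the first rule the
    correction alone would hand every small group a spurious
    ``log(n_all/n_group)``-sized enrichment when both rates are zero."""
    if n_group > 0 and hits_group * n_all == hits_all * n_group:
        return 0.0
    return log_odds_enrichment(
        _corrected_proportion(hits_group, n_group),
        _corrected_proportion(hits_all, n_all),
    )


def summarize_type(rho_plus: float, rho_minus: float) -> str:
    """Apply the threshold rule to the two enrichments."""
    if rho_plus >= 1.0 and rho_minus < 1.0:
        return "positive"
    if rho_minus >= 1.0 and rho_plus < 1.0:
        return "negative"
    return "inconclusive"


def summarize_cell_types(
    results: pd.DataFrame,
    cell_types: pd.Series | np.ndarray,
    p_threshold: float = 0.05,
    min_fraction: float = MIN_POPULATION_FRACTION,
) -> pd.DataFrame:
    """Summarize per-cell calls into one row per known cell type.

    Parameters
    ----------
    results
        Per-cell table with columns ``Lambda`` (standardized strength) and
        ``p_value``.
    cell_types
        Per-cell type annotation aligned with ``results``.

    Returns a table with columns ``cell_type, fraction, rho_plus, rho_minus,
    call``; ``call`` is missing for types below ``min_fraction`` of the
    population.
    """
    types = np.asarray(cell_types)
    if len(types) != len(results):
        raise ValueError("cell_types length does not match results")
    lam = results["Lambda"].to_numpy()
    p = results["p_value"].to_numpy()
    sig_pos = (p < p_threshold) & (lam > 0)
    sig_neg = (p < p_threshold) & (lam < 0)
    m = len(types)
    all_pos = int(sig_pos.sum())
    all_neg = int(sig_neg.sum())
    rows = []
    for t in pd.unique(types):
        mask = types == t
        n_t = int(mask.sum())
        frac = n_t / m
        rho_p = _enrichment(int(sig_pos[mask].sum()), n_t, all_pos, m)
        rho_m = _enrichment(int(sig_neg[mask].sum()), n_t, all_neg, m)
        call = summarize_type(rho_p, rho_m) if frac >= min_fraction else None
        rows.append(
            {"cell_type": t, "fraction": frac, "rho_plus": rho_p,
             "rho_minus": rho_m, "call": call}
        )
    return pd.DataFrame(rows)
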