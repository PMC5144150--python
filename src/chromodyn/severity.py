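"""Functional vs clinical severity scoring.

The Functional Severity Score (FSS) summarizes how far a mutant's
chromocenter morphometry deviates from wild type.  The default functional
form is an explicit, injectable stand-in — a weighted sum of relative
deviations,

    FSS = w_cn * |CN_mut/CN_wt - 1| + w_cs * |CS_mut/CS_wt - 1|,

with weights (0.5, 0.5) — chosen so that FSS = 0 for a wild-type-like
mutant and FSS grows monotonically with either deviation.  Any other form
can be passed via ``form`` without touching the rest of the pipeline.

Clinical Severity Scores (CSS) are consumed as a per-participant table and
averaged per mutation; the FSS-CSS relationship is summarized by Pearson
and Spearman coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SeverityRecord",
    "compute_fss",
    "aggregate_css",
    "correlate_severity",
]


@dataclass
class SeverityRecord:
    mutation: str
    cn_rel: float | None
    cs_rel: float | None
    fss: float | None
    css: float | None
    n_participants: int = 0


def compute_fss(
    cn_mut: float | None,
    cs_mut: float | None,
    cn_wt: float,
    cs_wt: float,
    weights: tuple[float, float] = (0.5, 0.5),
    form: Callable[[float, float, tuple[float, float]], float] | None = None,
) -> float | None:
    """Functional severity score from mutant and wild-type CN / CS means.

    Returns ``None`` (missing) when the mutant means are undefined, as for
    constructs whose chromocenter clustering or binding is abolished.
    ``form``, if given, is called as ``form(cn_rel, cs_rel, weights)``.
    """
    if cn_wt is None or cs_wt is None or cn_wt <= 0 or cs_wt <= 0:
        raise ValueError("wild-type CN and CS means must be > 0")
    if cn_mut is None or cs_mut is None or not np.isfinite([cn_mut, cs_mut]).all():
        return None
    cn_rel = cn_mut / cn_wt
    cs_rel = cs_mut / cs_wt
    if form is not None:
        return float(form(cn_rel, cs_rel, weights))
    w_cn, w_cs = weights
    return float(w_cn * abs(cn_rel - 1.0) + w_cs * abs(cs_rel - 1.0))


def aggregate_css(records: pd.DataFrame) -> pd.DataFrame:
    """Average CSS per mutation across participants.

    ``records`` needs columns ``mutation`` and ``css``; returns one row per
    mutation with the mean CSS and the participant count.
    """
    if len(records) == 0:
        raise ValueError("empty CSS input")
    out = (
        records.groupby("mutation", sort=False)["css"]
        .agg(css="mean", n_participants="count")
        .reset_index()
    )
    return out


def correlate_severity(records: list[SeverityRecord]) -> dict:
    """Correlate FSS with CSS across mutations.

    Uses only records where both scores are defined (at least three are
    required).  Returns Pearson and Spearman coefficients with two-sided
    p-values (t approximation) and the mutations ranked by CSS ascending
    (mildest first).
    """
    complete = [r for r in records
                if r.fss is not None and r.css is not None]
    if len(complete) < 3:
        raise ValueError("need >= 3 records with both FSS and CSS defined")
    fss = np.array([r.fss for r in complete], dtype=float)
    css = np.array([r.css for r in complete], dtype=float)
    pear = sps.pearsonr(fss, css)
    spear = sps.spearmanr(fss, css)
    ranking = [r.mutation for r in sorted(complete, key=lambda r: r.css)]
    return {
        "n": len(complete),
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
        "ranking_by_css": ranking,
    }
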