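"""Per-construct chromocenter morphometry and nonparametric comparison.

Per-cell chromocenter number (CN) and mean size (CS) are aggregated per
construct (mean +/- SEM) and compared against wild type with a two-tailed
Mann-Whitney U test: exact p by full enumeration for small untied samples
(n1 + n2 <= 12), otherwise a normal approximation with tie and continuity
corrections.  Significance is reported in two tiers, p <= 0.005 ("***")
and p <= 0.05 ("**"); no multiple-testing correction is applied by default
(a Bonferroni flag is available but off, matching the single-comparison
reporting convention of the analysis this reproduces).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .segmentation import ChromocenterSet

__all__ = [
    "ConstructStats",
    "TestResult",
    "ComparisonResult",
    "aggregate_construct",
    "mann_whitney_u",
    "compare_to_wt",
]

EXACT_MAX_N = 12  # pooled size up to which the exact null is enumerated
TIER_STRICT = 0.005
TIER_LOOSE = 0.05


@dataclass
class ConstructStats:
    construct: str
    per_cell_cn: np.ndarray
    per_cell_cs: np.ndarray  # NaN for cells whose CS is undefined (CN = 0)
    mean_cn: float = field(init=False)
    sem_cn: float = field(init=False)
    mean_cs: float | None = field(init=False)
    sem_cs: float | None = field(init=False)

    def __post_init__(self) -> None:
        cn = np.asarray(self.per_cell_cn, dtype=float)
        self.mean_cn = float(cn.mean())
        self.sem_cn = float(cn.std(ddof=1) / math.sqrt(cn.size)) if cn.size > 1 else float("nan")
        cs = np.asarray(self.per_cell_cs, dtype=float)
        cs = cs[~np.isnan(cs)]
        if cs.size == 0:
            self.mean_cs = None
            self.sem_cs = None
        else:
            self.mean_cs = float(cs.mean())
            self.sem_cs = (float(cs.std(ddof=1) / math.sqrt(cs.size))
                           if cs.size > 1 else float("nan"))

    @property
    def n_cells(self) -> int:
        return int(np.asarray(self.per_cell_cn).size)

    @property
    def cs_values(self) -> np.ndarray:
        cs = np.asarray(self.per_cell_cs, dtype=float)
        return cs[~np.isnan(cs)]


@dataclass
class TestResult:
    u: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass
class ComparisonResult:
    construct: str
    cn_test: TestResult | None
    cs_test: TestResult | None
    cn_significant_increase: bool
    cs_significant_decrease: bool
    not_analyzable: bool
    tier_cn: str = ""
    tier_cs: str = ""


def aggregate_construct(cells: list[ChromocenterSet] | None,
                        construct: str,
                        cn: np.ndarray | None = None,
                        cs: np.ndarray | None = None) -> ConstructStats:
    """Aggregate per-cell CN / CS into a :class:`ConstructStats`.

    Accepts either a list of :class:`ChromocenterSet` or raw ``cn`` / ``cs``
    arrays.  Cells with CN = 0 contribute to the CN statistics but are
    excluded from CS (their size is undefined).  At least two cells are
    required for an SEM to exist.
    """
    if cells is not None:
        cn = np.array([c.cn for c in cells], dtype=float)
        cs = np.array(
            [c.cs_px2 if c.cs_px2 is not None else np.nan for c in cells],
            dtype=float,
        )
    if cn is None or cs is None:
        raise ValueError("provide either cells or cn and cs arrays")
    cn = np.asarray(cn, dtype=float)
    cs = np.asarray(cs, dtype=float)
    if cn.size < 2:
        raise ValueError("need at least 2 cells per construct")
    if cn.size != cs.size:
        raise ValueError("cn and cs must have the same length")
    return ConstructStats(construct=construct, per_cell_cn=cn, per_cell_cs=cs)


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is the statistic of ``group_a`` (rank-sum form, midranks for ties).
    The p-value is exact (full enumeration of the permutation null) when
    the pooled sample size is at most ``EXACT_MAX_N`` and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction is used.  Two-sided p is capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= EXACT_MAX_N and not has_ties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(
            a, b,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
    return TestResult(
        u=float(res.statistic),
        p_two_sided=float(min(1.0, res.pvalue)),
        method="exact" if exact else "normal_approx",
    )


def _tier(p: float) -> str:
    if p <= TIER_STRICT:
        return "***"
    if p <= TIER_LOOSE:
        return "**"
    return ""


def compare_to_wt(stats: ConstructStats, wt: ConstructStats,
                  alpha: float = TIER_LOOSE) -> ComparisonResult:
    """Test a construct's per-cell CN and CS against wild type.

    Constructs with fewer than two cells carrying identifiable
    chromocenters are flagged ``not_analyzable`` (mirroring constructs
    whose binding is too impaired to yield countable chromocenters) and no
    CS test is run.  Flag directions come from the difference of means.
    """
    cs_mut = stats.cs_values
    not_analyzable = cs_mut.size < 2 or stats.mean_cs is None

    cn_test = mann_whitney_u(stats.per_cell_cn, wt.per_cell_cn)
    cn_up = (
        cn_test.p_two_sided <= alpha and stats.mean_cn > wt.mean_cn
    )

    cs_test = None
    cs_down = False
    if not not_analyzable:
        cs_test = mann_whitney_u(cs_mut, wt.cs_values)
        cs_down = (
            cs_test.p_two_sided <= alpha
            and stats.mean_cs is not None
            and wt.mean_cs is not None
            and stats.mean_cs < wt.mean_cs
        )

    return ComparisonResult(
        construct=stats.construct,
        cn_test=cn_test,
        cs_test=cs_test,
        cn_significant_increase=bool(cn_up),
        cs_significant_decrease=bool(cs_down),
        not_analyzable=bool(not_analyzable),
        tier_cn=_tier(cn_test.p_two_sided),
        tier_cs=_tier(cs_test.p_two_sided) if cs_test else "",
    )
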