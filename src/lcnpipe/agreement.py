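"""Manual-versus-automated method-comparison statistics.

Paired lacuna/osteocyte counts from a manual reader and the automated
pipeline are compared with descriptive statistics (mean, sample SD,
SEM), a Bland-Altman analysis (mean difference and 1.96-SD limits of
agreement), the mean absolute percentage error with the manual count as
reference, and a Wilcoxon matched-pairs signed-rank test.

The difference is oriented as manual − automated throughout, so a
pipeline that systematically counts more cells (e.g. by including
edge-touching cells a manual reader skips) yields a negative mean
difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import DataError

log = logging.getLogger(__name__)

__all__ = [
    "PairedCounts",
    "AgreementReport",
    "summary_stats",
    "bland_altman",
    "mean_percentage_error",
    "wilcoxon_signed_rank",
    "compare_counts",
]

EXACT_WILCOXON_MAX_N = 12


@dataclass
class PairedCounts:
    """Paired (manual, automated) counts, one pair per imaged region."""

    manual: np.ndarray
    automated: np.ndarray

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, float)
        self.automated = np.asarray(self.automated, float)
        if self.manual.shape != self.automated.shape or self.manual.ndim != 1:
            raise DataError("manual and automated must be 1D arrays of equal length")
        if self.n < 1:
            raise DataError("need at least one pair")
        if np.any(self.manual < 0) or np.any(self.automated < 0):
            raise DataError("counts must be >= 0")

    @property
    def n(self) -> int:
        return int(self.manual.size)

    @property
    def differences(self) -> np.ndarray:
        """manual − automated, per pair."""
        return self.manual - self.automated

    @classmethod
    def from_csv(cls, path) -> "PairedCounts":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "manual" not in cols or "automated" not in cols:
            raise DataError("counts CSV needs 'manual' and 'automated' columns")
        return cls(df[cols["manual"]].to_numpy(), df[cols["automated"]].to_numpy())


@dataclass
class AgreementReport:
    n: int
    mean_manual: float
    sd_manual: float | None
    sem_manual: float | None
    mean_auto: float
    sd_auto: float | None
    sem_auto: float | None
    ba_mean_diff: float
    ba_sd_diff: float
    ba_loa_low: float
    ba_loa_high: float
    mpe_mean: float
    mpe_sd: float
    mpe_signed_mean: float
    n_excluded_zero_manual: int
    wilcoxon_stat: float
    wilcoxon_p: float
    wilcoxon_method: str
    n_zero_differences: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _sd_sem(x: np.ndarray) -> tuple[float | None, float | None]:
    n = x.size
    if n < 2:
        return None, None
    sd = float(np.std(x, ddof=1))
    return sd, sd / math.sqrt(n)


def summary_stats(pairs: PairedCounts) -> dict:
    """Means, sample SDs (n−1 denominator) and SEMs (= sd/√n) per method."""
    sd_m, sem_m = _sd_sem(pairs.manual)
    sd_a, sem_a = _sd_sem(pairs.automated)
    return {
        "n": pairs.n,
        "mean_manual": float(pairs.manual.mean()),
        "sd_manual": sd_m,
        "sem_manual": sem_m,
        "mean_auto": float(pairs.automated.mean()),
        "sd_auto": sd_a,
        "sem_auto": sem_a,
    }


def bland_altman(pairs: PairedCounts) -> dict:
    """Bland-Altman agreement: mean difference and mean ± 1.96 SD limits."""
    if pairs.n < 2:
        raise DataError("Bland-Altman needs at least two pairs")
    d = pairs.differences
    mean_diff = float(d.mean())
    sd_diff = float(np.std(d, ddof=1))
    return {
        "ba_mean_diff": mean_diff,
        "ba_sd_diff": sd_diff,
        "ba_loa_low": mean_diff - 1.96 * sd_diff,
        "ba_loa_high": mean_diff + 1.96 * sd_diff,
    }


def mean_percentage_error(pairs: PairedCounts) -> dict:
    """Percentage error per pair, |auto − manual| / manual × 100.

    Pairs with a zero manual count carry no defined reference and are
    excluded (their number is reported). The signed mean is also emitted
    for completeness; the absolute form is the headline figure.
    """
    valid = pairs.manual > 0
    if not valid.any():
        raise DataError("all manual counts are zero; percentage error undefined")
    m = pairs.manual[valid]
    a = pairs.automated[valid]
    e = np.abs(a - m) / m * 100.0
    signed = (a - m) / m * 100.0
    return {
        "mpe_mean": float(e.mean()),
        "mpe_sd": float(np.std(e, ddof=1)) if e.size >= 2 else 0.0,
        "mpe_signed_mean": float(signed.mean()),
        "n_excluded_zero_manual": int((~valid).sum()),
    }


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Average ranks of |d| (ties share their mean rank)."""
    return stats.rankdata(np.abs(d), method="average")


def wilcoxon_signed_rank(
    pairs: PairedCounts, exact_max_n: int = EXACT_WILCOXON_MAX_N
) -> tuple[float, float, str]:
    """Wilcoxon matched-pairs signed-rank test (two-sided).

    W is the sum of the ranks of positive differences (manual − automated),
    with average ranks for ties and zero differences dropped. The p-value
    is exact (full enumeration of the 2^n sign patterns, valid with ties)
    for effective n <= ``exact_max_n`` and a normal approximation with
    continuity correction otherwise; the rank-based variance Σr²/4 makes
    the approximation tie-corrected automatically.
    """
    d = pairs.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, "degenerate"
    ranks = _signed_ranks(d)
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        total = sums.size
        p_le = np.sum(sums <= w + 1e-9) / total
        p_ge = np.sum(sums >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p), "exact"
    mu = float(ranks.sum()) / 2.0
    sigma = math.sqrt(float(np.sum(ranks**2)) / 4.0)
    if sigma == 0:
        return w, 1.0, "degenerate"
    cc = 0.5 if w != mu else 0.0
    z = (w - mu - math.copysign(cc, w - mu)) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0)), "normal"


def compare_counts(pairs: PairedCounts) -> AgreementReport:
    """Full method-agreement report on paired manual/automated counts."""
    summ = summary_stats(pairs)
    ba = bland_altman(pairs) if pairs.n >= 2 else {
        "ba_mean_diff": float(pairs.differences.mean()),
        "ba_sd_diff": 0.0,
        "ba_loa_low": float(pairs.differences.mean()),
        "ba_loa_high": float(pairs.differences.mean()),
    }
    mpe = mean_percentage_error(pairs)
    w, p, method = wilcoxon_signed_rank(pairs)
    n_zero = int(np.sum(pairs.differences == 0))
    if n_zero:
        log.info("dropped %d zero differences before signed-rank ranking", n_zero)
    return AgreementReport(
        n=summ["n"],
        mean_manual=summ["mean_manual"],
        sd_manual=summ["sd_manual"],
        sem_manual=summ["sem_manual"],
        mean_auto=summ["mean_auto"],
        sd_auto=summ["sd_auto"],
        sem_auto=summ["sem_auto"],
        **ba,
        **mpe,
        wilcoxon_stat=w,
        wilcoxon_p=p,
        wilcoxon_method=method,
        n_zero_differences=n_zero,
    )
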