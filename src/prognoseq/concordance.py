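"""Cross-platform agreement statistics.

Lin's concordance correlation coefficient (CCC) measures agreement with the
identity line, penalizing both location and scale shifts on top of Pearson
correlation; it is the headline statistic for comparing hazard-ratio
estimates across platforms (RNA-seq vs RT-PCR or microarray). RT-PCR crossing
thresholds are converted to expression by subtracting each gene's C_T from
the cohort median C_T (so higher = more expressed). Prognostic-agreement
tables cross-classify features as prognostic/not on two platforms and test
association with Fisher's exact test, optionally stratified by abundance bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2), all
    moments with n denominators (Lin's original definition). Raises when both
    vectors are constant with equal means (degenerate 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    vx, vy = x.var(), y.var()
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean**2
    if denom == 0:
        raise ValueError("both inputs constant with equal means: CCC undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


def ct_normalize(ct: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """RT-PCR normalization: cohort median C_T minus each sample's C_T.

    Accepts one gene's C_T vector across the cohort, or a genes x samples
    frame (normalized per gene/row). A sample at the cohort median maps to 0;
    one PCR cycle below the median maps to +1 (more expressed).
    """
    if isinstance(ct, pd.DataFrame):
        arr = ct.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("C_T values must be finite")
        return ct.median(axis=1).to_numpy()[:, None] - ct
    arr = np.asarray(ct, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("C_T values must be finite")
    return np.median(arr) - arr


@dataclass
class AgreementTable:
    """2x2 cross-classification of features as prognostic on two platforms."""

    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float  # inf when a zero off-diagonal makes it unbounded
    odds_ratio_unbounded: bool
    fisher_p: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.both, self.a_only], [self.b_only, self.neither]])

    @property
    def n(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    def transpose(self) -> "AgreementTable":
        return AgreementTable(
            self.both, self.b_only, self.a_only, self.neither,
            self.odds_ratio, self.odds_ratio_unbounded, self.fisher_p,
        )


def prognostic_agreement(
    p_a: np.ndarray,
    p_b: np.ndarray,
    alpha: float = 0.05,
    abundance: np.ndarray | None = None,
    bins: tuple[float, ...] = (10, 100, 1000),
) -> AgreementTable | dict[str, AgreementTable]:
    """Cross-classify features as prognostic (p < alpha) on two platforms.

    Returns one table, or — when per-feature ``abundance`` (median raw
    counts) is given — a dict of tables stratified by abundance bin, since
    cross-platform concordance falls off as transcript abundance decreases.
    Fisher's exact p is two-sided; the odds ratio is reported as unbounded
    (inf) when an off-diagonal cell is 0.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape or p_a.size == 0:
        raise ValueError("p-value vectors must be equal-length and non-empty")
    if abundance is not None:
        abundance = np.asarray(abundance, dtype=float)
        edges = (-np.inf,) + tuple(bins) + (np.inf,)
        labels = [f"<{bins[0]:g}"] + [
            f"{bins[i]:g}-{bins[i + 1]:g}" for i in range(len(bins) - 1)
        ] + [f">={bins[-1]:g}"]
        out: dict[str, AgreementTable] = {}
        for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
            mask = (abundance >= lo) & (abundance < hi)
            if mask.sum():
                out[lab] = prognostic_agreement(p_a[mask], p_b[mask], alpha=alpha)
        return out
    sig_a = p_a < alpha
    sig_b = p_b < alpha
    both = int((sig_a & sig_b).sum())
    a_only = int((sig_a & ~sig_b).sum())
    b_only = int((~sig_a & sig_b).sum())
    neither = int((~sig_a & ~sig_b).sum())
    table = [[both, a_only], [b_only, neither]]
    _, p = fisher_exact(table, alternative="two-sided")
    unbounded = (a_only == 0 or b_only == 0) and both > 0 and neither > 0
    if a_only and b_only:
        oratio = both * neither / (a_only * b_only)
    else:
        oratio = float("inf") if both and neither else float("nan")
    return AgreementTable(both, a_only, b_only, neither, float(oratio), unbounded, float(p))


def hazard_ratio_scatter_stats(hr_a: np.ndarray, hr_b: np.ndarray) -> tuple[float, float]:
    """(Lin CCC, Pearson r) of two platforms' hazard ratios on the log2 scale."""
    la = np.log2(np.asarray(hr_a, dtype=float))
    lb = np.log2(np.asarray(hr_b, dtype=float))
    if la.size >= 3 and (la.std() == 0 or lb.std() == 0):
        raise ValueError("constant hazard-ratio vector: Pearson r undefined")
    r = float(pearsonr(la, lb).statistic)
    return lin_ccc(la, lb), r
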