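"""Group-level statistics for the cochlear-modulation analysis.

Covers the attention modulation index (AMI) and its pooling, one-sample and
paired t tests (one- or two-tailed), Benjamini-Hochberg FDR, uniformity
testing of peak frequencies, a nonparametric common-median test for circular
(phase) data, main-effect repeated-measures ANOVAs for fully crossed
two-level within-subject designs, and per-subject/condition reaction-time
median splits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preproc import ModulationSpectrum


@dataclass
class AmiMap:
    values: np.ndarray  # percent, (n_bands, n_mod_freqs); in [-100, 100] or NaN
    band_centers: np.ndarray
    mod_freqs: np.ndarray
    subject_id: str = ""
    ear: str = ""


@dataclass
class GroupTestResult:
    statistic: float
    df: float | tuple
    p_raw: float
    n: int
    tail: str = "two"
    p_fdr: float | None = None
    status: str = "ok"  # "zero-variance", "degenerate", ... when not testable

    @property
    def significant(self) -> bool:
        p = self.p_fdr if self.p_fdr is not None else self.p_raw
        return self.status == "ok" and p < 0.05


def compute_ami(power_a: ModulationSpectrum, power_v: ModulationSpectrum,
                subject_id: str = "", ear: str = "") -> AmiMap:
    """(Attend Auditory - Attend Visual) / (Attend Auditory + Attend Visual) x 100.

    Cells where both condition powers are zero are NaN and excluded from any
    later pooling.
    """
    if power_a.mode != power_v.mode:
        raise ValueError("modes differ between conditions")
    if (not np.array_equal(power_a.band_centers, power_v.band_centers)
            or not np.array_equal(power_a.mod_freqs, power_v.mod_freqs)):
        raise ValueError("condition spectra have mismatched axes")
    a, v = power_a.power, power_v.power
    with np.errstate(divide="ignore", invalid="ignore"):
        ami = (a - v) / (a + v) * 100.0
    return AmiMap(values=ami, band_centers=power_a.band_centers,
                  mod_freqs=power_a.mod_freqs, subject_id=subject_id, ear=ear)


def pool_ami(ami: AmiMap, band_range: tuple[float, float] = (1000.0, 2000.0),
             mod_range: tuple[float, float] = (1.0, 10.0)) -> float:
    """Mean of non-NaN AMI cells within the band and modulation-frequency
    ranges (the index is averaged, not recomputed from pooled power)."""
    bsel = (ami.band_centers >= band_range[0]) & (ami.band_centers <= band_range[1])
    fsel = (ami.mod_freqs >= mod_range[0]) & (ami.mod_freqs <= mod_range[1])
    if not bsel.any() or not fsel.any():
        raise ValueError("pooling ranges do not intersect the map axes")
    cells = ami.values[np.ix_(bsel, fsel)]
    return float(np.nanmean(cells))


def pool_ami_power_first(power_a: ModulationSpectrum, power_v: ModulationSpectrum,
                         band_range=(1000.0, 2000.0), mod_range=(1.0, 10.0)) -> float:
    """Alternative pooling: AMI of range-averaged power (config-exposed)."""
    def _pool(spec):
        bsel = (spec.band_centers >= band_range[0]) & (spec.band_centers <= band_range[1])
        fsel = (spec.mod_freqs >= mod_range[0]) & (spec.mod_freqs <= mod_range[1])
        return spec.power[np.ix_(bsel, fsel)].mean()
    a, v = _pool(power_a), _pool(power_v)
    return float((a - v) / (a + v) * 100.0)


def t_test(values, paired_with=None, mu: float = 0.0,
           tail: str = "two") -> GroupTestResult:
    """One-sample (or paired) t test with explicit tail handling.

    ``tail``: "two", "greater" (alternative mean > mu), or "less".
    Zero-variance data yields an error status rather than a p-value.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired vectors must have equal length")
        x = x - y
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        return GroupTestResult(np.nan, n - 1, np.nan, n, tail, status="zero-variance")
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.ttest_1samp(x, popmean=mu, alternative=alt)
    return GroupTestResult(float(res.statistic), n - 1, float(res.pvalue), n, tail)


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def ks_uniformity_test(peak_freqs, support: tuple[float, float]) -> GroupTestResult:
    """One-sample KS test of peak frequencies against Uniform(support).

    The classical D in [0, 1] is reported as the statistic; the sqrt(n)-scaled
    value (the convention of some R uniformity packages, which can exceed 1)
    is available as ``result.d_scaled``.
    """
    x = np.asarray(peak_freqs, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    lo, hi = support
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("values outside the stated support")
    res = sps.kstest(x, sps.uniform(loc=lo, scale=hi - lo).cdf)
    out = GroupTestResult(float(res.statistic), x.size, float(res.pvalue), x.size)
    out.d_scaled = float(np.sqrt(x.size) * res.statistic)
    return out


def circ_dist(a, b):
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def circ_median(angles: np.ndarray) -> float:
    """Circular median: the sample angle minimizing mean absolute circular
    deviation (ties broken toward the smallest deviation sum)."""
    a = np.asarray(angles, dtype=float)
    dev = np.abs(circ_dist(a[:, None], a[None, :])).mean(axis=0)
    return float(a[int(np.argmin(dev))])


def circ_common_median_test(angles_g1, angles_g2) -> GroupTestResult:
    """Nonparametric test that two circular samples share a common median.

    The circle is split by the diameter perpendicular to the pooled circular
    median, i.e. into the half-circle centered on the median and the far
    half; per group the observations on each side form 2x2 counts and a
    chi-square statistic (1 df).  This split gives the test power against
    both small and antipodal median shifts.  When every observation falls on
    one side the split carries no evidence and the statistic is 0.
    """
    g1 = np.asarray(angles_g1, dtype=float)
    g2 = np.asarray(angles_g2, dtype=float)
    if g1.size < 5 or g2.size < 5:
        raise ValueError("each group needs at least 5 angles")
    pooled = np.concatenate([g1, g2])
    if np.abs(np.mean(np.exp(1j * pooled))) < 1e-12:
        return GroupTestResult(np.nan, 1, np.nan, pooled.size,
                               status="degenerate")
    med = circ_median(pooled)
    m = np.array([(np.cos(circ_dist(g, med)) < 0).sum() for g in (g1, g2)],
                 dtype=float)
    nn = np.array([g1.size, g2.size], dtype=float)
    N, M = nn.sum(), m.sum()
    if M == 0 or M == N:
        return GroupTestResult(0.0, 1, 1.0, int(N))
    P = N ** 2 / (M * (N - M)) * np.sum(m ** 2 / nn) - N * M / (N - M)
    P = max(0.0, float(P))
    return GroupTestResult(P, 1, float(sps.chi2.sf(P, 1)), int(N))


def rm_anova(values: np.ndarray, factors: list[tuple[str, tuple]]):
    """Main-effect F tests for a fully crossed two-level within-subject design.

    ``values`` is subjects x cells with cells ordered as the cartesian
    product of factor levels (first factor varying slowest).  Each factor's
    main effect uses the factor x subject interaction as its error term,
    giving F with df (1, n_subjects - 1).  Zero error variance is reported as
    a status ("F -> infinity"), not a number.
    """
    x = np.asarray(values, dtype=float)
    n_subj, n_cells = x.shape
    shape = tuple(len(levels) for _, levels in factors)
    if int(np.prod(shape)) != n_cells:
        raise ValueError("cell count does not match the factor structure")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    cube = x.reshape((n_subj,) + shape)
    out = {}
    for ax, (name, levels) in enumerate(factors):
        if len(levels) != 2:
            raise ValueError("two-level factors only")
        other = tuple(i + 1 for i in range(len(factors)) if i != ax)
        collapsed = cube.mean(axis=other) if other else cube  # subjects x 2
        grand = collapsed.mean()
        level_means = collapsed.mean(axis=0)
        subj_means = collapsed.mean(axis=1)
        ss_factor = n_subj * np.sum((level_means - grand) ** 2)
        resid = collapsed - subj_means[:, None] - level_means[None, :] + grand
        ss_err = np.sum(resid ** 2)
        df_err = n_subj - 1
        scale = np.sum((collapsed - grand) ** 2)
        eps = 1e-12 * max(scale, 1e-300)
        if ss_factor < eps:
            ss_factor = 0.0
        if ss_err < eps:
            ss_err = 0.0
        if ss_err == 0:
            status = "zero-error-variance" if ss_factor > 0 else "ok"
            f = np.inf if ss_factor > 0 else 0.0
            p = np.nan if ss_factor > 0 else 1.0
            out[name] = GroupTestResult(f, (1, df_err), p, n_subj, status=status)
            continue
        f = float(ss_factor / (ss_err / df_err))
        out[name] = GroupTestResult(f, (1, df_err), float(sps.f.sf(f, 1, df_err)),
                                    n_subj)
    return out


def rm_anova_cells(factors: list[tuple[str, tuple]]):
    """Cell label tuples in the order rm_anova expects."""
    return list(itertools.product(*[levels for _, levels in factors]))


def median_split(trial_table: pd.DataFrame, key: str = "reaction_time_ms",
                 group_cols=("condition",), ties: str = "fast"):
    """Label trials slow/fast by the within-group median of ``key``.

    The median is computed separately for each group (subject x condition in
    a cohort table); trials at or below the median are "fast" (tie rule
    config-exposed via ``ties``).  Returns (labels Series aligned to the
    table, list of degenerate group keys where all values were identical).
    """
    labels = pd.Series(index=trial_table.index, dtype=object)
    degenerate = []
    for gkey, sub in trial_table.groupby(list(group_cols)):
        if len(sub) < 2:
            raise ValueError("need at least 2 trials per group for a split")
        vals = sub[key].to_numpy(dtype=float)
        med = np.median(vals)
        if np.ptp(vals) == 0:
            degenerate.append(gkey)
        if ties == "fast":
            fast = vals <= med
        else:
            fast = vals < med
        labels.loc[sub.index] = np.where(fast, "fast", "slow")
    return labels, degenerate
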