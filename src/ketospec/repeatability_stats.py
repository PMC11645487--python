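"""Test–retest statistics for two-session MRSI studies.

Implements the repeatability battery used to compare a baseline session
(S1) with a post-intervention session (S2): paired Wilcoxon signed-rank
tests (exact enumeration at small n, mid-ranks for ties, zero differences
dropped), Bland–Altman bias with 1.96-SD limits of agreement, the
between-session coefficient of variation averaged across subjects, Spearman
rank correlation (exact permutation p at small n), and the correlation of
tumor ketone-body concentrations with segmented tumor sub-region volumes.

The difference direction is S2 - S1 throughout.  No multiple-testing
correction is applied; reports annotate raw p-values with the conventional
significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "RepeatabilityReport",
    "WilcoxonResult",
    "BlandAltmanResult",
    "wilcoxon_signed_rank",
    "bland_altman",
    "coefficient_of_variation",
    "spearman_rho",
    "correlate_kb_volumes",
    "build_report",
    "p_stars",
]


@dataclass
class PairedSeries:
    """Complete pairs of one quantity measured in both sessions."""

    subject: np.ndarray
    value_s1: np.ndarray
    value_s2: np.ndarray
    name: str = ""
    region: str = "tumor"

    def __post_init__(self):
        self.value_s1 = np.asarray(self.value_s1, dtype=float)
        self.value_s2 = np.asarray(self.value_s2, dtype=float)
        self.subject = np.asarray(self.subject)
        if not (self.subject.size == self.value_s1.size == self.value_s2.size):
            raise ValueError("paired series lengths differ")
        keep = np.isfinite(self.value_s1) & np.isfinite(self.value_s2)
        if not keep.all():  # listwise exclusion of incomplete pairs
            self.subject = self.subject[keep]
            self.value_s1 = self.value_s1[keep]
            self.value_s2 = self.value_s2[keep]

    @property
    def differences(self) -> np.ndarray:
        return self.value_s2 - self.value_s1

    def __len__(self):
        return self.value_s1.size


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ = rank sum of positive differences
    pvalue: float
    degenerate: bool = False


class BlandAltmanResult(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def _pairs_to_diff(pairs, y):
    if isinstance(pairs, PairedSeries):
        return pairs.differences
    x = np.asarray(pairs, dtype=float)
    if y is not None:
        return np.asarray(y, dtype=float) - x
    return x


EXACT_WILCOXON_MAX_N = 15


def wilcoxon_signed_rank(pairs, y=None) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Accepts a :class:`PairedSeries`, a precomputed difference array, or two
    arrays ``(s1, s2)`` (differences are S2 - S1).  Zero differences are
    dropped; tied absolute differences receive mid-ranks.  The p-value is an
    exact enumeration over all sign assignments for n <= 15 and a normal
    approximation with continuity and tie correction above.
    """
    d = _pairs_to_diff(pairs, y)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        dist = signs @ ranks
        p_le = np.mean(dist <= w_pos + 1e-12)
        p_ge = np.mean(dist >= w_pos - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, float(p), degenerate=False)


def bland_altman(pairs, y=None) -> BlandAltmanResult:
    """Bland–Altman bias (mean S2 - S1) and 1.96-SD limits of agreement."""
    d = _pairs_to_diff(pairs, y)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd)


def coefficient_of_variation(values) -> float:
    """Mean between-session CV (%) across subjects.

    ``values``: array of shape (n_subjects, n_sessions).  Per subject,
    CV = sd/mean (sample sd); the mean CV averages subjects, reported in %.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    means = v.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("per-subject means must be positive")
    cv = v.std(axis=1, ddof=1) / means
    return float(100.0 * cv.mean())


EXACT_SPEARMAN_MAX_N = 10


def _rho_of_ranks(rx, ry):
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    if denom == 0:
        raise ValueError("constant input")
    return float(np.sum(rx * ry) / denom)


def spearman_rho(x, y) -> tuple:
    """Spearman rank correlation with mid-rank ties.

    p-value: exact permutation over all orderings of one variable for
    n <= 10, a t-distribution approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt(np.sum(rxc ** 2) * np.sum(ryc ** 2))
        target = abs(np.sum(rxc * ryc))
        count = total = 0
        perm_iter = permutations(range(n))
        while True:
            chunk = list(islice(perm_iter, 100_000))
            if not chunk:
                break
            P = ryc[np.array(chunk)]
            s = np.abs(P @ rxc)
            count += int(np.sum(s >= target - 1e-9))
            total += len(chunk)
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
    return rho, float(p)


def correlate_kb_volumes(quants, masks, kb_names=("bhb", "acac"),
                         volume_classes=("necrotic_core", "ce_tumor"),
                         tumor_tissues=("ce_tumor", "necrotic_core")) -> pd.DataFrame:
    """Spearman correlations of tumor ketone-body levels with sub-region volumes.

    ``quants``/``masks``: per-subject QuantResult and SegMask sequences.
    Subjects without any accepted fit of a ketone body are excluded for that
    metabolite; at least 3 accepted subjects are required per correlation.
    Volumes are in mL from voxel counts times the voxel volume.
    """
    if len(quants) != len(masks):
        raise ValueError("quants and masks lengths differ")
    rows = []
    for kb in kb_names:
        conc, vols = [], {vc: [] for vc in volume_classes}
        for q, m in zip(quants, masks):
            c = q.subject_mean(kb, tissues=tumor_tissues)
            if not np.isfinite(c):
                continue
            conc.append(c)
            v = m.volumes()
            for vc in volume_classes:
                vols[vc].append(v[vc])
        for vc in volume_classes:
            if len(conc) < 3:
                raise ValueError(
                    f"fewer than 3 subjects with accepted {kb} fits")
            rho, p = spearman_rho(np.array(conc), np.array(vols[vc]))
            rows.append(dict(metabolite=kb, volume_class=vc, rho=rho, p=p,
                             n=len(conc)))
    return pd.DataFrame(rows)


def p_stars(p: float) -> str:
    """Conventional significance annotation of a raw p-value."""
    for threshold, stars in [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                             (0.05, "*")]:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class RepeatabilityReport:
    """Repeatability summary plus optional correlation table."""

    summary: pd.DataFrame
    correlations: pd.DataFrame = None
    note: str = "No multiple-testing correction applied."


def build_report(series_list, correlations: pd.DataFrame = None) -> RepeatabilityReport:
    """Summarize Wilcoxon / Bland–Altman / CV per paired series."""
    rows = []
    for s in series_list:
        w = wilcoxon_signed_rank(s)
        ba = bland_altman(s)
        cv = coefficient_of_variation(np.column_stack([s.value_s1, s.value_s2]))
        rows.append(dict(
            name=s.name, region=s.region, n=len(s),
            wilcoxon_p=w.pvalue, stars=p_stars(w.pvalue),
            degenerate=w.degenerate,
            bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
            mean_cv_pct=cv,
        ))
    return RepeatabilityReport(summary=pd.DataFrame(rows),
                               correlations=correlations)
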