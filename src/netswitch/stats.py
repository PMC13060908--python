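"""Drowsy-vs-alert group comparisons and the moderation model.

Conventions follow the motivating analysis: the Mann-Whitney U statistic is
reported on the alert side (U = n_d n_a + n_a(n_a+1)/2 - R_alert), the normal
approximation z (with midrank tie correction, no continuity correction) is
positive when the drowsy group ranks higher, the effect size is the
rank-biserial r = z / sqrt(N), and multiplicity is handled per family with
Benjamini-Hochberg FDR. The moderation model is an ordinary least-squares fit
of accuracy on {1, switching, drowsy, switching x drowsy} with a two-sided
t-test on the interaction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    measure_id: str
    n_drowsy: int
    n_alert: int
    U: float
    rank_mean_drowsy: float
    rank_mean_alert: float
    z: float
    r: float
    p: float
    q: float | None = None  # attached by the family-level FDR step

    def __post_init__(self) -> None:
        if not 0 <= self.U <= self.n_drowsy * self.n_alert:
            raise ValueError("U out of range [0, n_d * n_a]")


def mann_whitney(
    drowsy: np.ndarray, alert: np.ndarray, measure_id: str = ""
) -> GroupComparison:
    """Mann-Whitney U comparison of a scalar scan measure across states.

    Midranks are assigned over the pooled sample; z uses the tie-corrected
    normal approximation and is positive when drowsy values rank higher.
    If every pooled value is identical, z = 0 and p = 1.
    """
    d = np.asarray(drowsy, float)
    a = np.asarray(alert, float)
    if d.size == 0 or a.size == 0:
        raise ValueError("both groups must be non-empty")
    nd, na = d.size, a.size
    n = nd + na
    pooled = np.concatenate([d, a])
    ranks = sps.rankdata(pooled)
    r_alert = ranks[nd:].sum()
    u = nd * na + na * (na + 1) / 2 - r_alert

    # tie correction for the variance of U
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = nd * na / 12 * ((n + 1) - tie_term)
    if var_u == 0:
        z = 0.0
        p = 1.0
    else:
        z = (u - nd * na / 2) / np.sqrt(var_u)
        p = 2 * sps.norm.sf(abs(z))
    return GroupComparison(
        measure_id=measure_id,
        n_drowsy=nd,
        n_alert=na,
        U=float(u),
        rank_mean_drowsy=float(ranks[:nd].mean()),
        rank_mean_alert=float(ranks[nd:].mean()),
        z=float(z),
        r=float(z / np.sqrt(n)),
        p=float(min(p, 1.0)),
    )


def rank_biserial(drowsy: np.ndarray, alert: np.ndarray) -> float:
    """The z / sqrt(N) effect size of the drowsy-vs-alert comparison."""
    return mann_whitney(drowsy, alert).r


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(comparisons: list[GroupComparison]) -> list[GroupComparison]:
    """Attach BH-FDR q-values across a family of comparisons."""
    qs = bh_fdr(np.array([c.p for c in comparisons]))
    for c, q in zip(comparisons, qs):
        c.q = float(q)
    return comparisons


@dataclass
class ModerationFit:
    """OLS fit of accuracy on switching, arousal (drowsy=1), and their
    interaction."""

    coefficients: np.ndarray  # beta0..beta3
    standard_errors: np.ndarray
    interaction_p: float
    n: int
    interaction_q: float | None = None
    term_names: tuple[str, ...] = (
        "intercept",
        "switching",
        "drowsy",
        "switching_x_drowsy",
    )

    @property
    def interaction_beta(self) -> float:
        return float(self.coefficients[3])

    def simple_slopes(self) -> tuple[float, float]:
        """Fitted switching slope in the alert and drowsy groups."""
        b = self.coefficients
        return float(b[1]), float(b[1] + b[3])


def moderation_test(
    accuracy: np.ndarray, switching: np.ndarray, arousal: list[str]
) -> ModerationFit:
    """Test whether arousal state moderates the switching-accuracy slope."""
    acc = np.asarray(accuracy, float)
    sw = np.asarray(switching, float)
    if not (acc.size == sw.size == len(arousal)):
        raise ValueError("accuracy, switching and arousal must have equal lengths")
    drowsy = np.array([1.0 if s == "drowsy" else 0.0 for s in arousal])
    if drowsy.min() == drowsy.max():
        raise ValueError("both arousal levels must be present")
    if sw.min() == sw.max():
        raise ValueError("switching is constant; the design is rank deficient")
    if acc.size < 5:
        raise ValueError("need at least 5 observations")
    design = np.column_stack([np.ones(acc.size), sw, drowsy, sw * drowsy])
    rank = np.linalg.matrix_rank(design)
    if rank < 4:
        raise ValueError(
            "rank-deficient design: switching does not vary within one of the "
            "arousal groups (switching x drowsy is collinear)"
        )
    fit = sm.OLS(acc, design).fit()
    return ModerationFit(
        coefficients=np.asarray(fit.params, float),
        standard_errors=np.asarray(fit.bse, float),
        interaction_p=float(fit.pvalues[3]),
        n=int(acc.size),
    )


def moderation_family(fits: list[ModerationFit]) -> list[ModerationFit]:
    """BH-FDR across the tested outcomes of a moderation family."""
    qs = bh_fdr(np.array([f.interaction_p for f in fits]))
    for f, q in zip(fits, qs):
        f.interaction_q = float(q)
    return fits
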