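"""Hemisphere-flow comparison, group statistics and metric-outcome correlation.

Group comparisons follow the classical parametric toolkit: paired t tests on
pre/post SAM changes within groups, one-way MANOVA (Wilks Lambda with Rao's
F approximation and the multivariate partial eta squared 1 - Lambda^(1/s),
s = min(p, df_hypothesis)) across the three groups, Tukey HSD for pairwise
follow-ups, and Pearson correlation between nodal graph metrics and
subjective/behavioral outcomes.  Correlation p-values are reported
uncorrected (the selection rule is an explicit list of band/metric/outcome
combinations); a Benjamini-Hochberg column is emitted additionally and is
clearly labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import PSIMatrix
from .montage import Montage

#: anterior-posterior electrode pairs compared between hemispheres,
#: (label, left-hemisphere pair, right-hemisphere pair); the anterior
#: electrode is always the prefrontal Fp1/Fp2 site
HEMI_PAIRS: tuple[tuple[str, tuple[str, str], tuple[str, str]], ...] = (
    ("FP1/2-F3/4", ("Fp1", "F3"), ("Fp2", "F4")),
    ("FP1/2-FC1/2", ("Fp1", "FC1"), ("Fp2", "FC2")),
    ("FP1/2-FC5/6", ("Fp1", "FC5"), ("Fp2", "FC6")),
    ("FP1/2-C3/4", ("Fp1", "C3"), ("Fp2", "C4")),
    ("FP1/2-CP1/2", ("Fp1", "CP1"), ("Fp2", "CP2")),
    ("FP1/2-CP5/6", ("Fp1", "CP5"), ("Fp2", "CP6")),
    ("FP1/2-P3/4", ("Fp1", "P3"), ("Fp2", "P4")),
    ("FP1/2-O1/2", ("Fp1", "O1"), ("Fp2", "O2")),
)


def hemisphere_flow(psim: PSIMatrix, montage: Montage | None = None,
                    pairs=HEMI_PAIRS) -> pd.DataFrame:
    """Mean |PSI| per anterior-posterior pair and hemisphere.

    The signed direction summary is the normalized PSI from the anterior to
    the posterior electrode: positive values mean anterior -> posterior
    information flow.
    """
    labels = list(psim.labels)
    rows = []
    for name, (la, lp), (ra, rp) in pairs:
        for ch in (la, lp, ra, rp):
            if ch not in labels:
                raise ValueError(f"channel {ch!r} missing from PSI matrix")
        ia, ip = labels.index(la), labels.index(lp)
        ja, jp = labels.index(ra), labels.index(rp)
        rows.append({
            "pair": name,
            "band": psim.band,
            "lh_mean_abs_psi": abs(psim.psi[ia, ip]),
            "rh_mean_abs_psi": abs(psim.psi[ja, jp]),
            "lh_signed": psim.psi[ia, ip],
            "rh_signed": psim.psi[ja, jp],
        })
    return pd.DataFrame(rows)


@dataclass
class GroupStats:
    test: str
    statistic: float
    df: tuple
    p: float
    wilks_lambda: float | None = None
    partial_eta_sq: float | None = None
    pairwise_p: dict = field(default_factory=dict)


def paired_t(pre: np.ndarray, post: np.ndarray) -> GroupStats:
    """Classical paired t test (two-tailed), df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("need n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return GroupStats("paired_t", 0.0, (n - 1,), 1.0)
        raise ValueError("zero variance of nonzero differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return GroupStats("paired_t", float(t), (n - 1,), float(p))


def group_manova(outcomes: np.ndarray, groups: np.ndarray) -> GroupStats:
    """One-way MANOVA: Wilks Lambda, Rao's F approximation, partial eta^2.

    ``outcomes`` is subjects x variables; ``groups`` the per-subject labels.
    Lambda = det(E) / det(E + H) with E the pooled within-group and H the
    between-group SSCP matrices; partial eta^2 = 1 - Lambda^(1/s) with
    s = min(p, g - 1).
    """
    Y = np.atleast_2d(np.asarray(outcomes, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    groups = np.asarray(groups)
    if len(groups) != Y.shape[0]:
        raise ValueError("groups length must match outcome rows")
    labels = pd.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = Y.shape
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for lab in labels:
        Yg = Y[groups == lab]
        mg = Yg.mean(axis=0)
        R = Yg - mg
        E += R.T @ R
        dm = (mg - grand)[:, None]
        H += len(Yg) * (dm @ dm.T)
    if np.linalg.matrix_rank(E) < p:
        raise ValueError("singular within-group covariance")
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    df_h = g - 1
    df_e = n - g
    # Rao's F approximation
    if p ** 2 + df_h ** 2 - 5 > 0:
        t = np.sqrt((p ** 2 * df_h ** 2 - 4) / (p ** 2 + df_h ** 2 - 5))
    else:
        t = 1.0
    w = df_e + df_h - (p + df_h + 1) / 2.0
    df1 = p * df_h
    df2 = w * t - (p * df_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    s = min(p, df_h)
    eta = 1.0 - lam ** (1.0 / s)
    return GroupStats("manova_wilks", float(F), (df1, float(df2)), pval,
                      wilks_lambda=lam, partial_eta_sq=float(eta))


def tukey_hsd(outcome: np.ndarray, groups: np.ndarray) -> GroupStats:
    """Tukey HSD pairwise comparisons on one outcome.

    Uses the studentized-range distribution with the harmonic-mean group
    size under mild imbalance.
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [y[groups == lab] for lab in labels]
    sizes = np.array([len(s) for s in samples])
    if np.any(sizes < 2):
        small = [str(labels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    k = len(labels)
    df_e = int(sizes.sum() - k)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_e
    n_h = k / np.sum(1.0 / sizes)  # harmonic mean group size
    se = np.sqrt(mse / n_h)
    pairwise = {}
    qmax = 0.0
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        q = abs(samples[i].mean() - samples[j].mean()) / se
        pw = float(sps.studentized_range.sf(q, k, df_e))
        pairwise[(str(a), str(b))] = pw
        qmax = max(qmax, q)
    pmin = min(pairwise.values())
    return GroupStats("tukey_hsd", float(qmax), (k, df_e), float(pmin),
                      pairwise_p=pairwise)


def correlate_metrics(metrics: pd.DataFrame, outcomes: pd.DataFrame,
                      selection: list[tuple[str, str, str]] | None = None,
                      alpha: float = 0.05,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of nodal graph metrics with outcomes.

    ``metrics`` has columns (subject, band, metric, electrode, value);
    ``outcomes`` has columns (subject, outcome, value).  ``selection``
    optionally restricts to (band, metric, outcome) combinations.  Returns
    the full table and the significant-rows view (uncorrected p < alpha).
    A Benjamini-Hochberg adjusted column ``p_bh`` (not part of the original
    selection rule) is included in both.
    """
    need_m = {"subject", "band", "metric", "electrode", "value"}
    need_o = {"subject", "outcome", "value"}
    if not need_m <= set(metrics.columns):
        raise ValueError(f"metrics table needs columns {sorted(need_m)}")
    if not need_o <= set(outcomes.columns):
        raise ValueError(f"outcomes table needs columns {sorted(need_o)}")
    rows = []
    for (band, metric, electrode), dm in metrics.groupby(
            ["band", "metric", "electrode"], sort=True):
        for outcome, do in outcomes.groupby("outcome", sort=True):
            if selection is not None and (band, metric, outcome) not in selection:
                continue
            merged = pd.merge(dm[["subject", "value"]],
                              do[["subject", "value"]],
                              on="subject", suffixes=("_m", "_o"))
            if len(merged) < 4:
                continue
            x = merged["value_m"].to_numpy()
            y = merged["value_o"].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # constant metric or outcome: r undefined
            r, p = sps.pearsonr(x, y)
            rows.append({"band": band, "metric": metric,
                         "electrode": electrode, "outcome": outcome,
                         "n": len(merged), "r": float(r), "p": float(p)})
    full = pd.DataFrame(rows, columns=["band", "metric", "electrode",
                                       "outcome", "n", "r", "p"])
    if len(full):
        from statsmodels.stats.multitest import multipletests
        full["p_bh"] = multipletests(full["p"], method="fdr_bh")[1]
    else:
        full["p_bh"] = pd.Series(dtype=float)
    sig = full[full["p"] < alpha].reset_index(drop=True)
    return full, sig


#: default (band, metric, outcome) selection for the correlation analysis:
#: segregation/centrality metrics in theta and alpha, local efficiency in
#: alpha, against the outcomes that show group effects
DEFAULT_CORR_SELECTION: list[tuple[str, str, str]] = [
    (band, metric, outcome)
    for band, metric in (
        ("theta", "CC"), ("theta", "BC"),
        ("alpha", "CC"), ("alpha", "BC"), ("alpha", "LE"),
    )
    for outcome in ("dV", "dA", "RT1", "ACC2")
]
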