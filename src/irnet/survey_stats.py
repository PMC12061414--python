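"""Survey-weighted descriptive statistics and marker-performance metrics.

Estimators for complex survey samples (weight / stratum / PSU design):
weighted cross-tabulations, the Rao-Scott corrected chi-square test of
independence (second-order, Satterthwaite-adjusted, referred to an F
distribution), weighted mutual information with an uncertainty-coefficient
normalization, and a weighted ROC / AUC.

All estimators are invariant to a global rescaling of the weights and
collapse to their classical unweighted counterparts when every weight is
equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedCrosstab",
    "TestResult",
    "weighted_proportions",
    "rao_scott_chi2",
    "weighted_mutual_information",
    "roc_auc",
]


class UndefinedMarginError(ValueError):
    pass


class UndefinedEntropyError(ValueError):
    pass


class UndefinedAUCError(ValueError):
    pass


class SingletonPSUError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weighted cross-tabulations
# ---------------------------------------------------------------------------

@dataclass
class WeightedCrosstab:
    """Weighted totals and raw counts of ``row_var`` by ``col_var``."""

    row_var: str
    col_var: str | None
    weighted: pd.DataFrame
    counts: pd.DataFrame
    design: dict

    @property
    def proportions(self) -> pd.DataFrame:
        """Cell proportion within each column margin (weighted)."""
        tot = self.weighted.sum(axis=0)
        if (tot <= 0).any():
            raise UndefinedMarginError(
                f"zero total weight in margin(s) {tot.index[tot <= 0].tolist()}")
        return self.weighted / tot

    @property
    def overall(self) -> pd.Series:
        tot = self.weighted.to_numpy().sum()
        return self.weighted.sum(axis=1) / tot


def weighted_proportions(df, var, by=None, weight="weight",
                         stratum="stratum", psu="psu") -> WeightedCrosstab:
    """Weighted frequency table of ``var`` (optionally split by ``by``)."""
    w = pd.to_numeric(df[weight], errors="raise")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    cols = df[by] if by is not None else pd.Series("all", index=df.index)
    weighted = pd.crosstab(df[var], cols, values=w, aggfunc="sum", dropna=False).fillna(0.0)
    counts = pd.crosstab(df[var], cols, dropna=False)
    tab = WeightedCrosstab(
        row_var=var, col_var=by, weighted=weighted, counts=counts,
        design={"weight": weight, "stratum": stratum, "psu": psu})
    tot = weighted.to_numpy().sum()
    if tot <= 0:
        raise UndefinedMarginError("zero total weight")
    return tab


# ---------------------------------------------------------------------------
# Rao-Scott chi-square
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    correction: dict

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def _design_cov(z: np.ndarray, strata, psus, singleton: str = "error"):
    """Stratified between-PSU covariance of a total of linearized scores.

    ``z`` is (n, k); PSU totals are centered at their stratum mean with the
    usual ``a_h / (a_h - 1)`` factor.  A stratum with one PSU contributes
    zero when ``singleton='center'`` (logged), or raises otherwise.
    """
    k = z.shape[1]
    V = np.zeros((k, k))
    design_df = 0
    frame = pd.DataFrame({"stratum": np.asarray(strata), "psu": np.asarray(psus)})
    for _, sub in frame.groupby("stratum", observed=True):
        idx = sub.index.to_numpy()
        psu_tot = pd.DataFrame(z[idx]).groupby(sub["psu"].to_numpy()).sum().to_numpy()
        a_h = psu_tot.shape[0]
        if a_h < 2:
            if singleton == "center":
                logger.warning("rao_scott_chi2: singleton PSU stratum contributes "
                               "zero variance")
                continue
            raise SingletonPSUError("a stratum contains a single PSU")
        centered = psu_tot - psu_tot.mean(axis=0)
        V += (a_h / (a_h - 1)) * centered.T @ centered
        design_df += a_h - 1
    return V, design_df


def rao_scott_chi2(df, var, outcome, weight="weight", stratum="stratum",
                   psu="psu", singleton: str = "error") -> TestResult:
    """Design-corrected test of independence between two categorical columns.

    The Pearson statistic is computed on the weighted proportions and
    referred to an F distribution after the second-order Rao-Scott
    correction: the generalized design-effect matrix ``Delta`` compares the
    linearized design covariance of the independence residuals with their
    multinomial covariance; ``F = X2 / tr(Delta)`` with numerator df
    ``tr(Delta)^2 / tr(Delta^2)`` (Satterthwaite) and denominator df scaled
    by the design degrees of freedom (PSUs minus strata).
    """
    work = df[[var, outcome, weight, stratum, psu]].dropna().reset_index(drop=True)
    n = len(work)
    w = pd.to_numeric(work[weight]).to_numpy(dtype=float)
    r_lab = [x for x in pd.unique(work[var]) if pd.notna(x)]
    c_lab = [x for x in pd.unique(work[outcome]) if pd.notna(x)]
    r_lab, c_lab = sorted(map(str, r_lab)), sorted(map(str, c_lab))
    R, C = len(r_lab), len(c_lab)
    if R < 2 or C < 2:
        raise ValueError("both variables need >= 2 observed levels")
    ri = pd.Categorical(work[var].astype(str), categories=r_lab).codes
    ci = pd.Categorical(work[outcome].astype(str), categories=c_lab).codes

    cell = ri * C + ci
    W = np.bincount(cell, weights=w, minlength=R * C).reshape(R, C)
    wtot = w.sum()
    p = W / wtot
    prow, pcol = p.sum(axis=1), p.sum(axis=0)
    E = np.outer(prow, pcol)
    mask = E > 0
    X2 = n * float(((p - E)[mask] ** 2 / E[mask]).sum())

    # linearized scores of the cell proportions
    y = np.zeros((n, R * C))
    y[np.arange(n), cell] = 1.0
    z = (w[:, None] * (y - p.ravel()[None, :])) / wtot
    V, design_df = _design_cov(z, work[stratum], work[psu],
                               singleton="center" if singleton != "error" else "error")
    if design_df < 1:
        raise SingletonPSUError("no design degrees of freedom for variance estimation")
    V0 = (np.diag(p.ravel()) - np.outer(p.ravel(), p.ravel())) / n

    # Jacobian of the independence residuals u_rc = p_rc - p_r. * p_.c
    # over the first (R-1) x (C-1) cells
    m = (R - 1) * (C - 1)
    H = np.zeros((m, R * C))
    for a in range(R - 1):
        for b in range(C - 1):
            row = a * (C - 1) + b
            # du/dp_ij = 1{i=a,j=b} - 1{i=a} p_.b - 1{j=b} p_a.
            for i in range(R):
                for j in range(C):
                    v = (1.0 if (i == a and j == b) else 0.0)
                    if i == a:
                        v -= pcol[b]
                    if j == b:
                        v -= prow[a]
                    H[row, i * C + j] = v

    G0 = H @ V0 @ H.T
    G = H @ V @ H.T
    delta = np.linalg.solve(G0, G) if np.linalg.matrix_rank(G0) == m else (
        np.linalg.pinv(G0) @ G)
    t1 = float(np.trace(delta))
    t2 = float(np.trace(delta @ delta))
    eig_mean = t1 / m
    if t1 <= 0 or t2 <= 0:
        # degenerate design covariance (e.g. exact independence): fall back
        # to the uncorrected chi-square
        pval = float(stats.chi2.sf(X2, m))
        return TestResult(statistic=X2, df=float(m), p_value=pval,
                          correction={"method": "uncorrected", "pearson_x2": X2,
                                      "design_df": design_df})
    df1 = t1 * t1 / t2
    df2 = df1 * design_df
    F = X2 / t1
    pval = float(stats.f.sf(F, df1, df2))
    cv2 = t2 * m / (t1 * t1) - 1.0
    return TestResult(
        statistic=float(F), df=float(df1), p_value=pval,
        correction={
            "method": "rao-scott-second-order-F",
            "pearson_x2": X2,
            "mean_deff": eig_mean,
            "eig_cv2": float(cv2),
            "df_num": float(df1),
            "df_den": float(df2),
            "design_df": design_df,
        })


# ---------------------------------------------------------------------------
# Weighted mutual information
# ---------------------------------------------------------------------------

def weighted_mutual_information(df, var, outcome, weight="weight") -> dict:
    """Plug-in MI of the weighted joint distribution, in nats, plus the
    uncertainty-coefficient normalization 100 * MI / H(outcome)."""
    work = df[[var, outcome, weight]].dropna()
    w = pd.to_numeric(work[weight]).to_numpy(dtype=float)
    joint = pd.crosstab(work[var], work[outcome], values=w, aggfunc="sum",
                        dropna=False).fillna(0.0).to_numpy()
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    if (py > 0).sum() < 2:
        raise UndefinedEntropyError(f"{outcome!r} has a single observed level")
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    pyv = py.ravel()[py.ravel() > 0]
    h = float(-(pyv * np.log(pyv)).sum())
    return {"mi_nats": max(mi, 0.0), "normalized_pct": 100.0 * max(mi, 0.0) / h,
            "outcome_entropy_nats": h}


# ---------------------------------------------------------------------------
# Weighted ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, weights=None) -> dict:
    """Weighted AUC (Mann-Whitney with ties counted 1/2) and ROC curve.

    ``labels`` are binary (1 / "yes" = positive).  The curve lists
    ``(threshold, fpr, tpr)`` for the rule "positive if score >= threshold"
    at every distinct score, plus the two trivial endpoints.
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray([1 if str(x) in ("1", "yes", "True", "1.0") else 0 for x in labels])
    w = np.ones_like(scores) if weights is None else np.asarray(weights, dtype=float)
    ok = ~np.isnan(scores)
    scores, lab, w = scores[ok], lab[ok], w[ok]
    wp = w[lab == 1].sum()
    wn = w[lab == 0].sum()
    if wp <= 0 or wn <= 0:
        raise UndefinedAUCError("both classes must be present with positive weight")
    order = np.argsort(scores, kind="mergesort")
    s, la, wo = scores[order], lab[order], w[order]
    uniq, start = np.unique(s, return_index=True)
    bounds = np.append(start, len(s))
    auc = 0.0
    cum_neg = 0.0
    pos_w, neg_w = [], []
    for i in range(len(uniq)):
        seg = slice(bounds[i], bounds[i + 1])
        wp_i = wo[seg][la[seg] == 1].sum()
        wn_i = wo[seg][la[seg] == 0].sum()
        auc += wp_i * (cum_neg + 0.5 * wn_i)
        cum_neg += wn_i
        pos_w.append(wp_i)
        neg_w.append(wn_i)
    auc /= wp * wn
    # curve: thresholds descending; predict positive when score >= threshold
    pos_w = np.asarray(pos_w)[::-1]
    neg_w = np.asarray(neg_w)[::-1]
    tpr = np.cumsum(pos_w) / wp
    fpr = np.cumsum(neg_w) / wn
    curve = pd.DataFrame({
        "threshold": np.concatenate(([np.inf], uniq[::-1])),
        "fpr": np.concatenate(([0.0], fpr)),
        "tpr": np.concatenate(([0.0], tpr)),
    })
    return {"auc": float(auc), "curve": curve}
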