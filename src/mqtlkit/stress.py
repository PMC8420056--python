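"""Drought-responsive metabolite calling.

A metabolite is called drought-responsive by the intersection of three
criteria: OPLS-DA variable importance for the projection (VIP) >= 1,
Benjamini-Hochberg FDR of the paired WW-vs-DS t-test <= 0.05, and raw-scale
fold change DS/WW >= 2 or <= 0.5. OPLS-DA is implemented from first
principles (single predictive component, Trygg-Wold orthogonal filtering),
with VIP normalized so the mean squared VIP over metabolites equals one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteMatrix


# ---------------------------------------------------------------------------
# PCA over the stacked condition samples
# ---------------------------------------------------------------------------

def pca_conditions(
    ww: MetaboliteMatrix, ds: MetaboliteMatrix, n_pc: int = 2,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of line x condition samples stacked over the shared metabolites.

    Returns per-sample scores (index ``<line>:<condition>``) and the
    variance fraction of each component, sorted descending.
    """
    common = [m for m in ww.metabolite_ids if m in set(ds.metabolite_ids)]
    X = np.vstack([ww.values[common].to_numpy(dtype=float),
                   ds.values[common].to_numpy(dtype=float)])
    labels = ([f"{l}:WW" for l in ww.line_ids] + [f"{l}:DS" for l in ds.line_ids])
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    rank = min(Xc.shape) - 1 if min(Xc.shape) > 1 else 1
    if n_pc > rank:
        warnings.warn(f"n_pc={n_pc} exceeds rank {rank}; clamped")
        n_pc = rank
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = pd.DataFrame(U[:, :n_pc] * s[:n_pc], index=labels,
                          columns=[f"PC{i + 1}" for i in range(n_pc)])
    return scores, frac[:n_pc]


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted two-class O-PLS model (one predictive component).

    ``w`` is the unit predictive weight vector over the modeled metabolites,
    ``t`` the predictive scores, ``t_ortho``/``p_ortho`` the orthogonal
    score/loading pairs, ``r2y`` the fraction of class variance captured by
    the predictive component and ``vip`` the per-metabolite importance
    (mean squared VIP = 1). ``columns`` names the metabolites actually
    modeled (zero-variance columns are excluded).
    """

    w: np.ndarray
    t: np.ndarray
    t_ortho: list[np.ndarray]
    p_ortho: list[np.ndarray]
    r2y: float
    vip: pd.Series
    columns: list[str] = field(default_factory=list)


def fit_oplsda(
    X: pd.DataFrame, labels: pd.Series | np.ndarray, n_ortho: int = 1,
) -> OplsModel:
    """Two-class OPLS-DA on a samples x metabolites matrix.

    Metabolites are centered and scaled to unit variance; the class vector
    is the centered indicator of the two label values. Orthogonal variation
    is removed by ``n_ortho`` rounds of Trygg-Wold deflation (the loading's
    y-orthogonal part defines each orthogonal component) before the final
    predictive component w proportional to X'y.
    """
    y_raw = pd.Series(np.asarray(labels), index=X.index)
    classes = sorted(y_raw.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two label classes, got {classes}")
    y = (y_raw == classes[1]).to_numpy(dtype=float)
    y = y - y.mean()

    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} zero-variance metabolite(s)")
    cols = [c for c in X.columns if c not in set(dropped)]
    Xs = ((X[cols] - X[cols].mean(axis=0)) / sd[cols]).to_numpy(dtype=float)

    t_orthos, p_orthos = [], []
    Xf = Xs.copy()
    for _ in range(n_ortho):
        w = Xf.T @ y
        w /= np.linalg.norm(w)
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w  # y-orthogonal part of the loading
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        t_orthos.append(t_o)
        p_orthos.append(p_o)

    w = Xf.T @ y
    w /= np.linalg.norm(w)
    t = Xf @ w
    c = (t @ y) / (t @ t)
    r2y = float(1.0 - np.sum((y - t * c) ** 2) / np.sum(y**2))

    # VIP over the single predictive component: ssy weights cancel
    p_m = len(cols)
    vip = np.sqrt(p_m) * np.abs(w)
    vip_s = pd.Series(vip, index=cols).reindex(X.columns)
    return OplsModel(w=w, t=t, t_ortho=t_orthos, p_ortho=p_orthos, r2y=r2y,
                     vip=vip_s, columns=cols)


# ---------------------------------------------------------------------------
# paired testing and classification
# ---------------------------------------------------------------------------

def paired_test(ww: MetaboliteMatrix, ds: MetaboliteMatrix) -> pd.DataFrame:
    """Two-sided paired t-test per metabolite on log values, BH-adjusted.

    Lines missing either condition's value are dropped pairwise; metabolites
    with fewer than 3 complete pairs get missing p and are excluded from the
    BH family size. Identical WW and DS values (zero difference variance)
    give p = 1.
    """
    common = [m for m in ww.metabolite_ids if m in set(ds.metabolite_ids)]
    lines = [l for l in ww.line_ids if l in set(ds.line_ids)]
    A = ww.values.loc[lines, common].to_numpy(dtype=float)
    B = ds.values.loc[lines, common].to_numpy(dtype=float)
    t_stat = np.full(len(common), np.nan)
    p_raw = np.full(len(common), np.nan)
    n_pairs = np.zeros(len(common), dtype=int)
    for j in range(len(common)):
        ok = ~(np.isnan(A[:, j]) | np.isnan(B[:, j]))
        n_pairs[j] = ok.sum()
        if n_pairs[j] < 3:
            continue
        diff = B[ok, j] - A[ok, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            t_stat[j] = 0.0
            p_raw[j] = 1.0
            continue
        res = stats.ttest_rel(B[ok, j], A[ok, j])
        t_stat[j], p_raw[j] = float(res.statistic), float(res.pvalue)
    fdr = np.full(len(common), np.nan)
    tested = ~np.isnan(p_raw)
    if tested.any():
        fdr[tested] = multipletests(p_raw[tested], method="fdr_bh")[1]
    return pd.DataFrame({"t_stat": t_stat, "p_raw": p_raw, "fdr": fdr,
                         "n_pairs": n_pairs}, index=common)


def fold_change(ww: MetaboliteMatrix, ds: MetaboliteMatrix) -> pd.Series:
    """Raw-scale fold change DS/WW per metabolite over pairwise-complete lines."""
    common = [m for m in ww.metabolite_ids if m in set(ds.metabolite_ids)]
    lines = [l for l in ww.line_ids if l in set(ds.line_ids)]
    A = ww.raw_values().loc[lines, common].to_numpy(dtype=float)
    B = ds.raw_values().loc[lines, common].to_numpy(dtype=float)
    fc = np.full(len(common), np.nan)
    for j in range(len(common)):
        ok = ~(np.isnan(A[:, j]) | np.isnan(B[:, j]))
        if ok.sum() == 0:
            continue
        denom = A[ok, j].mean()
        if denom > 0:
            fc[j] = B[ok, j].mean() / denom
    return pd.Series(fc, index=common, name="fc")


def classify_responsive(
    vip: pd.Series, fdr: pd.Series, fc: pd.Series,
    vip_min: float = 1.0, fdr_max: float = 0.05, fc_min: float = 2.0,
) -> pd.DataFrame:
    """Apply the three-criterion intersection rule.

    responsive iff VIP >= vip_min AND FDR <= fdr_max AND
    (FC >= fc_min OR FC <= 1/fc_min); direction is up for FC >= fc_min,
    down for FC <= 1/fc_min. A metabolite with any missing statistic is
    never responsive and is flagged ``incomplete``.
    """
    idx = vip.index
    vip = vip.reindex(idx)
    fdr = fdr.reindex(idx)
    fc = fc.reindex(idx)
    incomplete = vip.isna() | fdr.isna() | fc.isna()
    up = fc >= fc_min
    down = fc <= 1.0 / fc_min
    responsive = ((vip >= vip_min) & (fdr <= fdr_max) & (up | down)
                  & ~incomplete)
    direction = np.where(responsive & up, "up",
                         np.where(responsive & down, "down", "none"))
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc.to_numpy(dtype=float))
    return pd.DataFrame({"vip": vip, "fc": fc, "log2fc": log2fc, "fdr": fdr,
                         "responsive": responsive.fillna(False),
                         "direction": direction,
                         "incomplete": incomplete}, index=idx)


def drought_response_table(
    ww: MetaboliteMatrix, ds: MetaboliteMatrix,
    vip_min: float = 1.0, fdr_max: float = 0.05, fc_min: float = 2.0,
    n_ortho: int = 1,
) -> pd.DataFrame:
    """End-to-end drought-response calling on two processed matrices.

    Fits OPLS-DA on the stacked log matrices (class = condition), runs the
    paired t-test, computes raw-scale fold changes, and intersects the three
    criteria. Returns one row per shared metabolite with every statistic
    plus the call.
    """
    common = [m for m in ww.metabolite_ids if m in set(ds.metabolite_ids)]
    lines = [l for l in ww.line_ids if l in set(ds.line_ids)]
    stacked = pd.concat([ww.values.loc[lines, common],
                         ds.values.loc[lines, common]], axis=0,
                        ignore_index=True)
    stacked = stacked.fillna(stacked.mean(axis=0))
    labels = np.array(["WW"] * len(lines) + ["DS"] * len(lines))
    model = fit_oplsda(stacked, labels, n_ortho=n_ortho)
    tests = paired_test(ww, ds)
    fc = fold_change(ww, ds)
    out = classify_responsive(model.vip.reindex(common), tests["fdr"], fc,
                              vip_min=vip_min, fdr_max=fdr_max, fc_min=fc_min)
    out["t_stat"] = tests["t_stat"]
    out["p_raw"] = tests["p_raw"]
    out["n_pairs"] = tests["n_pairs"]
    return out
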