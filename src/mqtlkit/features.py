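"""Feature-table processing: missingness filter, redundancy collapse, normalization.

The processing order mirrors standard population-metabolomics practice:
features missing in more than 20% of lines under either growth condition
are dropped; redundant features derived from the same metabolite (adducts,
in-source fragments, the same compound seen in both ionization modes) are
collapsed by retention-time proximity plus cross-line intensity
correlation; the collapsed matrices are then median-normalized, imputed and
log-transformed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FeatureTable, MetaboliteMatrix


def filter_missingness(
    ww: FeatureTable, ds: FeatureTable, max_missing: float = 0.2
) -> tuple[FeatureTable, FeatureTable]:
    """Drop features missing in more than ``max_missing`` of lines in either condition.

    Removal is always by feature, never by line: a feature is retained iff
    its missing fraction is <= ``max_missing`` in WW **and** in DS.
    """
    if set(ww.line_ids) != set(ds.line_ids):
        raise ValueError("WW and DS tables must share the same line set")
    shared = [f for f in ww.feature_ids if f in set(ds.feature_ids)]
    miss_ww = ww.intensities.loc[shared].isna().mean(axis=1)
    miss_ds = ds.intensities.loc[shared].isna().mean(axis=1)
    keep = [f for f in shared
            if miss_ww[f] <= max_missing and miss_ds[f] <= max_missing]
    return (
        FeatureTable(meta=ww.meta.loc[keep], condition="WW",
                     intensities=ww.intensities.loc[keep]),
        FeatureTable(meta=ds.meta.loc[keep], condition="DS",
                     intensities=ds.intensities.loc[keep, ww.intensities.columns]),
    )


def _components(ids: list[str], adjacency: dict[str, set[str]]) -> list[list[str]]:
    """Connected components; member order and component order follow ``ids``."""
    seen: set[str] = set()
    comps = []
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adjacency.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        comps.append(sorted(comp))
    return comps


def _pairwise_groups(
    meta: pd.DataFrame,
    log_int: pd.DataFrame,
    ids: list[str],
    rt_tol: float,
    corr_min: float,
    mode_rule: str,
    compat: pd.DataFrame | None,
) -> list[list[str]]:
    """Group features by |d rt| <= rt_tol AND correlation > corr_min.

    ``mode_rule="same"`` restricts edges to equal ionization mode (the
    within-mode collapse stage); ``"different"`` links only opposite-mode
    pairs (the cross-mode merge stage, which must not re-join same-mode
    groups that the first stage kept apart). ``compat`` is the optional
    MS/MS co-occurrence boolean matrix: when given, an edge additionally
    requires compatibility.
    """
    rt = meta["rt"]
    mode = meta["mode"]
    adjacency: dict[str, set[str]] = {f: set() for f in ids}
    X = log_int.loc[ids].to_numpy(dtype=float)
    row = {f: i for i, f in enumerate(ids)}
    # candidate pairs only within the retention-time window (sorted sweep)
    by_rt = sorted(ids, key=lambda f: (rt[f], f))
    for a, fi in enumerate(by_rt):
        for fj in by_rt[a + 1:]:
            if rt[fj] - rt[fi] > rt_tol:
                break
            if mode_rule == "same" and mode[fi] != mode[fj]:
                continue
            if mode_rule == "different" and mode[fi] == mode[fj]:
                continue
            if compat is not None and not bool(compat.loc[fi, fj]):
                continue
            xi, xj = X[row[fi]], X[row[fj]]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3:
                continue
            u, v = xi[ok], xj[ok]
            su, sv = u.std(), v.std()
            if su == 0 or sv == 0:
                continue
            r = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
            if r > corr_min:
                adjacency[fi].add(fj)
                adjacency[fj].add(fi)
    return _components(ids, adjacency)


def collapse_redundant(
    ww: FeatureTable,
    ds: FeatureTable,
    rt_tol: float = 0.2,
    corr_min: float = 0.95,
    compat: pd.DataFrame | None = None,
    corr_on_log: bool = True,
) -> tuple[MetaboliteMatrix, MetaboliteMatrix]:
    """Collapse redundant features into nonredundant metabolites.

    Two grouping passes build a pairwise compatibility graph whose connected
    components are the metabolites: first within each ionization mode
    (retention-time tolerance ``rt_tol`` minutes AND cross-line correlation
    > ``corr_min``, optionally additionally gated by an MS/MS co-occurrence
    matrix ``compat``), then group representatives from the positive and
    negative modes are merged by the same retention-time and correlation
    criteria. Correlation is computed across all lines of both conditions,
    on log intensities by default (``corr_on_log``).

    The representative intensity of a group is the member with fewest
    missing values over both conditions (ties broken by larger median
    intensity, then lexicographically smaller feature id).
    """
    if rt_tol < 0:
        raise ValueError("rt_tol must be nonnegative")
    if not -1 < corr_min < 1:
        raise ValueError("corr_min must lie in (-1, 1)")
    ids = ww.feature_ids
    stacked = pd.concat([ww.intensities, ds.intensities], axis=1)
    corr_basis = np.log(stacked) if corr_on_log else stacked

    # stage 1: within-mode components
    comps = _pairwise_groups(ww.meta, corr_basis, ids, rt_tol, corr_min,
                             mode_rule="same", compat=compat)

    # stage 2: merge across modes by criteria i + iii between representatives
    reps = {f"_g{k}": comp for k, comp in enumerate(comps)}
    rep_feature = {g: _representative(comp, stacked) for g, comp in reps.items()}
    rep_meta = ww.meta.loc[[rep_feature[g] for g in reps]].copy()
    rep_meta.index = list(reps)
    rep_int = corr_basis.loc[[rep_feature[g] for g in reps]].copy()
    rep_int.index = list(reps)
    merged = _pairwise_groups(rep_meta, rep_int, list(reps), rt_tol, corr_min,
                              mode_rule="different", compat=None)

    group_map: dict[str, list[str]] = {}
    rows_ww, rows_ds, met_ids = [], [], []
    for comp_of_groups in merged:
        members = sorted(m for g in comp_of_groups for m in reps[g])
        rep = _representative(members, stacked)
        met_id = rep
        met_ids.append(met_id)
        group_map[met_id] = members
        rows_ww.append(ww.intensities.loc[rep])
        rows_ds.append(ds.intensities.loc[rep])

    mm_ww = MetaboliteMatrix(values=pd.DataFrame(rows_ww, index=met_ids).T,
                             condition="WW", group_map=group_map)
    mm_ds = MetaboliteMatrix(values=pd.DataFrame(rows_ds, index=met_ids).T,
                             condition="DS", group_map=group_map)
    return mm_ww, mm_ds


def _representative(members: list[str], stacked: pd.DataFrame) -> str:
    """Fewest missing values; ties -> larger median; ties -> smaller id."""
    sub = stacked.loc[members]
    n_missing = sub.isna().sum(axis=1)
    med = sub.median(axis=1)
    order = sorted(members, key=lambda f: (n_missing[f], -med[f], f))
    return order[0]


def median_normalize(values: pd.DataFrame,
                     batch_labels: pd.Series | None = None) -> pd.DataFrame:
    """Equalize per-sample medians (optionally within batches first).

    With batches, each batch's samples are first scaled so the batch median
    matches the global median (day normalization); every sample is then
    scaled so its own median matches the global median. Idempotent.
    """
    vals = values.copy()
    global_med = np.nanmedian(vals.to_numpy(dtype=float))
    if batch_labels is not None:
        batch_labels = pd.Series(batch_labels, index=vals.index)
        for _, idx in vals.groupby(batch_labels).groups.items():
            bmed = np.nanmedian(vals.loc[idx].to_numpy(dtype=float))
            if bmed > 0:
                vals.loc[idx] = vals.loc[idx] * (global_med / bmed)
    sample_med = vals.median(axis=1, skipna=True)
    factors = global_med / sample_med
    return vals.mul(factors, axis=0)


def normalize_and_log(
    matrix: MetaboliteMatrix,
    batch_labels: pd.Series | None = None,
) -> MetaboliteMatrix:
    """Median normalization, half-minimum imputation, natural-log transform.

    Residual missing cells (those surviving the missingness filter) are
    imputed with half the per-metabolite minimum on the normalized raw
    scale — the conventional below-detection-limit treatment — before
    logging.
    """
    if matrix.log_transformed:
        raise ValueError("matrix is already log transformed")
    vals = matrix.values
    arr = vals.to_numpy(dtype=float)
    bad = np.argwhere(arr <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive intensity at line {vals.index[i]!r}, "
            f"metabolite {vals.columns[j]!r}")
    normed = median_normalize(vals, batch_labels)
    half_min = normed.min(axis=0, skipna=True) / 2.0
    normed = normed.fillna(half_min)
    logged = np.log(normed)
    return MetaboliteMatrix(values=logged, condition=matrix.condition,
                            group_map=dict(matrix.group_map),
                            log_transformed=True)


def process_feature_tables(
    ww: FeatureTable,
    ds: FeatureTable,
    max_missing: float = 0.2,
    rt_tol: float = 0.2,
    corr_min: float = 0.95,
    batch_labels: pd.Series | None = None,
    compat: pd.DataFrame | None = None,
) -> tuple[MetaboliteMatrix, MetaboliteMatrix]:
    """Full preprocessing: filter -> collapse -> normalize + log."""
    ww_f, ds_f = filter_missingness(ww, ds, max_missing=max_missing)
    if not ww_f.feature_ids:
        warnings.warn("no features survive the missingness filter")
    mm_ww, mm_ds = collapse_redundant(ww_f, ds_f, rt_tol=rt_tol,
                                      corr_min=corr_min, compat=compat)
    return (normalize_and_log(mm_ww, batch_labels),
            normalize_and_log(mm_ds, batch_labels))
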