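"""Gene-metabolite and gene-gene networks, permutation hub calling, enrichment.

Edges between a gene's expression and a metabolite's abundance come from
simple linear regression (two-sided slope t-test, df = n - 2) at
P <= 1e-5; gene-gene co-expression edges from the Pearson-correlation
t-transform at P <= 4.67e-9. Hub genes are called by comparing each gene's
metabolite degree with a permutation null in which edge gene-endpoints are
reassigned uniformly at random; pathway over-representation uses the
one-sided hypergeometric (Fisher) test with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MetaboliteMatrix


@dataclass
class BipartiteNetwork:
    """Gene-metabolite edge set for one growth condition."""

    edges: pd.DataFrame  # columns: gene_id, metabolite_id, beta, p
    genes: list[str]
    metabolites: list[str]
    condition: str
    threshold: float

    def degree(self) -> pd.Series:
        """Metabolite degree per gene in the network's gene universe."""
        counts = self.edges.groupby("gene_id")["metabolite_id"].nunique()
        return counts.reindex(self.genes, fill_value=0).astype(int)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    return Z, sd


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of Pearson r via t = r sqrt(n-2)/sqrt(1-r^2), df = n - 2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, np.nextafter(0, 1), p)


def gene_metabolite_edges(
    expression: ExpressionMatrix,
    metabolites: MetaboliteMatrix,
    threshold: float = 1e-5,
) -> BipartiteNetwork:
    """OLS edges: metabolite ~ gene expression, edge iff slope p <= threshold.

    The slope p-value is computed through the algebraically identical
    correlation t-transform, vectorized over all gene x metabolite pairs on
    the intersected line set. Constant genes or metabolites cannot form
    edges.
    """
    lines = [l for l in expression.line_ids if l in set(metabolites.line_ids)]
    if len(lines) < 4:
        raise ValueError(f"need >= 4 shared lines, got {len(lines)}")
    E = expression.values.loc[lines].to_numpy(dtype=float)
    M = metabolites.values.loc[lines].to_numpy(dtype=float)
    M = np.where(np.isnan(M), np.nanmean(M, axis=0, keepdims=True), M)
    n = len(lines)
    Ze, sd_e = _standardize(E)
    Zm, sd_m = _standardize(M)
    r = Ze.T @ Zm / (n - 1)
    p = _corr_pvalues(r, n)
    ok = (sd_e[:, None] > 0) & (sd_m[None, :] > 0)
    gi, mi = np.nonzero(ok & (p <= threshold))
    genes = list(expression.gene_ids)
    mets = list(metabolites.metabolite_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = r * (sd_m[None, :] / np.where(sd_e[:, None] > 0, sd_e[:, None], 1.0))
    edges = pd.DataFrame({
        "gene_id": [genes[i] for i in gi],
        "metabolite_id": [mets[j] for j in mi],
        "beta": beta[gi, mi], "p": p[gi, mi],
    }).drop_duplicates(["gene_id", "metabolite_id"])
    edges["condition"] = expression.condition
    return BipartiteNetwork(edges=edges, genes=genes, metabolites=mets,
                            condition=expression.condition, threshold=threshold)


def coexpression_edges(
    expression: ExpressionMatrix, threshold: float = 4.67e-9,
) -> pd.DataFrame:
    """Gene-gene Pearson edges (symmetric, no self-edges) at ``threshold``.

    Constant genes are excluded with a warning. Returns one row per
    unordered pair with r and p.
    """
    import warnings

    E = expression.values.to_numpy(dtype=float)
    genes = np.asarray(expression.gene_ids)
    sd = E.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"excluding {(sd == 0).sum()} constant gene(s)")
    keep = sd > 0
    E, genes = E[:, keep], genes[keep]
    n = E.shape[0]
    R = np.corrcoef(E, rowvar=False)
    P = _corr_pvalues(R, n)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = P[iu, ju] <= threshold
    return pd.DataFrame({
        "gene_a": genes[iu[mask]], "gene_b": genes[ju[mask]],
        "r": R[iu, ju][mask], "p": P[iu, ju][mask],
        "condition": expression.condition,
    })


# ---------------------------------------------------------------------------
# hub calling
# ---------------------------------------------------------------------------

@dataclass
class HubResult:
    """Permutation-derived degree threshold and per-gene hub calls."""

    threshold: int | None
    calls: pd.DataFrame  # gene_id, degree, is_hub
    condition: str
    n_perm: int
    alpha: float


def hub_threshold(
    network: BipartiteNetwork,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    mode: str = "edge",
    gene_universe: list[str] | None = None,
) -> int:
    """Degree threshold from the random-reassignment permutation null.

    Each permutation reassigns edge gene-endpoints uniformly at random over
    the gene universe (``mode="edge"``; metabolite endpoints and the edge
    count are preserved) or sends each metabolite's whole edge bundle to
    one random gene (``mode="metabolite"``). The per-gene degree counts of
    all permutations are pooled and the threshold is the smallest k with
    empirical P(degree >= k) < alpha.
    """
    if network.edges.empty:
        raise ValueError("network has no edges; hub threshold undefined")
    genes = gene_universe if gene_universe is not None else network.genes
    G = len(genes)
    rng = np.random.default_rng(seed)
    E = len(network.edges)
    # pooled histogram of per-gene degrees over all permutations
    max_deg = E
    hist = np.zeros(max_deg + 1, dtype=np.int64)
    if mode == "edge":
        for _ in range(n_perm):
            counts = np.bincount(rng.integers(0, G, size=E), minlength=G)
            hist += np.bincount(counts, minlength=max_deg + 1)[: max_deg + 1]
    elif mode == "metabolite":
        met_deg = (network.edges.groupby("metabolite_id")["gene_id"]
                   .nunique().to_numpy())
        for _ in range(n_perm):
            assign = rng.integers(0, G, size=len(met_deg))
            counts = np.bincount(assign, weights=met_deg, minlength=G)
            counts = counts.astype(int)
            hist += np.bincount(counts, minlength=max_deg + 1)[: max_deg + 1]
    else:
        raise ValueError("mode must be 'edge' or 'metabolite'")
    total = hist.sum()
    tail = np.cumsum(hist[::-1])[::-1] / total  # tail[k] = P(degree >= k)
    exceed = np.flatnonzero(tail < alpha)
    # fully degenerate null (e.g. a single gene): no tail ever drops below
    # alpha within the attainable range; collapse to the maximum degree
    return int(exceed[0]) if len(exceed) else int(max_deg)


def call_hubs(
    network: BipartiteNetwork,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    mode: str = "edge",
) -> HubResult:
    """Hub calls for one condition: degree >= permutation threshold."""
    degree = network.degree()
    if network.edges.empty:
        calls = pd.DataFrame({"gene_id": network.genes, "degree": 0,
                              "is_hub": False})
        return HubResult(threshold=None, calls=calls,
                         condition=network.condition, n_perm=n_perm,
                         alpha=alpha)
    thr = hub_threshold(network, n_perm=n_perm, alpha=alpha, seed=seed,
                        mode=mode)
    calls = pd.DataFrame({"gene_id": degree.index, "degree": degree.values,
                          "is_hub": degree.values >= thr})
    return HubResult(threshold=thr, calls=calls, condition=network.condition,
                     n_perm=n_perm, alpha=alpha)


# ---------------------------------------------------------------------------
# enrichment and ratio reporting
# ---------------------------------------------------------------------------

def fisher_enrichment(
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
    pathways: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    p = P(X >= overlap) drawing |gene_set| genes from a universe of which
    the pathway covers its in-universe members; BH adjustment across tested
    pathways. Pathways with no universe member are skipped.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"pathway": name, "overlap": k, "pathway_size": K,
                     "odds_ratio": odds, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size",
                                      "odds_ratio", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def summarize_ratios(
    counts: dict[str, tuple[int, int] | tuple[int, int, int]],
) -> dict[str, float]:
    """Percentages from labeled numerator/denominator pairs.

    Each value is ``(numerator, denominator)`` or
    ``(numerator, denominator, decimals)``; the percentage 100*num/den is
    rounded half-even to ``decimals`` places (default 1; use 0 for integer
    percent labels).
    """
    out: dict[str, float] = {}
    for label, pair in counts.items():
        num, den = pair[0], pair[1]
        decimals = pair[2] if len(pair) > 2 else 1
        if den == 0:
            raise ValueError(f"zero denominator for {label!r}")
        quant = Decimal(1).scaleb(-decimals)
        pct = (Decimal(100) * Decimal(num) / Decimal(den)).quantize(
            quant, rounding=ROUND_HALF_EVEN)
        out[label] = float(pct)
    return out
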