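"""Spatial statistics: neighbourhood permutation testing, nearest-type
distances, binned neighbourhood profiles, and domain composition.

The permutation test asks, for every ordered pair of cell types (A, B),
whether B is enriched or depleted in the direct neighbourhood of A.  The
observed statistic is the mean number of B-neighbours per A-cell on the
fixed neighbour graph; the null distribution shuffles cell-type labels over
cells (the graph never changes) ``n_perm`` times.  P-values use the add-one
estimator ``p = (1 + #extreme) / (1 + n_perm)`` so they are never zero, and
the effect size is ``log2((baseline + eps) / (perm_mean + eps))`` with a
pseudocount ``eps = 1 / n_cells``.  Stratifying by tissue domain restricts
cells and edges to each domain and permutes within the stratum only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "neighbourhood_permutation",
    "nearest_type_distance",
    "binned_neighbour_profile",
    "domain_composition",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


def _directed_edges(
    cell_ids: np.ndarray, relationships: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Relationship pairs -> directed edge index arrays (both directions)."""
    pos = pd.Series(np.arange(len(cell_ids)), index=cell_ids)
    a = relationships["cell_id_a"].to_numpy()
    b = relationships["cell_id_b"].to_numpy()
    missing = ~(pd.Index(a).isin(pos.index) & pd.Index(b).isin(pos.index))
    if missing.any():
        raise ValueError("relationship ids absent from the cell table")
    ia = pos[a].to_numpy()
    ib = pos[b].to_numpy()
    return np.concatenate([ia, ib]), np.concatenate([ib, ia])


def _pair_counts(
    type_codes: np.ndarray, ea: np.ndarray, eb: np.ndarray, n_types: int
) -> np.ndarray:
    """Directed edge counts per (type_a, type_b), shape (n_types, n_types)."""
    joint = type_codes[ea] * n_types + type_codes[eb]
    return np.bincount(joint, minlength=n_types * n_types).reshape(n_types, n_types)


def _one_stratum(
    types: np.ndarray,
    type_names: list[str],
    ea: np.ndarray,
    eb: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_cells = len(types)
    T = len(type_names)
    counts_per_type = np.bincount(types, minlength=T).astype(float)
    safe_n = np.where(counts_per_type > 0, counts_per_type, 1.0)

    observed = _pair_counts(types, ea, eb, T) / safe_n[:, None]

    # vectorised permutations: one bincount over (perm, type_a, type_b)
    perm_sum = np.zeros((T, T), dtype=np.float64)
    ge = np.zeros((T, T), dtype=np.int64)
    le = np.zeros((T, T), dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e7 // max(len(ea), 1)) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.empty((m, n_cells), dtype=np.int64)
        for i in range(m):
            perms[i] = types[rng.permutation(n_cells)]
        joint = perms[:, ea] * T + perms[:, eb]
        offset = (np.arange(m) * (T * T))[:, None]
        flat = np.bincount((joint + offset).ravel(), minlength=m * T * T)
        mats = flat.reshape(m, T, T) / safe_n[None, :, None]
        perm_sum += mats.sum(axis=0)
        ge += (mats >= observed[None]).sum(axis=0)
        le += (mats <= observed[None]).sum(axis=0)
        done += m
    perm_mean = perm_sum / n_perm
    p_enr = (1.0 + ge) / (1.0 + n_perm)
    p_dep = (1.0 + le) / (1.0 + n_perm)
    eps = 1.0 / n_cells
    log2fc = np.log2((observed + eps) / (perm_mean + eps))

    rows = []
    for ai, a in enumerate(type_names):
        for bi, b in enumerate(type_names):
            if counts_per_type[ai] == 0 or counts_per_type[bi] == 0:
                rows.append((a, b, 0.0, 0.0, 1.0, 1.0, 0.0))
            else:
                rows.append(
                    (
                        a, b,
                        observed[ai, bi], perm_mean[ai, bi],
                        p_enr[ai, bi], p_dep[ai, bi], log2fc[ai, bi],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "type_a", "type_b", "baseline", "perm_mean",
            "p_enriched", "p_depleted", "log2fc",
        ],
    )


def neighbourhood_permutation(
    cell_table: pd.DataFrame,
    relationships: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    stratify_by_domain: bool = False,
    type_column: str = "cell_type",
    type_names: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation test of neighbourhood enrichment per ordered type pair.

    Returns a tidy frame with one row per (stratum,) type_a, type_b:
    ``baseline`` (mean B-neighbours per A-cell), ``perm_mean``,
    ``p_enriched``, ``p_depleted``, ``log2fc`` and ``n_perm``.  Types with
    zero cells in a stratum yield baseline 0 and p = 1.
    """
    if type_column not in cell_table.columns:
        raise KeyError(f"cell table has no {type_column!r} column")
    rng = np.random.default_rng(seed)
    names = (
        list(type_names)
        if type_names is not None
        else sorted(map(str, pd.unique(cell_table[type_column].astype(str))))
    )
    code = {t: i for i, t in enumerate(names)}

    def encode(sub: pd.DataFrame) -> np.ndarray:
        return sub[type_column].astype(str).map(code).to_numpy(dtype=np.int64)

    results = []
    if stratify_by_domain:
        if "domain" not in cell_table.columns:
            raise KeyError("stratify_by_domain requires a 'domain' column")
        for dom in sorted(map(str, pd.unique(cell_table["domain"].astype(str)))):
            sub = cell_table[cell_table["domain"].astype(str) == dom]
            ids = set(sub["cell_id"])
            rel = relationships[
                relationships["cell_id_a"].isin(ids)
                & relationships["cell_id_b"].isin(ids)
            ]
            ea, eb = _directed_edges(sub["cell_id"].to_numpy(), rel)
            df = _one_stratum(encode(sub), names, ea, eb, n_perm, rng)
            df.insert(0, "stratum", dom)
            results.append(df)
    else:
        ea, eb = _directed_edges(cell_table["cell_id"].to_numpy(), relationships)
        df = _one_stratum(encode(cell_table), names, ea, eb, n_perm, rng)
        df.insert(0, "stratum", "all")
        results.append(df)
    out = pd.concat(results, ignore_index=True)
    out["n_perm"] = n_perm
    return out


def nearest_type_distance(
    cell_table: pd.DataFrame,
    target_type: str,
    type_column: str = "cell_type",
) -> np.ndarray:
    """Euclidean centroid distance from every cell to the nearest target cell.

    Computed per ROI; a target-type cell excludes itself, and an ROI without
    target cells yields NaN for its cells.
    """
    out = np.full(len(cell_table), np.nan)
    roi = (
        cell_table["roi_id"]
        if "roi_id" in cell_table.columns
        else pd.Series(["roi"] * len(cell_table), index=cell_table.index)
    )
    pos = cell_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    is_target = (cell_table[type_column] == target_type).to_numpy()
    for _, idx in cell_table.groupby(roi, sort=False).indices.items():
        tgt = idx[is_target[idx]]
        if tgt.size == 0:
            continue
        tree = cKDTree(pos[tgt])
        k = 2 if tgt.size > 1 else 1
        d, nn = tree.query(pos[idx], k=k)
        d = np.atleast_2d(d.T).T if d.ndim == 1 else d
        first = d[:, 0].copy()
        own = is_target[idx]
        if tgt.size > 1:
            # for target cells the nearest hit is themselves (distance 0)
            first[own] = d[own, 1]
        else:
            first[own] = np.nan
        out[idx] = first
    return out


def binned_neighbour_profile(
    cell_table: pd.DataFrame,
    reference_type: str,
    bin_edges=DEFAULT_BIN_EDGES,
    type_column: str = "cell_type",
    stratify: list[str] | None = None,
) -> pd.DataFrame:
    """Composition of the neighbourhood of a reference type by distance bin.

    For each stratum (e.g. domain x treatment), each cell's distance to the
    nearest reference-type cell is placed in half-open bins ``[lo, hi)`` and
    the count of each cell type per bin is recorded; bin columns are then
    scaled to sum to one (all-zero columns stay zero).  Reference cells do
    not count themselves at distance zero (self is excluded by
    :func:`nearest_type_distance`); cells beyond the last edge are dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    work = cell_table.copy()
    work["_dist"] = nearest_type_distance(cell_table, reference_type, type_column)

    strat_cols = stratify or []
    groups = work.groupby(strat_cols, sort=True) if strat_cols else [((), work)]
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
    all_types = sorted(map(str, pd.unique(cell_table[type_column].astype(str))))
    type_index = {t: i for i, t in enumerate(all_types)}
    frames = []
    for key, sub in groups:
        ok = sub["_dist"].notna() & (sub["_dist"] >= edges[0]) & (sub["_dist"] < edges[-1])
        sub = sub[ok]
        mat = np.zeros((len(all_types), len(labels)))
        if len(sub):
            t_idx = sub[type_column].astype(str).map(type_index).to_numpy(dtype=int)
            b_idx = np.digitize(sub["_dist"].to_numpy(dtype=float), edges) - 1
            np.add.at(mat, (t_idx, b_idx), 1.0)
        sums = mat.sum(axis=0)
        mat = mat / np.where(sums > 0, sums, 1.0)[None, :]
        scaled = pd.DataFrame(mat, columns=labels)
        scaled.insert(0, "cell_type", all_types)
        if strat_cols:
            key = key if isinstance(key, tuple) else (key,)
            for col, val in zip(strat_cols, key):
                scaled.insert(0, col, val)
        frames.append(scaled)
    return pd.concat(frames, ignore_index=True)


def domain_composition(
    cell_table: pd.DataFrame,
    groupby: str | None = "treatment",
    type_column: str = "cell_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two tidy proportion summaries with per-ROI means and SEM.

    Returns ``(types_across_domains, domains_across_types)``:

    * per cell type, its distribution across tissue domains;
    * per domain, its composition across cell types;

    each computed per ROI and then averaged within the ``groupby`` level
    (mean and standard error of the mean over ROIs).
    """
    for col in (type_column, "domain", "roi_id"):
        if col not in cell_table.columns:
            raise KeyError(f"cell table has no {col!r} column")
    group_cols = [groupby] if groupby and groupby in cell_table.columns else []

    def summarise(outer: str, inner: str) -> pd.DataFrame:
        counts = (
            cell_table.groupby(group_cols + ["roi_id", outer, inner], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        totals = (
            counts.groupby(group_cols + ["roi_id", outer], observed=True)["n"]
            .sum()
            .rename("total")
            .reset_index()
        )
        merged = counts.merge(totals, on=group_cols + ["roi_id", outer])
        merged["proportion"] = merged["n"] / merged["total"]
        agg = (
            merged.groupby(group_cols + [outer, inner], observed=True)["proportion"]
            .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                 n_roi="count")
            .reset_index()
        )
        return agg

    return summarise(type_column, "domain"), summarise("domain", type_column)
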