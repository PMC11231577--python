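"""Rank-based motif enrichment over differential-accessibility results.

Regions are ranked by the signed significance of their accessibility change
(most treatment-increased first). For each motif, the enrichment score E
measures whether regions carrying the motif concentrate at one end of the
ranking:

    E = 1 - 2 * mean_h((r_h - 0.5) / N)

with N regions and hit ranks r_1..r_H (1-based). E is a rescaled
Mann-Whitney statistic in (-1, 1): positive E means motif-bearing regions
are concentrated among regions that gained accessibility in treatment; the
score is exactly antisymmetric under ranking reversal. Significance comes
from a permutation null (hit labels shuffled over ranks), with BH adjustment
across motifs within each annotation stratum (all / promoter / nongenic).
A quartile "barcode" (hit counts in four contiguous rank blocks) summarizes
where in the ranking the hits fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .diffacc import bh_adjust

__all__ = [
    "rank_regions",
    "e_score",
    "permutation_p",
    "barcode",
    "run_enrichment",
]

STRATA = ("all", "promoter", "nongenic")


def rank_regions(
    diff: pd.DataFrame,
    labels: pd.Series | None = None,
    stratum: str = "all",
) -> pd.Index:
    """Order regions by signed_rank_stat descending, ties broken by region_id.

    ``diff`` is an nb_wald_test result (index region_id, column
    signed_rank_stat). For stratum "promoter"/"nongenic" the regions are
    first filtered by ``labels``.
    """
    d = diff
    if stratum != "all":
        if labels is None:
            raise ValueError("labels required for stratum filtering")
        keep = labels[labels == stratum].index
        d = d.loc[d.index.intersection(keep)]
    if len(d) == 0:
        raise ValueError(f"stratum {stratum!r} contains no regions")
    # mergesort is stable; pre-sorting by id gives a deterministic tie rule
    order = (
        d.assign(_id=d.index)
        .sort_values("_id", kind="mergesort")
        .sort_values("signed_rank_stat", ascending=False, kind="mergesort")
    )
    return order.index


def e_score(ranked: pd.Index | np.ndarray, hits: pd.Series) -> tuple[float, bool]:
    """Enrichment score for one motif; returns (E, informative).

    ``hits`` is a boolean Series over region_ids. An all-hit or no-hit motif
    is uninformative: E = 0 with informative=False.
    """
    h = hits.reindex(ranked).to_numpy(dtype=bool)
    N = h.size
    H = int(h.sum())
    if H == 0 or H == N:
        return 0.0, False
    ranks = np.nonzero(h)[0] + 1  # 1-based
    return float(1.0 - 2.0 * np.mean((ranks - 0.5) / N)), True


def _e_from_ranks(ranks: np.ndarray, N: int) -> np.ndarray:
    return 1.0 - 2.0 * np.mean((ranks - 0.5) / N, axis=-1)


def permutation_p(
    ranked: pd.Index | np.ndarray,
    hits: pd.Series,
    n_permutations: int,
    seed: int | np.random.Generator,
) -> tuple[float, float]:
    """Two-sided permutation p-value for the E-score, plus an analytic check.

    Hit labels are permuted over ranks: each permutation draws H ranks
    uniformly without replacement.  p = (1 + #{\\|E_perm\\| >= \\|E_obs\\|}) /
    (n_permutations + 1). When all C(N, H) label placements number at most
    min(n_permutations, 10^4) the null is enumerated exhaustively instead and
    p is the exact tail fraction. The second return value is the
    normal-approximation p from the rank-sum null, Var(E) ~= (N - H)/(3*N*H).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    e_obs, informative = e_score(ranked, hits)
    N = len(ranked)
    H = int(hits.reindex(ranked).sum())
    if not informative:
        return float("nan"), float("nan")
    from math import comb
    from itertools import combinations

    n_exact = comb(N, H)
    if n_exact <= min(n_permutations, 10**4):
        all_ranks = np.array(
            list(combinations(range(1, N + 1), H)), dtype=float
        )
        e_all = _e_from_ranks(all_ranks, N)
        p_perm = np.mean(np.abs(e_all) >= abs(e_obs) - 1e-12)
    else:
        # argpartition of iid uniforms -> uniform random H-subset of 0..N-1
        u = rng.random((n_permutations, N))
        idx = np.argpartition(u, H - 1, axis=1)[:, :H]
        e_perm = _e_from_ranks(idx + 1.0, N)
        p_perm = (1.0 + np.sum(np.abs(e_perm) >= abs(e_obs) - 1e-12)) / (
            n_permutations + 1.0
        )
    var_e = (N - H) / (3.0 * N * H)
    p_norm = 2.0 * stats.norm.sf(abs(e_obs) / np.sqrt(var_e))
    return float(p_perm), float(p_norm)


def barcode(ranked: pd.Index | np.ndarray, hits: pd.Series) -> tuple[int, int, int, int]:
    """Hit counts per rank quartile (Q1 = most treatment-increased end).

    Ranks are split into 4 contiguous blocks with sizes differing by at most
    one; earlier quartiles receive the extra positions.
    """
    h = hits.reindex(ranked).to_numpy(dtype=bool)
    N = h.size
    if N < 4:
        raise ValueError("need at least 4 regions for a quartile barcode")
    base, extra = divmod(N, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    bounds = np.cumsum([0] + sizes)
    return tuple(int(h[bounds[q] : bounds[q + 1]].sum()) for q in range(4))


def run_enrichment(
    diff: pd.DataFrame,
    labels: pd.Series,
    hit_table: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    strata: tuple[str, ...] = STRATA,
) -> pd.DataFrame:
    """E-score, permutation p, and BH padj for every motif in every stratum.

    ``hit_table`` is the boolean regions x motifs indicator from
    ``motifs.scan_regions`` over the same regions as ``diff``. Motifs that
    hit all or no regions in a stratum are flagged uninformative (E = 0,
    p = NaN) and excluded from the BH family. Returns one row per
    motif x stratum with columns stratum, motif_id, n_hit_regions, e_score,
    p_value, p_normal, padj, q1..q4, informative.
    """
    cfg = cfg or AnalysisConfig()
    missing = diff.index.difference(hit_table.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} tested regions missing from hit_table"
        )
    rows = []
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 0x7FEA])
    )
    for stratum in strata:
        ranked = rank_regions(diff, labels, stratum)
        for motif_id in hit_table.columns:
            hits = hit_table[motif_id]
            e, informative = e_score(ranked, hits)
            if informative:
                p_perm, p_norm = permutation_p(
                    ranked, hits, cfg.n_permutations, rng
                )
                q = barcode(ranked, hits)
            else:
                p_perm = p_norm = float("nan")
                q = barcode(ranked, hits) if len(ranked) >= 4 else (0, 0, 0, 0)
            rows.append(
                {
                    "stratum": stratum,
                    "motif_id": motif_id,
                    "n_hit_regions": int(hits.reindex(ranked).sum()),
                    "e_score": e,
                    "p_value": p_perm,
                    "p_normal": p_norm,
                    "q1": q[0],
                    "q2": q[1],
                    "q3": q[2],
                    "q4": q[3],
                    "informative": informative,
                }
            )
    res = pd.DataFrame(rows)
    res["padj"] = np.nan
    for stratum in strata:
        mask = res["stratum"] == stratum
        res.loc[mask, "padj"] = bh_adjust(res.loc[mask, "p_value"].to_numpy())
    return res.sort_values(["stratum", "padj"], kind="mergesort").reset_index(
        drop=True
    )
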