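"""Weighted Kolmogorov-Smirnov gene-set enrichment on a ranked list.

The running sum increments by |stat|^exponent (normalized over the set's
hits) at each hit and decrements by 1/(N - N_hit) at each miss; the
enrichment score (ES) is the signed maximal deviation and the leading edge
the hits at or before it (positive ES) or at or after the minimum (negative
ES).  The null distribution comes from size-matched random gene sets drawn
without replacement (gene permutation); p-values are one-sided tail
frequencies on the matching sign with a +1 pseudocount, and NES divides ES
by the mean |null ES| of the same sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffabund import DEResult, adjust_bh
from .io import GeneSetCollection


@dataclass
class RankedList:
    """Genes ordered by a descending ranking statistic."""

    genes: np.ndarray
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("ranked list is empty")
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list has duplicate gene ids")
        if np.any(np.diff(self.stats) > 0):
            raise ValueError("statistics must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedList":
        return RankedList(self.genes[::-1].copy(), -self.stats[::-1])


@dataclass
class GseaResult:
    """Per-set enrichment table plus gene lists for downstream networks."""

    table: pd.DataFrame                 # size, ES, NES, pval, padj
    leading_edges: dict[str, list[str]]
    members: dict[str, list[str]]       # set members intersected with the universe


def rank_features(de: DEResult | pd.Series, by: str = "t") -> RankedList:
    """Rank genes descending by a statistic (moderated t, PC loadings, ...).

    Ties are broken by ascending gene id so the order is reproducible.
    """
    if isinstance(de, DEResult):
        series = de.table[by]
    else:
        series = de
    series = series.dropna()
    if len(series) == 0:
        raise ValueError("no finite statistics to rank")
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    df = pd.DataFrame({"stat": series, "gene": series.index.astype(str)})
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(df["gene"].to_numpy(), df["stat"].to_numpy())


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(weights: np.ndarray, positions: np.ndarray, n: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ES for B sets given sorted 0-based hit positions.

    ``weights`` (B x k) are |stat|^exponent at the hit positions, in position
    order.  Returns (es, argext_kind, argext_index): the signed maximal
    deviation, whether the extremum is the positive max (1) or negative min
    (0), and the hit ordinal attaining it.
    """
    B, k = positions.shape
    d = 1.0 / (n - k)
    wsum = weights.sum(axis=1, keepdims=True)
    if np.any(wsum == 0):
        # all hit statistics zero: fall back to unweighted increments
        unw = np.where(wsum == 0, 1.0, 0.0)
        weights = weights + unw / k
        wsum = weights.sum(axis=1, keepdims=True)
    W = np.cumsum(weights / wsum, axis=1)            # cumulative hit mass after hit i
    i = np.arange(1, k + 1)[None, :]
    misses_through = positions + 1 - i               # misses up to & incl. position p_i
    at_hit = W - d * misses_through                  # running sum right after hit i
    before_hit = np.concatenate([np.zeros((B, 1)), W[:, :-1]], axis=1) - d * (positions - (i - 1))
    pos_max = at_hit.max(axis=1)
    pos_arg = at_hit.argmax(axis=1)
    neg_min = np.minimum(before_hit.min(axis=1), 0.0)
    neg_arg = before_hit.argmin(axis=1)
    take_pos = pos_max >= -neg_min
    es = np.where(take_pos, pos_max, neg_min)
    arg = np.where(take_pos, pos_arg, neg_arg)
    return es, take_pos, arg


def enrichment_score(ranked: RankedList, gene_set, exponent: float = 1.0
                     ) -> tuple[float, list[str]]:
    """ES and leading edge of one gene set against a ranked list."""
    universe = {g: i for i, g in enumerate(ranked.genes)}
    hits = sorted({universe[g] for g in gene_set if g in universe})
    n = len(ranked)
    if not hits:
        raise ValueError("gene set does not intersect the ranked universe")
    if len(hits) == n:
        raise ValueError("gene set equals the ranked universe")
    positions = np.asarray(hits, dtype=int)[None, :]
    weights = np.abs(ranked.stats[positions]) ** exponent
    es, take_pos, arg = _es_from_positions(weights, positions, n)
    es, take_pos, arg = float(es[0]), bool(take_pos[0]), int(arg[0])
    if take_pos:
        leading = [str(ranked.genes[h]) for h in hits[: arg + 1]]
    else:
        leading = [str(ranked.genes[h]) for h in hits[arg:]]
    return es, leading


def _shuffle_ties(ranked: RankedList, rng: np.random.Generator) -> RankedList:
    """Randomize order within equal-statistic blocks (ES tie-break de-bias)."""
    stats_ = ranked.stats
    genes = ranked.genes.copy()
    start = 0
    for end in range(1, len(stats_) + 1):
        if end == len(stats_) or stats_[end] != stats_[start]:
            if end - start > 1:
                genes[start:end] = rng.permutation(genes[start:end])
            start = end
    return RankedList(genes, stats_)


def gsea(ranked: RankedList, sets: GeneSetCollection, n_perm: int = 10000,
         min_size: int = 20, max_size: int | None = None, exponent: float = 1.0,
         seed: int = 0) -> GseaResult:
    """Permutation GSEA over a collection of gene sets.

    Sets are intersected with the ranked universe and filtered to
    ``min_size <= size <= max_size``.  Every set gets its own permutation
    null (so p-values are independent across sets); sets whose null has no
    same-sign draws get an undefined NES and are flagged in the table.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ranked = _shuffle_ties(ranked, rng)
    n = len(ranked)
    universe = {g: i for i, g in enumerate(ranked.genes)}
    filtered = sets.filtered(universe, min_size=max(1, min_size),
                             max_size=max_size if max_size is not None else n - 1)
    abs_stats = np.abs(ranked.stats) ** exponent

    chunk = max(1, int(2e7 // n))  # bound the permutation workspace

    def null_es(k: int) -> np.ndarray:
        out = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            u = rng.random((b, n))
            pos = np.sort(np.argpartition(u, k, axis=1)[:, :k], axis=1)
            es, _, _ = _es_from_positions(abs_stats[pos], pos, n)
            out[done:done + b] = es
            done += b
        return out

    rows = []
    leading_edges: dict[str, list[str]] = {}
    members: dict[str, list[str]] = {}
    for sid, genes in sorted(filtered.sets.items()):
        inter = sorted({universe[g] for g in genes if g in universe})
        k = len(inter)
        if k >= n:
            continue
        es, leading = enrichment_score(ranked, genes, exponent)
        null = null_es(k)
        same_sign = null >= 0 if es >= 0 else null < 0
        m = int(same_sign.sum())
        if es >= 0:
            b = int((null[same_sign] >= es).sum())
        else:
            b = int((null[same_sign] <= es).sum())
        pval = (b + 1.0) / (m + 1.0)
        if m > 0:
            nes = es / float(np.abs(null[same_sign]).mean())
            flagged = False
        else:
            nes = np.nan
            flagged = True
        rows.append({"set_id": sid, "size": k, "ES": es, "NES": nes,
                     "pval": pval, "nes_undefined": flagged})
        leading_edges[sid] = leading
        members[sid] = [str(ranked.genes[i]) for i in inter]
    if not rows:
        raise ValueError("no gene set survives size filtering")
    table = pd.DataFrame(rows).set_index("set_id")
    table["padj"] = adjust_bh(table["pval"].to_numpy())
    return GseaResult(table, leading_edges, members)


def write_gsea_table(result: GseaResult, path) -> None:
    out = result.table.copy()
    out["leading_edge"] = [",".join(result.leading_edges[s]) for s in out.index]
    out.to_csv(path, sep="\t")
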