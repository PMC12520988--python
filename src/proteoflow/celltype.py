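"""Cell-type marker derivation and composition inference for bulk proteomes.

A single-cell-derived reference (mean expression and fraction-expressed per
cell type) yields per-gene z-scores across cell types; genes whose z
exceeds a threshold (2 for ventricular nuclei, 2.5 for sinoatrial-node
nuclei, i.e. the 97.72th / 99.38th standard-normal percentiles) and that
are expressed in at least 25% of cells of that type become markers.  Marker
sets feed the permutation GSEA engine to read cell-type composition shifts
off a ranked bulk contrast, and each protein can be assigned its primary
expressing cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsea import GseaResult, RankedList, gsea
from .io import GeneSetCollection, harmonize_ids

UNASSIGNED = "unassigned"


@dataclass
class CellReference:
    """Genes x cell types: mean log-normalized expression and fraction of
    cells expressing each gene (> 0)."""

    mean: pd.DataFrame
    fraction: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.fraction.index) or \
           not self.mean.columns.equals(self.fraction.columns):
            raise ValueError("mean and fraction matrices must share both axes")
        if self.mean.index.duplicated().any():
            raise ValueError("duplicate gene ids in reference")
        frac = self.fraction.to_numpy()
        if np.nanmin(frac) < 0 or np.nanmax(frac) > 1:
            raise ValueError("fraction-expressed must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean.columns)

    def restricted(self, universe) -> "CellReference":
        """Keep genes measured in the bulk universe (exact uppercased match)."""
        uni = set(harmonize_ids(universe))
        keep = harmonize_ids(self.mean.index).isin(uni)
        return CellReference(self.mean.loc[keep], self.fraction.loc[keep])


@dataclass
class MarkerSets:
    """Cell type -> [(gene, z-score)] plus the thresholds used."""

    sets: dict[str, list[tuple[str, float]]]
    z_threshold: float
    min_fraction: float
    multi_markers: set[str] = field(default_factory=set)

    def genes(self, cell_type: str) -> list[str]:
        return [g for g, _ in self.sets.get(cell_type, [])]

    def as_collection(self, min_size: int = 1) -> GeneSetCollection:
        sets = {t: [g for g, _ in gs] for t, gs in self.sets.items() if len(gs) >= min_size}
        if not sets:
            raise ValueError("no marker set reaches min_size")
        return GeneSetCollection(sets, {t: f"markers z>{self.z_threshold}" for t in sets})


def zscore_across_types(ref: CellReference, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z of mean expression across cell types (each type is one
    observation; SD uses the n-1 denominator by default).  Genes with zero
    spread get z = 0 everywhere."""
    if ref.mean.shape[1] < 2:
        raise ValueError("z-scores need >=2 cell types")
    x = ref.mean.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, index=ref.mean.index, columns=ref.mean.columns)


def derive_markers(ref: CellReference, universe=None, z_threshold: float = 2.0,
                   min_fraction: float = 0.25, ddof: int = 1) -> MarkerSets:
    """Marker sets per cell type from z-scores and the fraction filter.

    The reference is first restricted to the measured universe (when given);
    a gene marks every type where z > z_threshold and fraction-expressed >=
    min_fraction, and genes marking several types are flagged.
    """
    if universe is not None:
        ref = ref.restricted(universe)
    z = zscore_across_types(ref, ddof=ddof)
    passing = (z > z_threshold) & (ref.fraction >= min_fraction)
    sets: dict[str, list[tuple[str, float]]] = {t: [] for t in ref.cell_types}
    n_pass = passing.sum(axis=1)
    multi = set(ref.mean.index[n_pass > 1].astype(str))
    for t in ref.cell_types:
        hits = passing.index[passing[t]]
        ranked = sorted(((str(g), float(z.loc[g, t])) for g in hits),
                        key=lambda gz: -gz[1])
        sets[t] = ranked
    return MarkerSets(sets, z_threshold, min_fraction, multi)


def celltype_enrichment(ranked: RankedList, markers: MarkerSets, n_perm: int = 10000,
                        min_size: int = 3, seed: int = 0) -> GseaResult:
    """Permutation GSEA of the marker sets against a ranked bulk contrast."""
    return gsea(ranked, markers.as_collection(), n_perm=n_perm,
                min_size=min_size, max_size=None, seed=seed)


def assign_primary_celltype(protein_ids, ref: CellReference,
                            min_fraction: float = 0.25, ddof: int = 1) -> pd.Series:
    """Primary expressing cell type per protein.

    Among cell types where the gene is expressed in >= min_fraction of
    cells, the type with the highest z wins; ties go to the higher
    fraction-expressed, then alphabetical order.  Proteins absent from the
    reference, or failing the fraction filter in every type, are
    ``unassigned``.
    """
    ids = pd.Index([str(p) for p in protein_ids])
    upper_map = {}
    for g in ref.mean.index:
        upper_map.setdefault(str(g).upper(), g)
    z = zscore_across_types(ref, ddof=ddof)
    out = {}
    for pid in ids:
        gene = upper_map.get(pid.upper())
        if gene is None:
            out[pid] = UNASSIGNED
            continue
        fr = ref.fraction.loc[gene]
        candidates = [t for t in ref.cell_types if fr[t] >= min_fraction]
        if not candidates:
            out[pid] = UNASSIGNED
            continue
        zrow = z.loc[gene]
        best = sorted(candidates, key=lambda t: (-zrow[t], -fr[t], t))[0]
        out[pid] = best
    return pd.Series(out, name="primary_celltype").reindex(ids)
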