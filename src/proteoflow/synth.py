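"""Synthetic protein-intensity datasets with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes for bottom-up proteomes of preserved tissue: log-normally
distributed protein means with a wide dynamic range, additive random
effects on the log2 scale for individual, processing workflow, fixation and
batch, planted group fold changes, and intensity-dependent (left-censored,
MNAR) missingness.  It also builds single-cell-style expression references
with planted cell-type markers and multinomial stereology grid counts.

Everything is driven by one :class:`numpy.random.Generator`; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import IntensityMatrix, SampleMetadata

RANDOM_FACTORS = ("group_re", "individual", "workflow", "fixation", "batch")


class InvalidDesignError(ValueError):
    """The simulation design violates its invariants."""


@dataclass
class SimDesign:
    """Sample layout of a simulated experiment.

    ``samples`` must contain columns ``sample_id``, ``group``,
    ``individual``, ``workflow``, ``fixation``, ``batch`` and the covariates
    ``age`` and ``sex``.  Helpers :func:`two_group_design` and
    :func:`paired_workflow_design` build the two layouts used throughout:
    a case/control cohort and a paired preservation/workflow comparison.
    """

    n_proteins: int
    samples: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise InvalidDesignError("n_proteins must be >= 1")
        if len(self.samples) == 0:
            raise InvalidDesignError("design has zero samples")
        required = {"sample_id", "group", "individual", "workflow", "fixation", "batch"}
        missing = required - set(self.samples.columns)
        if missing:
            raise InvalidDesignError(f"design lacks columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise InvalidDesignError("duplicate sample_ids in design")

    def metadata(self) -> SampleMetadata:
        return SampleMetadata(self.samples.set_index("sample_id").copy())


@dataclass
class SimEffects:
    """Effect sizes and noise structure of the simulation.

    Variance components are on the log2^2 scale.  Defaults mirror a
    paired-preservation benchmark in which the processing workflow is the
    dominant source of variance, individual differences are intermediate and
    fixation is negligible.  ``missing_model`` is ``(slope, midpoint)`` of a
    logistic left-censoring rule: P(missing | y) = expit(-slope * (y -
    midpoint)), non-increasing in intensity for slope >= 0.
    """

    base_mean_log2: float = 20.0
    base_sd_log2: float = 2.5
    var_group: float = 0.0
    var_individual: float = 0.11
    var_workflow: float = 0.29
    var_fixation: float = 0.01
    var_batch: float = 0.0
    var_residual: float = 0.59
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    missing_model: tuple[float, float] | None = None  # (slope, midpoint); None = no missingness

    def __post_init__(self) -> None:
        for name in ("var_group", "var_individual", "var_workflow", "var_fixation",
                     "var_batch", "var_residual"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise InvalidDesignError("de_fraction must lie in [0, 1]")
        if self.missing_model is not None and self.missing_model[0] < 0:
            raise InvalidDesignError("missing_model slope must be >= 0 (left-censoring)")

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "group_re": self.var_group,
            "individual": self.var_individual,
            "workflow": self.var_workflow,
            "fixation": self.var_fixation,
            "batch": self.var_batch,
            "residual": self.var_residual,
        }


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``per_protein`` carries the planted log2 fold change and the true
    variance fractions for every protein; ``markers`` maps planted marker
    genes to their cell type (cell-reference simulations only).
    """

    per_protein: pd.DataFrame
    markers: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        self.per_protein.to_csv(path, sep="\t", index_label="protein_id")


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def two_group_design(n_proteins: int, n_per_group: int = 10,
                     groups: tuple[str, str] = ("case", "control"),
                     seed: int = 0) -> SimDesign:
    """Case/control cohort: one individual per sample, single workflow/batch."""
    rows = []
    rng = np.random.default_rng(seed)
    for g in groups:
        for i in range(n_per_group):
            rows.append({
                "sample_id": f"{g}_{i + 1:02d}",
                "group": g,
                "individual": f"ind_{g}_{i + 1:02d}",
                "workflow": "standard",
                "fixation": "ffpe",
                "batch": "b1",
                "age": int(rng.integers(35, 75)),
                "sex": str(rng.choice(["F", "M"])),
            })
    return SimDesign(n_proteins, pd.DataFrame(rows), seed)


def paired_workflow_design(n_proteins: int, n_individuals: int = 5,
                           workflows: tuple[str, ...] = ("optimized", "optimized", "reference"),
                           fixations: tuple[str, ...] = ("ffpe", "ff", "ff"),
                           seed: int = 0) -> SimDesign:
    """Paired preservation benchmark: every individual measured under every
    (workflow, fixation) condition."""
    if len(workflows) != len(fixations):
        raise InvalidDesignError("workflows and fixations must align")
    rng = np.random.default_rng(seed)
    ages = rng.integers(40, 80, size=n_individuals)
    sexes = rng.choice(["F", "M"], size=n_individuals)
    rows = []
    for i in range(n_individuals):
        for k, (wf, fx) in enumerate(zip(workflows, fixations)):
            rows.append({
                "sample_id": f"ind{i + 1}_{wf}_{fx}_{k + 1}",
                "group": "benchmark",
                "individual": f"ind_{i + 1}",
                "workflow": wf,
                "fixation": fx,
                "batch": "b1",
                "age": int(ages[i]),
                "sex": str(sexes[i]),
            })
    return SimDesign(n_proteins, pd.DataFrame(rows), seed)


def replicate_design(n_proteins: int, n_individuals: int, n_replicates: int,
                     seed: int = 0) -> SimDesign:
    """n_individuals blocks with n_replicates technical replicates each."""
    rows = []
    for i in range(n_individuals):
        for r in range(n_replicates):
            rows.append({
                "sample_id": f"ind{i + 1}_rep{r + 1}",
                "group": "all",
                "individual": f"ind_{i + 1}",
                "workflow": "standard",
                "fixation": "ffpe",
                "batch": "b1",
                "age": 60,
                "sex": "F",
            })
    return SimDesign(n_proteins, pd.DataFrame(rows), seed)


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

def simulate_intensity_dataset(design: SimDesign, effects: SimEffects
                               ) -> tuple[IntensityMatrix, SimTruth]:
    """Draw a proteins x samples log2 intensity matrix from the additive model

        y_ps = mu_p + lfc_p * 1[group != reference] + u_individual + u_workflow
               + u_fixation + u_batch + u_group + eps

    where every u is a protein-specific level effect with the corresponding
    variance component and eps has variance ``var_residual``.  Missing cells
    arise only through the logistic left-censoring rule of
    ``effects.missing_model``.
    """
    rng = np.random.default_rng(design.seed)
    P = design.n_proteins
    samples = design.samples
    S = len(samples)

    mu = rng.normal(effects.base_mean_log2, effects.base_sd_log2, size=P)

    groups = samples["group"].to_numpy()
    group_levels = list(dict.fromkeys(groups))
    test_group = group_levels[0]  # planted effects act on the first group level

    # planted fold changes: a de_fraction subset, random sign; true_lfc is the
    # first-group-minus-rest contrast
    lfc = np.zeros(P)
    n_de = int(round(effects.de_fraction * P))
    if n_de > 0 and len(group_levels) > 1:
        de_idx = rng.choice(P, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = signs * effects.de_log2fc

    y = np.tile(mu[:, None], (1, S))
    if len(group_levels) > 1:
        affected = (groups == test_group).astype(float)
        y += lfc[:, None] * affected[None, :]

    comp = effects.variance_components
    factor_cols = {"group_re": "group", "individual": "individual",
                   "workflow": "workflow", "fixation": "fixation", "batch": "batch"}
    for factor in RANDOM_FACTORS:
        var = comp[factor]
        labels = samples[factor_cols[factor]].to_numpy()
        levels, codes = np.unique(labels, return_inverse=True)
        # draw even when var == 0 so the stream layout is stable across settings
        u = rng.normal(0.0, np.sqrt(var), size=(P, len(levels)))
        y += u[:, codes]
    y += rng.normal(0.0, np.sqrt(comp["residual"]), size=(P, S))

    values = pd.DataFrame(y, index=pd.Index([f"P{i + 1:05d}" for i in range(P)],
                                            name="protein_id"),
                          columns=samples["sample_id"].tolist())

    if effects.missing_model is not None:
        slope, midpoint = effects.missing_model
        p_missing = expit(-slope * (y - midpoint))
        drop = rng.random(size=(P, S)) < p_missing
        values = values.mask(pd.DataFrame(drop, index=values.index, columns=values.columns))

    total_var = sum(comp.values())
    fractions = {f"frac_{k}": (v / total_var if total_var > 0 else 0.0)
                 for k, v in comp.items()}
    per_protein = pd.DataFrame({"true_lfc": lfc, **{k: np.full(P, v) for k, v in fractions.items()}},
                               index=values.index)
    return IntensityMatrix(values, scale="log2", provenance="synthetic"), SimTruth(per_protein)


# ---------------------------------------------------------------------------
# cell reference simulation
# ---------------------------------------------------------------------------

def simulate_cell_reference(n_genes: int, cell_types, planted_markers: dict[str, str] | None = None,
                            seed: int = 0, marker_elevation: float = 8.0,
                            between_type_sd: float = 1.0, base_mean: float = 1.0,
                            marker_fraction_range: tuple[float, float] = (0.5, 0.95),
                            background_fraction_range: tuple[float, float] = (0.05, 0.9)):
    """Build a genes x cell-types mean-expression / fraction-expressed reference.

    Non-marker genes have exchangeable means across types (gene baseline plus
    iid between-type noise).  A planted marker's mean is elevated by
    ``marker_elevation`` between-type SDs in its own type, and its
    fraction-expressed there is drawn above the conventional 25% marker
    threshold.  The default elevation of 8 SDs reflects the near-exclusive
    expression of canonical cell-type markers in log-normalized single-cell
    references; note that across ``n`` types the z-score of a single elevated
    type cannot exceed (n-1)/sqrt(n), so small elevations are undetectable by
    construction.

    Returns ``(CellReference, SimTruth)``.
    """
    from .celltype import CellReference

    cell_types = list(cell_types)
    if len(cell_types) != len(set(cell_types)):
        raise InvalidDesignError("duplicate cell-type labels")
    if n_genes < 1:
        raise InvalidDesignError("n_genes must be >= 1")
    planted = dict(planted_markers or {})
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    for g, t in planted.items():
        if g not in gene_set:
            raise InvalidDesignError(f"planted marker {g!r} not among simulated genes")
        if t not in cell_types:
            raise InvalidDesignError(f"planted marker type {t!r} unknown")
    if len(planted) != len(set(planted)):
        raise InvalidDesignError("duplicate gene ids among planted markers")

    rng = np.random.default_rng(seed)
    T = len(cell_types)
    baseline = rng.normal(base_mean, 0.5, size=n_genes)
    mean = baseline[:, None] + rng.normal(0.0, between_type_sd, size=(n_genes, T))
    frac = rng.uniform(*background_fraction_range, size=(n_genes, T))

    type_index = {t: j for j, t in enumerate(cell_types)}
    for g, t in planted.items():
        i, j = genes.index(g), type_index[t]
        mean[i, j] = baseline[i] + marker_elevation * between_type_sd
        frac[i, j] = rng.uniform(*marker_fraction_range)

    ref = CellReference(
        mean=pd.DataFrame(mean, index=pd.Index(genes, name="gene"), columns=cell_types),
        fraction=pd.DataFrame(np.clip(frac, 0.0, 1.0), index=pd.Index(genes, name="gene"),
                              columns=cell_types),
    )
    per_gene = pd.DataFrame({"marker_type": [planted.get(g, "") for g in genes]},
                            index=pd.Index(genes, name="gene"))
    return ref, SimTruth(per_gene, markers=planted)


# ---------------------------------------------------------------------------
# stereology simulation
# ---------------------------------------------------------------------------

def simulate_grid_sections(true_composition, n_points: int, n_sections: int, seed: int = 0,
                           spacing_um: float = 62.25, group: str = "simulated"):
    """Multinomial grid counts per section from a fixed tissue composition.

    ``true_composition`` is the (myocardium, fibrosis, adipose) proportion
    triple; per-section class counts are multinomial(n_points, composition).
    """
    from .stereology import GridCounts, TISSUE_CLASSES

    comp = np.asarray(true_composition, dtype=float)
    if comp.shape != (len(TISSUE_CLASSES),):
        raise InvalidDesignError(f"composition must have {len(TISSUE_CLASSES)} entries")
    if (comp < 0).any():
        raise InvalidDesignError("composition proportions must be >= 0")
    if not np.isclose(comp.sum(), 1.0):
        raise InvalidDesignError("composition proportions must sum to 1")
    if n_points < 1:
        raise InvalidDesignError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_points, comp, size=n_sections)
    table = pd.DataFrame(counts, columns=list(TISSUE_CLASSES),
                         index=pd.Index([f"section_{i + 1}" for i in range(n_sections)],
                                        name="section"))
    return GridCounts(table, spacing_um=spacing_um, group=group)
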