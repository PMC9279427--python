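"""Seeded synthetic data: single-cell cohorts and plasma cytokine panels.

The cohort generator emulates a small pediatric B-ALL study: a handful of
patients split into MRD-positive and MRD-negative groups (MRD = measurable
residual disease after induction chemotherapy), each contributing a mix of
leukemic blasts and non-malignant immune cells captured by droplet
single-cell RNA-seq.  Counts follow a per-gene negative-binomial model
(mean mu, size r, variance mu + mu^2/r) with lognormal per-gene means —
the standard overdispersed count model for scRNA-seq.  Three programs are
layered on top of the baseline means:

* cell-type identity: each type's marker genes are boosted ``marker_boost``-fold;
* exhaustion: the 14 signature genes are multiplied by
  ``exhaustion_effect_lambda`` in cells carrying the exhaustion program,
  which is restricted to cytotoxic types (mature CD8 T, NK, NK-T) and
  assigned at a per-group rate;
* mitochondrial content: per cell, mitochondrial gene means are scaled so
  the expected mito fraction equals a Beta-distributed draw (exercising the
  30% QC cutoff).

Ground truth (true cell type, true exhaustion, true malignancy) is recorded
per cell so downstream stages can be tested for parameter recovery.

All randomness flows from one integer seed through a single
``numpy.random.default_rng`` stream; identical config+seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    EXHAUSTION_SIGNATURE,
    LEUKEMIC_SORT,
    MRD_NEG,
    MRD_POS,
    NONLEUKEMIC_SORT,
    AnalytePanel,
    ContingencyTable2x2,
    CountMatrix,
    validate_annotation,
)

__all__ = [
    "CELL_TYPES",
    "CYTOTOXIC_TYPES",
    "DEFAULT_PROPORTIONS",
    "TRUTH_MARKER_MAP",
    "MITO_GENES",
    "CYTOKINE_35PLEX",
    "CohortConfig",
    "SyntheticCohort",
    "PanelConfig",
    "simulate_cohort",
    "simulate_cytokine_panel",
    "truth_contingency",
]

#: Cell types of the simulated marrow/blood mixture.
CELL_TYPES = (
    "leukemic_blast", "mature_CD8_T", "CD4_T", "NK", "NK_T",
    "myeloid", "erythroid_precursor", "B",
)

#: Types that can carry the exhaustion program.
CYTOTOXIC_TYPES = ("mature_CD8_T", "NK", "NK_T")

#: Default mixture: blasts dominate a diagnostic B-ALL sample; the sorted
#: non-leukemic compartment is T/NK-rich.
DEFAULT_PROPORTIONS = {
    "leukemic_blast": 0.52,
    "mature_CD8_T": 0.14,
    "CD4_T": 0.08,
    "NK": 0.07,
    "NK_T": 0.05,
    "myeloid": 0.06,
    "erythroid_precursor": 0.05,
    "B": 0.03,
}

#: Disjoint canonical marker genes per type; boosted in that type's cells
#: and shipped as the truth marker map for cell-type assignment tests.
TRUTH_MARKER_MAP = {
    "leukemic_blast": ["CD19", "MME", "VPREB1", "CD79A", "DNTT"],
    "mature_CD8_T": ["CD8A", "CD8B", "GZMK", "CCL5"],
    "CD4_T": ["CD4", "IL7R", "CCR7"],
    "NK": ["NCAM1", "KLRD1", "GNLY", "NKG7"],
    "NK_T": ["KLRB1", "ZBTB16", "SLAMF1"],
    "myeloid": ["LYZ", "CD14", "FCN1", "S100A8"],
    "erythroid_precursor": ["HBB", "HBA1", "GYPA", "KLF1"],
    "B": ["MS4A1", "CD79B", "IGHM"],
}

#: The 13 protein-coding human mitochondrial genes ("MT-" prefix drives the
#: mito mask downstream).
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: Analyte names of a representative 35-plex human cytokine/chemokine
#: Luminex panel (includes the IL-7 / IL-1a / IL-1b trio used downstream).
CYTOKINE_35PLEX = (
    "IL-7", "IL-1a", "IL-1b", "IL-1RA", "IL-2", "IL-2R", "IL-4", "IL-5",
    "IL-6", "IL-8", "IL-10", "IL-12", "IL-13", "IL-15", "IL-17A", "TNF-a",
    "IFN-g", "IFN-a", "GM-CSF", "G-CSF", "EGF", "FGF-basic", "HGF", "VEGF",
    "MCP-1", "MIG", "MIP-1a", "MIP-1b", "RANTES", "Eotaxin", "IP-10",
    "IL-22", "IL-9", "IL-21", "IL-23",
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic single-cell cohort.

    Defaults mirror the study design: 4 MRD+ and 3 MRD- patients, mostly
    leukemic blasts, with the exhaustion program enriched in cytotoxic
    cells of MRD+ patients.
    """

    n_mrd_pos: int = 4
    n_mrd_neg: int = 3
    cells_per_patient: int = 500
    cell_type_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_genes: int = 2000
    n_mito_genes: int = 13
    baseline_mean_log_mu: float = -0.5
    baseline_mean_log_sigma: float = 1.0
    dispersion: float = 2.0          # NB size r; variance = mu + mu^2/r
    marker_boost: float = 6.0
    marker_baseline_mean: float = 1.0  # baseline counts/cell of lineage markers (boosted in own type)
    type_program_genes: int = 30       # breadth of each type's diffuse expression program
    type_program_boost: float = 3.0    # fold change of program genes in their own type
    signature_baseline_scale: float = 1.8   # mean baseline counts/cell of signature genes
    signature_mean_log_sigma: float = 0.4   # spread of signature-gene means (milder than genome-wide)
    signature_dispersion: float = 5.0       # NB size r for signature genes
    signature_program_sigma: float = 0.25   # lognormal sd of the per-cell program intensity
    activated_frac: float = 0.07            # fraction of cells with transient activation program
    activated_boost: float = 1.5            # median signature boost in activated cells
    activated_sigma: float = 0.35           # lognormal sd of the activation boost
    exhaustion_effect_lambda: float = 3.0
    exhausted_frac_mrd_pos: float = 0.20
    exhausted_frac_mrd_neg: float = 0.02
    library_size_sigma: float = 0.45  # lognormal sd of per-cell size factor
    mito_frac_alpha: float = 2.0     # Beta(2, 13): ~4.8% of cells exceed 0.30
    mito_frac_beta: float = 13.0
    sort_error_rate: float = 0.02    # flow-sort mislabeling rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mrd_pos <= 0 or self.n_mrd_neg <= 0 or self.cells_per_patient <= 0:
            raise ValueError("patient and cell counts must be positive")
        if self.n_genes <= 0 or not (0 < self.n_mito_genes <= len(MITO_GENES)):
            raise ValueError(f"n_genes must be > 0 and 0 < n_mito_genes <= {len(MITO_GENES)}")
        props = self.cell_type_proportions
        unknown = set(props) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in proportions: {sorted(unknown)}")
        total = float(sum(props.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_proportions must sum to 1 (got {total})")
        if any(p < 0 for p in props.values()):
            raise ValueError("proportions must be nonnegative")
        for name in ("exhausted_frac_mrd_pos", "exhausted_frac_mrd_neg", "sort_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exhaustion_effect_lambda < 1.0:
            raise ValueError("exhaustion_effect_lambda must be >= 1")
        if self.signature_baseline_scale <= 0 or self.signature_mean_log_sigma <= 0:
            raise ValueError("signature mean parameters must be positive")
        if self.marker_baseline_mean <= 0:
            raise ValueError("marker_baseline_mean must be positive")
        if self.signature_program_sigma < 0:
            raise ValueError("signature_program_sigma must be >= 0")
        if not 0.0 <= self.activated_frac <= 1.0:
            raise ValueError("activated_frac must be in [0, 1]")
        if self.activated_boost < 1.0 or self.activated_sigma < 0:
            raise ValueError("activated_boost must be >= 1 and activated_sigma >= 0")
        if self.dispersion <= 0 or self.signature_dispersion <= 0 or self.baseline_mean_log_sigma <= 0:
            raise ValueError("dispersion parameters and baseline_mean_log_sigma must be positive")
        if self.mito_frac_alpha <= 0 or self.mito_frac_beta <= 0:
            raise ValueError("mito Beta parameters must be positive")
        if self.library_size_sigma < 0:
            raise ValueError("library_size_sigma must be >= 0")
        if self.type_program_genes < 0 or self.type_program_boost < 1.0:
            raise ValueError("type_program_genes must be >= 0 and type_program_boost >= 1")
        n_special = (len(EXHAUSTION_SIGNATURE)
                     + sum(len(v) for v in TRUTH_MARKER_MAP.values())
                     + len(CELL_TYPES) * self.type_program_genes)
        if self.n_genes < n_special + self.n_mito_genes:
            raise ValueError(
                f"n_genes must be >= {n_special + self.n_mito_genes} to hold signature, "
                "marker, type-program and mitochondrial genes"
            )

    def program_gene_names(self, cell_type: str) -> list[str]:
        return [f"PRG-{cell_type}-{i:02d}" for i in range(self.type_program_genes)]

    def gene_names(self) -> list[str]:
        """Deterministic gene universe: signature, markers, type programs,
        mito, then filler."""
        names = list(EXHAUSTION_SIGNATURE)
        for t in CELL_TYPES:
            names.extend(TRUTH_MARKER_MAP[t])
        for t in CELL_TYPES:
            names.extend(self.program_gene_names(t))
        names.extend(MITO_GENES[: self.n_mito_genes])
        n_fill = self.n_genes - len(names)
        names.extend(f"GENE{i:05d}" for i in range(n_fill))
        return names


@dataclass
class SyntheticCohort:
    """A simulated cohort: counts, annotation with truth columns, config echo."""

    counts: CountMatrix
    annotation: pd.DataFrame
    config: CohortConfig
    seed: int

    def __post_init__(self) -> None:
        validate_annotation(self.annotation)
        for col in ("true_cell_type", "true_exhausted", "true_malignant"):
            if col not in self.annotation.columns:
                raise ValueError(f"truth column {col!r} missing from annotation")


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a seeded synthetic cohort under ``config``.

    Per cell: a type from the configured proportions; per gene a
    negative-binomial count with lognormal baseline mean, marker boost for
    the cell's own type, the exhaustion multiplier on signature genes iff
    the cell carries the program, and mitochondrial means scaled to an
    expected Beta-distributed mito fraction.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    patients = [f"P{i + 1:02d}" for i in range(config.n_mrd_pos + config.n_mrd_neg)]
    groups = [MRD_POS] * config.n_mrd_pos + [MRD_NEG] * config.n_mrd_neg
    n_cells = config.cells_per_patient * len(patients)

    # Baseline per-gene means, shared across patients.  Signature genes get
    # their own low mean with a milder spread: inhibitory receptors and
    # exhaustion TFs are lowly expressed at baseline, which gives the score
    # distributions the skewed right tail the upper-outlier rule operates on.
    base_mu = rng.lognormal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, n_genes)
    sig_rows = [gene_idx[g] for g in EXHAUSTION_SIGNATURE]
    base_mu[sig_rows] = config.signature_baseline_scale * rng.lognormal(
        -config.signature_mean_log_sigma**2 / 2.0, config.signature_mean_log_sigma,
        len(sig_rows),
    )
    # Lineage markers get a solid, mildly spread baseline: canonical subset
    # markers are well-expressed genes, which is what makes the marker boost
    # a clusterable signal.
    marker_rows = [gene_idx[g] for t in CELL_TYPES for g in TRUTH_MARKER_MAP[t]]
    base_mu[marker_rows] = config.marker_baseline_mean * rng.lognormal(
        -0.3**2 / 2.0, 0.3, len(marker_rows))

    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[[gene_idx[g] for g in MITO_GENES[: config.n_mito_genes]]] = True
    sig_cols = np.array([gene_idx[g] for g in EXHAUSTION_SIGNATURE])
    marker_cols = {t: np.array([gene_idx[g] for g in TRUTH_MARKER_MAP[t]]) for t in CELL_TYPES}

    types = np.array(CELL_TYPES)
    probs = np.array([config.cell_type_proportions.get(t, 0.0) for t in CELL_TYPES])

    # Per-cell draws.
    patient_id = np.repeat(patients, config.cells_per_patient)
    mrd_group = np.repeat(groups, config.cells_per_patient)
    cell_type = types[rng.choice(len(types), size=n_cells, p=probs)]
    is_cytotoxic = np.isin(cell_type, CYTOTOXIC_TYPES)
    exh_rate = np.where(mrd_group == MRD_POS, config.exhausted_frac_mrd_pos, config.exhausted_frac_mrd_neg)
    true_exhausted = is_cytotoxic & (rng.random(n_cells) < exh_rate)
    true_malignant = cell_type == "leukemic_blast"
    mito_frac = rng.beta(config.mito_frac_alpha, config.mito_frac_beta, n_cells)

    prog_cols = {t: np.array([gene_idx[g] for g in config.program_gene_names(t)], dtype=int)
                 for t in CELL_TYPES}

    # Expected-count matrix: baseline, then programs.
    mu = np.tile(base_mu, (n_cells, 1))
    for t in CELL_TYPES:
        rows = np.flatnonzero(cell_type == t)
        if rows.size:
            mu[np.ix_(rows, marker_cols[t])] *= config.marker_boost
            if prog_cols[t].size:
                mu[np.ix_(rows, prog_cols[t])] *= config.type_program_boost
    # The checkpoint/exhaustion program is continuous: every cell carries a
    # lognormal program intensity (mean 1) on the signature genes, and a
    # small fraction of cells transiently up-regulate the program on
    # activation (checkpoint genes are activation-induced).  Together these
    # give the pooled score distributions the heavy right tail the
    # upper-outlier rule is built for; cells labeled exhausted get an extra
    # lambda-fold boost on top.
    program = np.ones(n_cells)
    if config.signature_program_sigma > 0:
        program *= rng.lognormal(-config.signature_program_sigma**2 / 2.0,
                                 config.signature_program_sigma, n_cells)
    activated = rng.random(n_cells) < config.activated_frac
    if activated.any():
        program[activated] *= rng.lognormal(np.log(config.activated_boost),
                                            config.activated_sigma, int(activated.sum()))
    mu[:, sig_cols] *= program[:, None]
    exh_rows = np.flatnonzero(true_exhausted)
    if exh_rows.size:
        mu[np.ix_(exh_rows, sig_cols)] *= config.exhaustion_effect_lambda
    # Scale mito-gene means so E[mito]/E[total] = mito_frac per cell.
    nonmito_sum = mu[:, ~mito_mask].sum(axis=1)
    mito_weights = base_mu[mito_mask] / base_mu[mito_mask].sum()
    target_mito_sum = mito_frac / (1.0 - mito_frac) * nonmito_sum
    mu[:, mito_mask] = np.outer(target_mito_sum, mito_weights)
    # Per-cell library-size factor (mean 1): captures the capture-depth
    # spread of droplet data; scales the whole cell, so expected mito and
    # signature fractions are unchanged.
    if config.library_size_sigma > 0:
        size_factor = rng.lognormal(-config.library_size_sigma**2 / 2.0,
                                    config.library_size_sigma, n_cells)
        mu *= size_factor[:, None]

    # NB draw via gamma-Poisson mixture; signature genes carry their own
    # (smaller) size parameter.
    size_per_gene = np.full(n_genes, config.dispersion)
    size_per_gene[sig_cols] = config.signature_dispersion
    lam = rng.gamma(shape=size_per_gene, scale=mu / size_per_gene)
    counts = rng.poisson(lam).astype(np.int64)

    barcodes = [f"{p}-{i:05d}" for p, i in zip(patient_id, range(n_cells))]
    flow_label = np.where(true_malignant, LEUKEMIC_SORT, NONLEUKEMIC_SORT)
    flip = rng.random(n_cells) < config.sort_error_rate
    flow_label = np.where(
        flip,
        np.where(flow_label == LEUKEMIC_SORT, NONLEUKEMIC_SORT, LEUKEMIC_SORT),
        flow_label,
    )

    annotation = pd.DataFrame(
        {
            "barcode": barcodes,
            "patient_id": patient_id,
            "mrd_group": mrd_group,
            "flow_label": flow_label,
            "malignancy": np.where(flow_label == LEUKEMIC_SORT, "leukemic", "nonleukemic"),
            "true_cell_type": cell_type,
            "true_exhausted": true_exhausted,
            "true_malignant": true_malignant,
        }
    )
    matrix = CountMatrix(
        barcodes=barcodes, genes=genes, values=sp.csr_matrix(counts), mito_mask=mito_mask
    )
    return SyntheticCohort(counts=matrix, annotation=annotation, config=config, seed=config.seed)


@dataclass
class PanelConfig:
    """Parameters of the synthetic 35-analyte plasma cytokine panel.

    Per-analyte concentrations are lognormal; group effects multiply the
    median of the affected group.  The default effect elevates IL-7 in the
    MRD-negative group, mirroring the reported direction.
    """

    n_analytes: int = 35
    n_mrd_pos: int = 12
    n_mrd_neg: int = 12
    log_mean: float = 3.0            # ln pg/mL scale
    log_sd: float = 0.5
    effect_analytes: dict = field(default_factory=lambda: {"IL-7": (MRD_NEG, 3.5)})
    detection_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_analytes <= len(CYTOKINE_35PLEX)):
            raise ValueError(f"n_analytes must be in (0, {len(CYTOKINE_35PLEX)}]")
        if self.n_mrd_pos < 1 or self.n_mrd_neg < 1:
            raise ValueError("group sizes must be >= 1")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        for analyte, (grp, fold) in self.effect_analytes.items():
            if grp not in (MRD_POS, MRD_NEG):
                raise ValueError(f"effect group for {analyte!r} must be {MRD_POS} or {MRD_NEG}")
            if fold <= 0:
                raise ValueError("effect folds must be positive")

    def analyte_names(self) -> list[str]:
        return list(CYTOKINE_35PLEX[: self.n_analytes])


def simulate_cytokine_panel(config: PanelConfig) -> tuple[AnalytePanel, dict]:
    """Draw a seeded synthetic cytokine panel under ``config``.

    Returns the panel and the truth effect map (analyte -> (group, fold)).
    Values at/below the detection floor are stored at the floor with the
    below-floor flag set, never dropped.
    """
    rng = np.random.default_rng(config.seed)
    analytes = config.analyte_names()
    unknown = set(config.effect_analytes) - set(analytes)
    if unknown:
        raise ValueError(f"effect analytes not in panel: {sorted(unknown)}")

    samples = [f"S{i + 1:02d}" for i in range(config.n_mrd_pos + config.n_mrd_neg)]
    group = pd.Series(
        [MRD_POS] * config.n_mrd_pos + [MRD_NEG] * config.n_mrd_neg,
        index=samples, name="group",
    )

    log_conc = rng.normal(config.log_mean, config.log_sd, size=(len(samples), len(analytes)))
    values = pd.DataFrame(np.exp(log_conc), index=samples, columns=analytes)
    for analyte, (grp, fold) in config.effect_analytes.items():
        values.loc[group == grp, analyte] *= fold

    floors = pd.Series(config.detection_floor, index=analytes, dtype=float)
    below = values.le(floors, axis=1)
    values = values.mask(below, floors, axis=1)
    panel = AnalytePanel(values=values, group=group, detection_floor=floors, below_floor=below)
    return panel, dict(config.effect_analytes)


def truth_contingency(cohort: SyntheticCohort) -> ContingencyTable2x2:
    """Tally true exhaustion x MRD group among non-malignant cells.

    The oracle counterpart of the pipeline's estimated contingency table:
    rows are true_exhausted yes/no, columns MRD+ / MRD-.
    """
    ann = cohort.annotation
    for col in ("true_exhausted", "true_malignant"):
        if col not in ann.columns:
            raise ValueError(f"truth column {col!r} missing")
    scope = ann[~ann["true_malignant"]]
    pos = scope["mrd_group"] == MRD_POS
    exh = scope["true_exhausted"].astype(bool)
    return ContingencyTable2x2(
        a=int((exh & pos).sum()),
        b=int((exh & ~pos).sum()),
        c=int((~exh & pos).sum()),
        d=int((~exh & ~pos).sum()),
    )
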