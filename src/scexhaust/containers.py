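"""Core in-memory containers shared across the pipeline.

Conventions
-----------
Count and normalized matrices are oriented **cells x genes** everywhere.
Raw counts are nonnegative integers stored sparse (CSR); normalized values
are nonnegative floats with the same sparsity pattern as the counts they
came from.  Per-cell metadata travels as a plain :class:`pandas.DataFrame`
with a fixed column vocabulary (see :data:`ANNOTATION_COLUMNS`), the way
scanpy keeps ``adata.obs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormMatrix",
    "SignatureSet",
    "AnalytePanel",
    "TestResult",
    "ContingencyTable2x2",
    "EXHAUSTION_SIGNATURE",
    "MRD_POS",
    "MRD_NEG",
    "LEUKEMIC_SORT",
    "NONLEUKEMIC_SORT",
    "MALIGNANCY_LEVELS",
    "ANNOTATION_COLUMNS",
    "validate_annotation",
]

# Fixed vocabularies for the categorical annotation columns.
MRD_POS = "MRD_pos"
MRD_NEG = "MRD_neg"
LEUKEMIC_SORT = "leukemic_sort"
NONLEUKEMIC_SORT = "nonleukemic_sort"
MALIGNANCY_LEVELS = ("leukemic", "nonleukemic", "omitted")

#: Required / recognised columns of a cell annotation table.  ``barcode``,
#: ``patient_id``, ``mrd_group`` and ``flow_label`` are mandatory; the rest
#: are filled in by pipeline stages.
ANNOTATION_COLUMNS = {
    "barcode": None,
    "patient_id": None,
    "mrd_group": (MRD_POS, MRD_NEG),
    "flow_label": (LEUKEMIC_SORT, NONLEUKEMIC_SORT),
    "cluster_id": None,
    "malignancy": MALIGNANCY_LEVELS,
    "cell_type": None,
    "score_norm": None,
    "score_frac": None,
    "high_exhaustion": None,
}

_REQUIRED_ANNOTATION = ("barcode", "patient_id", "mrd_group", "flow_label")


def validate_annotation(ann: pd.DataFrame, require: Sequence[str] = _REQUIRED_ANNOTATION) -> pd.DataFrame:
    """Validate a per-cell annotation table against the fixed schema.

    Checks that required columns exist, barcodes are unique, and every
    categorical column only uses its fixed vocabulary.  Returns the frame
    unchanged on success.
    """
    missing = [c for c in require if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing required columns: {missing}")
    if ann["barcode"].duplicated().any():
        dup = ann["barcode"][ann["barcode"].duplicated()].iloc[0]
        raise ValueError(f"duplicate cell barcode in annotation: {dup!r}")
    for col, vocab in ANNOTATION_COLUMNS.items():
        if vocab is None or col not in ann.columns:
            continue
        values = ann[col].dropna()
        bad = set(values.unique()) - set(vocab)
        if bad:
            raise ValueError(f"annotation column {col!r} contains unknown categories {sorted(bad)}; allowed: {vocab}")
    return ann


def _as_int_csr(values) -> sp.csr_matrix:
    m = sp.csr_matrix(values)
    if m.nnz and m.data.min() < 0:
        raise ValueError("count matrix contains negative entries")
    if not np.issubdtype(m.dtype, np.integer):
        if m.nnz and not np.allclose(m.data, np.round(m.data)):
            raise ValueError("count matrix contains non-integer entries")
        m = m.astype(np.int64)
    m.eliminate_zeros()
    return m


@dataclass
class CountMatrix:
    """Sparse cells x genes raw transcript counts.

    Parameters
    ----------
    barcodes : cell identifiers, unique, in row order.
    genes : gene symbols, unique, in column order.
    values : sparse nonnegative integer matrix, shape (n_cells, n_genes).
    mito_mask : boolean per gene, True for mitochondrial genes.
    """

    barcodes: list[str]
    genes: list[str]
    values: sp.csr_matrix
    mito_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_int_csr(self.values)
        self.barcodes = [str(b) for b in self.barcodes]
        self.genes = [str(g) for g in self.genes]
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        n_cells, n_genes = self.values.shape
        if len(self.barcodes) != n_cells:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n_cells} matrix rows")
        if len(self.genes) != n_genes:
            raise ValueError(f"{len(self.genes)} genes for {n_genes} matrix columns")
        if self.mito_mask.shape != (n_genes,):
            raise ValueError("mito_mask length must equal number of genes")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("barcodes are not unique")
        if len(set(self.genes)) != n_genes:
            raise ValueError("gene symbols are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_totals(self) -> np.ndarray:
        """Total transcript count per cell."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return np.diff(self.values.indptr)

    def mito_fraction(self) -> np.ndarray:
        """Mitochondrial count fraction per cell; 0 for zero-total cells."""
        totals = self.cell_totals().astype(float)
        mito = np.asarray(self.values[:, self.mito_mask].sum(axis=1)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1), 0.0)
        return frac

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.arange(self.shape[0])[mask_or_idx]
        return CountMatrix(
            barcodes=[self.barcodes[i] for i in idx],
            genes=list(self.genes),
            values=self.values[idx],
            mito_mask=self.mito_mask.copy(),
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class NormMatrix:
    """Log-normalized expression with the same ids/shape as its source counts.

    ``values[c, g] = ln(1 + scale_factor * count[c, g] / total[c])`` — zero
    exactly where the raw count is zero.
    """

    barcodes: list[str]
    genes: list[str]
    values: sp.csr_matrix
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        n_cells, n_genes = self.values.shape
        if len(self.barcodes) != n_cells or len(self.genes) != n_genes:
            raise ValueError("barcode/gene lists inconsistent with matrix shape")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("normalized matrix contains non-finite values")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("normalized matrix contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


#: The 14-gene T/NK exhaustion signature used for per-cell scoring:
#: inhibitory receptors (PDCD1, CTLA4, HAVCR2, TIGIT, LAG3, CD244, CD160),
#: exhaustion-associated transcription factors (TOX, TOX2, NFATC1, NFATC2,
#: NR4A1, TCF7) and the costimulatory receptor ICOS.
EXHAUSTION_SIGNATURE = (
    "PDCD1", "CTLA4", "HAVCR2", "TIGIT", "TOX", "LAG3", "NFATC1",
    "NFATC2", "NR4A1", "TOX2", "TCF7", "CD244", "CD160", "ICOS",
)


@dataclass(frozen=True)
class SignatureSet:
    """A named gene list used for per-cell signature scoring."""

    name: str = "exhaustion"
    genes: tuple[str, ...] = EXHAUSTION_SIGNATURE

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate gene symbols")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "SignatureSet":
        """Read a signature as one gene symbol per line (blank lines and
        ``#`` comments ignored)."""
        with open(path) as fh:
            genes = tuple(
                line.strip() for line in fh
                if line.strip() and not line.lstrip().startswith("#")
            )
        return cls(name=name or str(path), genes=genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnalytePanel:
    """Samples x analytes concentration table (e.g. a Luminex cytokine panel).

    ``values`` holds concentrations in assay units; ``group`` gives one label
    per sample; ``below_floor`` marks values at/below the per-analyte
    detection floor (stored at the floor value, never dropped, so detection
    filtering stays a downstream decision).
    """

    values: pd.DataFrame            # index = samples, columns = analytes
    group: pd.Series                # index = samples
    detection_floor: pd.Series      # index = analytes
    below_floor: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.group.index):
            raise ValueError("panel group labels must be indexed by the same samples as values")
        self.detection_floor = self.detection_floor.reindex(self.values.columns)
        if self.detection_floor.isna().any():
            missing = list(self.detection_floor[self.detection_floor.isna()].index)
            raise ValueError(f"detection floor missing for analytes: {missing}")
        if (self.detection_floor < 0).any():
            raise ValueError("detection floors must be >= 0")
        if (self.values.values < 0).any():
            raise ValueError("concentrations must be >= 0")
        if self.below_floor is None:
            self.below_floor = self.values.le(self.detection_floor, axis=1)
        if self.group.nunique() < 1 or (self.group.value_counts() < 1).any():
            raise ValueError("each group must be nonempty")

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def group_values(self, analyte: str, label: str) -> np.ndarray:
        if analyte not in self.values.columns:
            raise KeyError(f"analyte {analyte!r} not in panel")
        return self.values.loc[self.group == label, analyte].to_numpy(float)

    def subset_analytes(self, keep: Sequence[str]) -> "AnalytePanel":
        keep = list(keep)
        return AnalytePanel(
            values=self.values[keep].copy(),
            group=self.group.copy(),
            detection_floor=self.detection_floor[keep].copy(),
            below_floor=self.below_floor[keep].copy(),
        )


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with procedure metadata."""

    statistic: float
    p: float
    method: str
    q: float | None = None
    reject: bool | None = None
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")
        if self.q is not None and not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q-value out of [0, 1]: {self.q}")

    def with_q(self, q: float, reject: bool) -> "TestResult":
        return replace(self, q=q, reject=reject)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "p": self.p,
            "q": self.q,
            "reject": self.reject,
            "method": self.method,
            "n": list(self.n),
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table.

    Rows: high-exhaustion flag (yes / no); columns: MRD group (pos / neg).

    ``a`` = flagged & MRD+, ``b`` = flagged & MRD-,
    ``c`` = unflagged & MRD+, ``d`` = unflagged & MRD-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def margins(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((row1, row2), (col1, col2)) marginal totals."""
        return ((self.a + self.b, self.c + self.d), (self.a + self.c, self.b + self.d))

    def swapped_groups(self) -> "ContingencyTable2x2":
        """Transpose the group columns (MRD+ <-> MRD-)."""
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)
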