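"""Per-cell exhaustion scoring, upper-outlier calling and MRD association.

Two scores are computed per cell over a fixed gene signature (default: the
14-gene T/NK exhaustion program spanning PDCD1, LAG3, TIGIT, HAVCR2, CTLA4,
CD244, CD160, ICOS, TOX, TOX2, NFATC1, NFATC2, NR4A1 and TCF7):

* ``score_norm`` — the sum of log-normalized expression of the signature
  genes (nonnegative, unbounded);
* ``score_frac`` — signature transcripts as a fraction of all transcripts
  in the cell (in [0, 1]).

"Highly exhausted" cells are the upper outliers of the score
distributions, formalized as the Tukey boxplot fence: score > Q3 + k*IQR
with k = 1.5 and linear-interpolation quartiles.  A cell is flagged when it
is an upper outlier in either score distribution (union default;
intersection available — the source wording does not fix the rule, see the
methods note).  The flag x MRD-group contingency among non-malignant cells
is tested with Pearson's chi-squared with Yates' continuity correction.

The chi-squared test treats cells as independent units, matching the
original pooled analysis; with few patients this pseudoreplicates
patient-level effects, so a per-patient permutation alternative is exposed
(``permutation_p_per_patient``) for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    MRD_NEG,
    MRD_POS,
    ContingencyTable2x2,
    CountMatrix,
    NormMatrix,
    SignatureSet,
    TestResult,
    validate_annotation,
)

__all__ = [
    "ExhaustionConfig",
    "ExhaustionResult",
    "score_normalized_sum",
    "score_count_fraction",
    "flag_upper_outliers",
    "combine_flags",
    "exhaustion_contingency",
    "yates_chi_square",
    "permutation_p_per_patient",
    "run_exhaustion_association",
]

logger = logging.getLogger(__name__)


def _signature_columns(genes: list[str], sig: SignatureSet) -> np.ndarray:
    idx = {g: i for i, g in enumerate(genes)}
    present = [g for g in sig.genes if g in idx]
    absent = [g for g in sig.genes if g not in idx]
    if absent:
        logger.warning("signature %s: %d/%d genes absent from matrix (contribute 0): %s",
                       sig.name, len(absent), len(sig.genes), absent)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    return np.array([idx[g] for g in present])


def score_normalized_sum(norm: NormMatrix, sig: SignatureSet = SignatureSet()) -> np.ndarray:
    """Sum of log-normalized expression of the signature genes, per cell.

    Nonnegative; invariant to gene-column order; signature genes absent
    from the matrix contribute zero (logged).
    """
    cols = _signature_columns(norm.genes, sig)
    return np.asarray(norm.values[:, cols].sum(axis=1)).ravel()


def score_count_fraction(counts: CountMatrix, sig: SignatureSet = SignatureSet()) -> np.ndarray:
    """Signature transcripts over total transcripts, per cell (in [0, 1])."""
    totals = counts.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-total cells present; run qc_filter first")
    cols = _signature_columns(counts.genes, sig)
    sig_counts = np.asarray(counts.values[:, cols].sum(axis=1)).ravel().astype(float)
    return sig_counts / totals


@dataclass(frozen=True)
class TukeyFences:
    q1: float
    q3: float
    upper: float


def flag_upper_outliers(scores: np.ndarray, k: float = 1.5) -> tuple[np.ndarray, TukeyFences]:
    """Flag scores above the Tukey upper fence Q3 + k*IQR.

    Quartiles use linear-interpolation quantiles.  Requires >= 4 finite
    scores; a constant vector has IQR 0 and flags nothing.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4 or not np.all(np.isfinite(scores)):
        raise ValueError("flag_upper_outliers requires >= 4 finite scores")
    q1, q3 = np.quantile(scores, [0.25, 0.75])  # linear interpolation default
    upper = q3 + k * (q3 - q1)
    return scores > upper, TukeyFences(q1=float(q1), q3=float(q3), upper=float(upper))


def combine_flags(outlier_norm: np.ndarray, outlier_frac: np.ndarray, mode: str = "union") -> np.ndarray:
    """Combine the two outlier flag vectors: AND (intersection) or OR (union)."""
    a = np.asarray(outlier_norm, dtype=bool)
    b = np.asarray(outlier_frac, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"flag vectors have different lengths: {a.shape} vs {b.shape}")
    if mode == "intersection":
        return a & b
    if mode == "union":
        return a | b
    raise ValueError(f"unknown combine mode {mode!r} (use 'intersection' or 'union')")


def exhaustion_contingency(
    annotation: pd.DataFrame, scope: str = "nonleukemic"
) -> ContingencyTable2x2:
    """Tally high_exhaustion x MRD group among cells with the given malignancy.

    Rows: flagged yes/no; columns: MRD+ / MRD-.  Omitted cells never enter.
    """
    validate_annotation(annotation, require=("barcode", "patient_id", "mrd_group", "flow_label", "malignancy", "high_exhaustion"))
    sub = annotation[annotation["malignancy"] == scope]
    if sub.empty:
        raise ValueError(f"no cells with malignancy == {scope!r} in scope")
    flagged = sub["high_exhaustion"].astype(bool)
    pos = sub["mrd_group"] == MRD_POS
    return ContingencyTable2x2(
        a=int((flagged & pos).sum()),
        b=int((flagged & ~pos).sum()),
        c=int((~flagged & pos).sum()),
        d=int((~flagged & ~pos).sum()),
    )


def yates_chi_square(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-squared test with Yates' continuity correction on a 2x2 table.

    Closed form: X^2 = N (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)),
    p from the upper tail of chi-squared with 1 df.  The correction is
    clamped at zero, so |ad - bc| <= N/2 gives statistic 0 and p = 1.
    Refused (error) when a marginal total is zero (an expected count is 0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    (r1, r2), (c1, c2) = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(f"degenerate 2x2 table with a zero margin: rows={r1, r2}, cols={c1, c2}")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    statistic = n * num**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(
        statistic=float(statistic),
        p=p,
        method="pearson_chi2_yates",
        n=(r1, r2),
        extra={"table": [[a, b], [c, d]]},
    )


def permutation_p_per_patient(
    annotation: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    scope: str = "nonleukemic",
) -> TestResult:
    """Patient-level permutation alternative to the pooled chi-squared test.

    Statistic: difference in flagged-cell fraction between MRD groups;
    null distribution from permuting MRD labels across patients.  Avoids
    treating cells as independent units.
    """
    sub = annotation[annotation["malignancy"] == scope]
    per_patient = sub.groupby("patient_id").agg(
        frac=("high_exhaustion", "mean"), group=("mrd_group", "first")
    )
    obs = per_patient.loc[per_patient["group"] == MRD_POS, "frac"].mean() - \
        per_patient.loc[per_patient["group"] == MRD_NEG, "frac"].mean()
    rng = np.random.default_rng(seed)
    labels = per_patient["group"].to_numpy()
    fracs = per_patient["frac"].to_numpy()
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        stat = fracs[perm == MRD_POS].mean() - fracs[perm == MRD_NEG].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return TestResult(
        statistic=float(obs), p=float(p), method="per_patient_permutation",
        n=(int((labels == MRD_POS).sum()), int((labels == MRD_NEG).sum())),
    )


@dataclass(frozen=True)
class ExhaustionConfig:
    """Scoring / flagging configuration."""

    signature: SignatureSet = field(default_factory=SignatureSet)
    tukey_k: float = 1.5
    combine_mode: str = "union"
    fence_scope: str = "pooled"   # or "per_patient"

    def __post_init__(self) -> None:
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be positive")
        if self.combine_mode not in ("intersection", "union"):
            raise ValueError("combine_mode must be 'intersection' or 'union'")
        if self.fence_scope not in ("pooled", "per_patient"):
            raise ValueError("fence_scope must be 'pooled' or 'per_patient'")


@dataclass
class ExhaustionResult:
    """Per-cell scores and flags plus the fences that produced them."""

    barcodes: list[str]
    score_norm: np.ndarray
    score_frac: np.ndarray
    outlier_norm: np.ndarray
    outlier_frac: np.ndarray
    high_exhaustion: np.ndarray
    fences_norm: TukeyFences | dict
    fences_frac: TukeyFences | dict
    combine_mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "score_norm": self.score_norm,
                "score_frac": self.score_frac,
                "outlier_norm": self.outlier_norm,
                "outlier_frac": self.outlier_frac,
                "high_exhaustion": self.high_exhaustion,
            }
        )


def _flag_scoped(scores, patient_ids, config: ExhaustionConfig):
    if config.fence_scope == "pooled":
        return flag_upper_outliers(scores, config.tukey_k)
    flags = np.zeros(scores.shape, dtype=bool)
    fences = {}
    for pid in pd.unique(patient_ids):
        m = patient_ids == pid
        flags[m], fences[pid] = flag_upper_outliers(scores[m], config.tukey_k)
    return flags, fences


def run_exhaustion_association(
    counts: CountMatrix,
    norm: NormMatrix,
    annotation: pd.DataFrame,
    config: ExhaustionConfig = ExhaustionConfig(),
) -> tuple[ExhaustionResult, ContingencyTable2x2, TestResult]:
    """End-to-end: score both ways, flag upper outliers among non-malignant
    cells, combine flags, tally against MRD group, run the Yates test.

    ``counts``/``norm``/``annotation`` must be QC'd, normalized and
    malignancy-reconciled, row-aligned by barcode.  Fences are computed on
    the non-malignant compartment (pooled across patients by default) —
    the compartment the association is about.  Omitted cells are excluded
    throughout.
    """
    if list(annotation["barcode"]) != list(counts.barcodes) or list(counts.barcodes) != list(norm.barcodes):
        raise ValueError("counts, norm and annotation must be row-aligned by barcode")

    s_norm = score_normalized_sum(norm, config.signature)
    s_frac = score_count_fraction(counts, config.signature)

    nonleuk = (annotation["malignancy"] == "nonleukemic").to_numpy()
    if nonleuk.sum() < 4:
        raise ValueError("need >= 4 non-malignant cells to compute outlier fences")
    pids = annotation["patient_id"].to_numpy()

    flags_norm = np.zeros(len(s_norm), dtype=bool)
    flags_frac = np.zeros(len(s_frac), dtype=bool)
    flags_norm[nonleuk], fences_norm = _flag_scoped(s_norm[nonleuk], pids[nonleuk], config)
    flags_frac[nonleuk], fences_frac = _flag_scoped(s_frac[nonleuk], pids[nonleuk], config)
    high = combine_flags(flags_norm, flags_frac, config.combine_mode)

    result = ExhaustionResult(
        barcodes=list(counts.barcodes),
        score_norm=s_norm,
        score_frac=s_frac,
        outlier_norm=flags_norm,
        outlier_frac=flags_frac,
        high_exhaustion=high,
        fences_norm=fences_norm,
        fences_frac=fences_frac,
        combine_mode=config.combine_mode,
    )

    ann = annotation.copy()
    ann["score_norm"] = s_norm
    ann["score_frac"] = s_frac
    ann["high_exhaustion"] = high
    table = exhaustion_contingency(ann, scope="nonleukemic")
    test = yates_chi_square(table)
    return result, table, test
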