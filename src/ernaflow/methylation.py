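"""Bisulfite-clone methylation summaries and the association between promoter
methylation and TP53 mutational status.

Clone matrices (clones x CpG positions, entries methylated/unmethylated/
missing) are reduced to a per-sample methylated fraction, thresholded into a
binary call, and cross-tabulated against TP53 status.  The association test
is the Pearson chi-square on the 2x2 table without continuity correction
(with Yates' correction the published cell-line table would not reproduce its
printed p-value).  Percentages are rounded half away from zero, the
convention of the published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

TP53_WT = "WT"
TP53_MUT = "mutant"

DEFAULT_CALL_THRESHOLD = 0.5


@dataclass
class CloneMatrix:
    """Bisulfite-sequencing clones for one sample.

    ``matrix`` is clones x CpG positions with entries 1 (methylated),
    0 (unmethylated) or NaN (missing).
    """

    sample_id: str
    tp53_status: str  # WT / mutant / unknown
    matrix: np.ndarray
    tumour_type: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or 0 in self.matrix.shape:
            raise ValueError("clone matrix needs >=1 clone and >=1 CpG")
        valid = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(valid, (0.0, 1.0)).all():
            raise ValueError("entries must be 0, 1 or NaN")
        if self.tp53_status not in (TP53_WT, TP53_MUT, "unknown"):
            raise ValueError(f"bad TP53 status {self.tp53_status!r}")


def methylation_fraction(clone_matrix: CloneMatrix) -> float:
    """Fraction of methylated entries among non-missing entries."""
    m = clone_matrix.matrix
    n_valid = np.count_nonzero(~np.isnan(m))
    if n_valid == 0:
        raise ValueError(f"{clone_matrix.sample_id}: all entries missing")
    return float(np.nansum(m) / n_valid)


def call_methylated(fraction: float, threshold: float = DEFAULT_CALL_THRESHOLD) -> str:
    """Binary promoter-methylation call; the threshold is inclusive."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return METHYLATED if fraction >= threshold else UNMETHYLATED


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows methylated/unmethylated x columns TP53 WT/mutant."""

    meth_wt: int
    meth_mut: int
    unmeth_wt: int
    unmeth_mut: int

    def __post_init__(self) -> None:
        cells = (self.meth_wt, self.meth_mut, self.unmeth_wt, self.unmeth_mut)
        if any(c < 0 for c in cells) or sum(cells) == 0:
            raise ValueError("counts must be non-negative with positive total")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.meth_wt, self.meth_mut], [self.unmeth_wt, self.unmeth_mut]]
        )


def chi_square_2x2(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (df 1, no continuity correction) and its upper-tail
    p-value.  Requires all expected cell counts to be positive."""
    a, b = table.meth_wt, table.meth_mut
    c, d = table.unmeth_wt, table.unmeth_mut
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal: chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def percent(numer: int, denom: int, convention: str = "round") -> int:
    """Integer percentage; "round" = half away from zero, "trunc" = floor."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * numer / denom
    if convention == "round":
        return int(math.floor(x + 0.5))
    if convention == "trunc":
        return int(math.floor(x))
    raise ValueError("convention must be 'round' or 'trunc'")


@dataclass
class AssociationSummary:
    table: ContingencyTable
    pct_wt: int
    pct_mut: int
    pct_overall: int
    chi2: float
    p_value: float


def association_summary(
    calls: Sequence[tuple[str, str]], convention: str = "round"
) -> AssociationSummary:
    """Tabulate (call, tp53_status) pairs and test the association.

    ``calls`` holds ``(methylation_call, tp53_status)`` per sample; samples
    with unknown TP53 status are excluded.  Raises if either TP53 group is
    empty.
    """
    counts = {(m, s): 0 for m in (METHYLATED, UNMETHYLATED) for s in (TP53_WT, TP53_MUT)}
    for call, status in calls:
        if status == "unknown":
            continue
        if (call, status) not in counts:
            raise ValueError(f"bad call/status pair {(call, status)!r}")
        counts[(call, status)] += 1
    n_wt = counts[(METHYLATED, TP53_WT)] + counts[(UNMETHYLATED, TP53_WT)]
    n_mut = counts[(METHYLATED, TP53_MUT)] + counts[(UNMETHYLATED, TP53_MUT)]
    if n_wt == 0 or n_mut == 0:
        raise ValueError("both TP53 groups need at least one sample")
    table = ContingencyTable(
        meth_wt=counts[(METHYLATED, TP53_WT)],
        meth_mut=counts[(METHYLATED, TP53_MUT)],
        unmeth_wt=counts[(UNMETHYLATED, TP53_WT)],
        unmeth_mut=counts[(UNMETHYLATED, TP53_MUT)],
    )
    chi2, p = chi_square_2x2(table)
    n_meth = table.meth_wt + table.meth_mut
    return AssociationSummary(
        table=table,
        pct_wt=percent(table.meth_wt, n_wt, convention),
        pct_mut=percent(table.meth_mut, n_mut, convention),
        pct_overall=percent(n_meth, n_wt + n_mut, convention),
        chi2=chi2,
        p_value=p,
    )


def tumour_frequency_table(
    calls: Sequence[tuple[str, str]], convention: str = "round"
) -> pd.DataFrame:
    """Per-tumour-type methylation frequency, sorted by descending percent.

    ``calls`` holds ``(methylation_call, tumour_type)`` per sample.  Columns:
    methylated, total, percent.
    """
    rows: dict[str, list[int]] = {}
    for call, ttype in calls:
        rows.setdefault(ttype, [0, 0])
        rows[ttype][1] += 1
        if call == METHYLATED:
            rows[ttype][0] += 1
    df = pd.DataFrame(
        [
            {
                "tumour_type": t,
                "methylated": m,
                "total": n,
                "percent": percent(m, n, convention),
            }
            for t, (m, n) in rows.items()
        ]
    )
    return df.sort_values(
        ["percent", "tumour_type"], ascending=[False, True]
    ).reset_index(drop=True)


def load_clone_matrices(clones_tsv: str, meta_tsv: str) -> list[CloneMatrix]:
    """Load clone matrices from TSV.

    ``clones_tsv`` is long-by-clone: columns ``sample``, ``clone``, then one
    column per CpG with entries 1/0/NA.  ``meta_tsv`` has columns ``sample``,
    ``tp53_status`` and optionally ``tumour_type``.
    """
    clones = pd.read_csv(clones_tsv, sep="\t")
    meta = pd.read_csv(meta_tsv, sep="\t").set_index("sample")
    cpg_cols = [c for c in clones.columns if c not in ("sample", "clone")]
    out = []
    for sample, sub in clones.groupby("sample", sort=True):
        m = sub.sort_values("clone")[cpg_cols].to_numpy(dtype=float)
        row = meta.loc[sample]
        out.append(
            CloneMatrix(
                sample_id=str(sample),
                tp53_status=str(row["tp53_status"]),
                matrix=m,
                tumour_type=(
                    str(row["tumour_type"]) if "tumour_type" in meta.columns else None
                ),
            )
        )
    return out


def write_clone_matrices(
    clones_tsv: str, meta_tsv: str, cohort: Sequence[CloneMatrix]
) -> None:
    """Inverse of :func:`load_clone_matrices` (NaN written as NA)."""
    rows = []
    n_cpgs = cohort[0].matrix.shape[1]
    cols = [f"cpg_{i + 1}" for i in range(n_cpgs)]
    for cm in cohort:
        for ci in range(cm.matrix.shape[0]):
            row = {"sample": cm.sample_id, "clone": ci}
            row.update(
                {
                    c: ("NA" if np.isnan(v) else int(v))
                    for c, v in zip(cols, cm.matrix[ci])
                }
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(clones_tsv, sep="\t", index=False, na_rep="NA")
    meta = pd.DataFrame(
        [
            {
                "sample": cm.sample_id,
                "tp53_status": cm.tp53_status,
                "tumour_type": cm.tumour_type if cm.tumour_type is not None else "NA",
            }
            for cm in cohort
        ]
    )
    meta.to_csv(meta_tsv, sep="\t", index=False)


def expression_methylation_anticorrelation(
    expression: Sequence[float], calls: Sequence[str]
) -> tuple[float, float]:
    """Rank-based association between expression and the methylation call.

    Returns ``(rank_biserial, p_value)`` from a two-sided Mann-Whitney U test
    comparing expression between methylated and unmethylated samples.  The
    rank-biserial correlation is negative when methylated samples express
    less (the silencing signature).
    """
    expr = np.asarray(expression, dtype=float)
    calls = list(calls)
    if len(expr) != len(calls):
        raise ValueError("expression and calls must align")
    meth = expr[[c == METHYLATED for c in calls]]
    unmeth = expr[[c == UNMETHYLATED for c in calls]]
    if len(meth) < 3 or len(unmeth) < 3:
        raise ValueError("need >=3 samples per methylation class")
    if np.all(meth == meth[0]) and np.all(unmeth == unmeth[0]) and meth[0] == unmeth[0]:
        return 0.0, 1.0
    res = stats.mannwhitneyu(meth, unmeth, alternative="two-sided")
    # U counts pairs where a methylated sample outranks an unmethylated one
    rank_biserial = 2.0 * res.statistic / (len(meth) * len(unmeth)) - 1.0
    return float(rank_biserial), float(res.pvalue)
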