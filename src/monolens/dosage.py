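"""Transcriptome dosage analysis for aneuploid samples.

Tests for dosage compensation compare each gene's observed read count with
the count expected were expression uniform across the genome. With
length-proportional expected counts (reads scale with transcript length at
constant molar expression) the per-gene observed/expected ratio sits near 1
genome-wide and near 0.5 on an uncompensated monosomic chromosome.

Also provided: size-factor-normalized log2 fold changes against control
samples (median-of-ratios normalization, spike-ins excluded), Spearman rank
correlation with exact permutation p-values at small n, and the correlation
of single-deletion fitness deviations with expression shifts on a
monosomic chromosome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountsTable",
    "DosageResult",
    "read_counts_table",
    "expected_counts_uniform",
    "dosage_ratio",
    "size_factors",
    "log2fc",
    "spearman",
    "fitness_expression_correlation",
    "benjamini_hochberg",
]

ANNOTATION_COLS = ("chrom", "start", "end", "length", "is_spike", "is_rp")


@dataclass
class CountsTable:
    """Gene x sample read counts with a per-gene annotation.

    ``annotation`` is indexed by gene id with columns chrom, start, end,
    length (1-based inclusive coordinates), is_spike and is_rp flags.
    ``conditions`` maps sample -> "control" or "monosomic:<chrom>".
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = [
            c for c in ANNOTATION_COLS if c not in self.annotation.columns
        ]
        if missing_cols:
            raise ValueError(f"annotation lacks columns {missing_cols}")
        unannotated = self.counts.index.difference(self.annotation.index)
        if len(unannotated):
            raise ValueError(
                f"{len(unannotated)} genes missing from the annotation, "
                f"e.g. {list(unannotated[:3])}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def gene_mask(self, spike: bool | None = None) -> pd.Series:
        ann = self.annotation.loc[self.counts.index]
        if spike is None:
            return pd.Series(True, index=self.counts.index)
        return ann["is_spike"].astype(bool) == spike


@dataclass
class DosageResult:
    """Per-gene ratios/log2FC plus per-chromosome means and a correlation."""

    sample: str
    gene_ratios: pd.Series
    chrom_ratios: dict[str, float]
    log2fc: pd.Series | None = None
    correlation: tuple[float, float, int] | None = None  # (r_s, p, n)


def read_counts_table(
    counts_path, annotation_path, conditions: Mapping[str, str] | None = None
) -> CountsTable:
    """Load a counts TSV (gene_id x sample) and an annotation TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    ann = pd.read_csv(annotation_path, sep="\t", index_col="gene_id")
    return CountsTable(
        counts=counts, annotation=ann, conditions=dict(conditions or {})
    )


def expected_counts_uniform(
    table: CountsTable, sample: str, length_weighted: bool = True
) -> pd.Series:
    """Expected per-gene counts under genome-wide uniform expression.

    Spike-ins are excluded from both the library size and the expectation.
    With ``length_weighted`` (default) the library is spread proportional
    to gene length; otherwise equally across genes. Either way the
    expectations sum exactly to the non-spike library size.
    """
    nonspike = table.gene_mask(spike=False)
    counts = table.counts.loc[nonspike, sample].astype(float)
    lib = float(counts.sum())
    if lib <= 0:
        raise ValueError(f"sample {sample!r} has an empty non-spike library")
    ann = table.annotation.loc[counts.index]
    if length_weighted:
        lengths = ann["length"].astype(float)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("annotation lengths missing or non-positive")
        weights = lengths / lengths.sum()
    else:
        weights = pd.Series(1.0 / len(counts), index=counts.index)
    return lib * weights


def dosage_ratio(
    table: CountsTable, sample: str, length_weighted: bool = True
) -> DosageResult:
    """Observed/expected ratio per gene and its mean per chromosome.

    Genes with zero observed counts keep an exact 0 ratio (no pseudocount
    here; they are real dropouts at the library sizes involved).
    """
    expected = expected_counts_uniform(
        table, sample, length_weighted=length_weighted
    )
    observed = table.counts.loc[expected.index, sample].astype(float)
    ratios = observed / expected
    ann = table.annotation.loc[expected.index]
    chrom_ratios = {
        str(chrom): float(ratios[ann["chrom"] == chrom].mean())
        for chrom in ann["chrom"].unique()
    }
    return DosageResult(
        sample=sample, gene_ratios=ratios, chrom_ratios=chrom_ratios
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-gene geometric mean across samples (genes expressed in
    every sample only); each sample's factor is the median count/reference
    ratio. The caller is expected to drop spike-in rows first.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    ref = np.exp(np.log(positive.to_numpy(dtype=float)).mean(axis=1))
    factors = {
        s: float(np.median(positive[s].to_numpy(dtype=float) / ref))
        for s in counts.columns
    }
    return pd.Series(factors)


def log2fc(
    table: CountsTable,
    monosomic_samples: Sequence[str],
    control_samples: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change of monosomic vs control group means.

    Counts are first scaled by median-of-ratios size factors computed on
    non-spike genes, making the result invariant to library depth.
    All-zero genes in both groups are reported as exactly 0.
    """
    if not monosomic_samples or not control_samples:
        raise ValueError("both sample groups must be non-empty")
    samples = list(dict.fromkeys([*monosomic_samples, *control_samples]))
    nonspike = table.gene_mask(spike=False)
    sf = size_factors(table.counts.loc[nonspike, samples])
    scaled = table.counts.loc[nonspike, samples].astype(float) / sf
    mono_mean = scaled[list(monosomic_samples)].mean(axis=1)
    ctrl_mean = scaled[list(control_samples)].mean(axis=1)
    lfc = np.log2(
        (mono_mean + pseudocount) / (ctrl_mean + pseudocount)
    )
    both_zero = (mono_mean == 0) & (ctrl_mean == 0)
    lfc[both_zero] = 0.0
    return lfc


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation with tie-aware ranks.

    r_s is the Pearson correlation of average ranks. The two-sided p-value
    uses the exact permutation distribution (all n! relabelings of y) for
    n <= ``exact_n_max``, otherwise the usual t approximation with n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n_max:
        rx_c = rx - rx.mean()
        denom = np.sqrt(np.sum(rx_c**2))
        perms = np.array(list(itertools.permutations(ry)))
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        rs_all = perms_c @ rx_c / (
            denom * np.sqrt(np.sum(perms_c**2, axis=1))
        )
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
    else:
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rs, p


def fitness_expression_correlation(
    fitness: Mapping[str, float],
    expression: Mapping[str, float],
    annotation: pd.DataFrame,
    chromosome: str,
) -> tuple[float, float, int]:
    """Correlate deletion fitness deviations with expression shifts.

    Pairs ``(d_i, log2FC_i)`` are formed over genes of ``chromosome``
    present in both maps; returns ``(r_s, p, n)``. Tests whether the most
    haploinsufficient genes are preferentially re-expressed under
    monosomy (compensation would give a negative association).
    """
    on_chrom = set(annotation.index[annotation["chrom"] == chromosome])
    genes = sorted(on_chrom & set(fitness) & set(expression))
    if len(genes) < 3:
        raise ValueError(
            f"only {len(genes)} genes on chromosome {chromosome} occur in "
            "both fitness and expression maps; need >= 3"
        )
    d = [fitness[g] for g in genes]
    lfc = [expression[g] for g in genes]
    rs, p = spearman(d, lfc)
    return rs, p, len(genes)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (off by default everywhere; helper only)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
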