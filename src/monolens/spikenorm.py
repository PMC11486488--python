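"""Absolute transcriptome sizing with external spike-in mRNA.

A fixed amount of synthetic spike mRNA (ERCC-style) added per unit of cell
volume turns relative RNA-seq counts into per-volume absolute comparisons:
the larger the fraction of the library the spike occupies, the smaller the
cellular transcriptome it was mixed into. Raw spike counts are first
multiplied by per-sample adjustment factors that equalize the spike amount
per given cell volume across samples; the non-spike/spike count ratio,
normalized to a reference sample, is then the relative mRNA abundance per
unit cell volume.

Cell volume comes from microscope axis measurements treated as ellipsoid
diameters with the two short axes equal: ``V = (pi/6) * L * W**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .dosage import CountsTable

__all__ = [
    "SpikeConfig",
    "CellGeometry",
    "TranscriptomeSize",
    "adjust_spike_counts",
    "spike_fraction",
    "cell_volume",
    "transcriptome_size",
]


@dataclass
class SpikeConfig:
    """Spike gene ids and per-sample spike adjustment factors.

    The reference sample carries factor 1; other samples' factors rescale
    their raw spike counts to the same spike amount per unit cell volume.
    """

    spike_genes: frozenset[str]
    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = {s: f for s, f in self.factors.items() if f <= 0}
        if bad:
            raise ValueError(f"adjustment factors must be positive: {bad}")
        if not any(f == 1.0 for f in self.factors.values()):
            raise ValueError("one sample must be the reference (factor 1)")

    @property
    def reference_sample(self) -> str:
        return next(s for s, f in self.factors.items() if f == 1.0)


@dataclass
class CellGeometry:
    """Ellipsoid cell-size summary from microscopy axis measurements."""

    long_axis: float
    short_axis: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.long_axis <= 0 or self.short_axis <= 0:
            raise ValueError("axes must be positive")

    @property
    def volume(self) -> float:
        """Single-cell volume, um^3."""
        return cell_volume(self.long_axis, self.short_axis)

    @property
    def total_volume(self) -> float:
        """Summed volume of the measured cells, um^3."""
        return self.n_cells * self.volume


@dataclass
class TranscriptomeSize:
    """Per-sample spike fraction and relative mRNA per unit cell volume."""

    sample: str
    spike_fraction_raw: float
    spike_fraction_adjusted: float
    relative_mrna_per_volume: float


def cell_volume(long_axis: float, short_axis: float) -> float:
    """Ellipsoid volume with the two short axes equal, axes as diameters.

    ``V = (pi/6) * L * W**2`` in um^3 for axes in um.
    """
    if long_axis <= 0 or short_axis <= 0:
        raise ValueError("axes must be positive")
    return math.pi / 6.0 * long_axis * short_axis**2


def adjust_spike_counts(
    counts: CountsTable, config: SpikeConfig
) -> CountsTable:
    """Multiply spike rows by each sample's adjustment factor.

    Non-spike rows are untouched. Adjusted spike counts are generally
    non-integer; they are calibrated abundances, not reads.
    """
    missing_genes = config.spike_genes - set(counts.counts.index)
    if missing_genes:
        raise ValueError(
            f"spike genes absent from the counts table: "
            f"{sorted(missing_genes)[:3]}..."
        )
    missing_factors = [
        s for s in counts.samples if s not in config.factors
    ]
    if missing_factors:
        raise ValueError(f"no adjustment factor for samples {missing_factors}")
    new = counts.counts.astype(float).copy()
    spike_rows = new.index.isin(config.spike_genes)
    for s in new.columns:
        new.loc[spike_rows, s] *= config.factors[s]
    return CountsTable(
        counts=new,
        annotation=counts.annotation,
        conditions=dict(counts.conditions),
    )


def spike_fraction(counts: CountsTable, sample: str) -> float:
    """Share of the sample's total counts that map to spike genes."""
    col = counts.counts[sample].astype(float)
    total = float(col.sum())
    if total <= 0:
        raise ValueError(f"sample {sample!r} has no counts")
    spikes = counts.gene_mask(spike=True)
    return float(col[spikes].sum()) / total


def transcriptome_size(
    counts: CountsTable,
    config: SpikeConfig,
    volumes: Mapping[str, float] | None = None,
) -> dict[str, TranscriptomeSize]:
    """Relative mRNA per unit cell volume for every sample.

    With spike amounts equalized per unit volume (the adjustment factors'
    job; ``volumes`` may additionally rescale when samples contributed
    different total cell volumes), each sample's non-spike/spike count
    ratio is proportional to its mRNA density, and is reported relative to
    the reference sample (factor 1), whose value is exactly 1.
    """
    adjusted = adjust_spike_counts(counts, config)
    density: dict[str, float] = {}
    raw_frac: dict[str, float] = {}
    adj_frac: dict[str, float] = {}
    for s in counts.samples:
        raw_frac[s] = spike_fraction(counts, s)
        adj_frac[s] = spike_fraction(adjusted, s)
        col = adjusted.counts[s]
        spike_sum = float(col[col.index.isin(config.spike_genes)].sum())
        if spike_sum <= 0:
            raise ValueError(f"sample {s!r} has zero spike counts")
        nonspike_sum = float(col.sum()) - spike_sum
        d = nonspike_sum / spike_sum
        if volumes is not None:
            vol = volumes.get(s)
            if vol is None or vol <= 0:
                raise ValueError(f"missing or non-positive volume for {s!r}")
            d /= vol / volumes[config.reference_sample]
        density[s] = d
    ref = density[config.reference_sample]
    return {
        s: TranscriptomeSize(
            sample=s,
            spike_fraction_raw=raw_frac[s],
            spike_fraction_adjusted=adj_frac[s],
            relative_mrna_per_volume=density[s] / ref,
        )
        for s in counts.samples
    }


def fractional_abundances(counts: CountsTable) -> pd.DataFrame:
    """Per-gene fraction of each sample's total counts.

    The scatter-plot input for cross-sample comparisons: on these axes,
    genes from a halved chromosome fall below the diagonal of a
    monosomic-vs-control plot while spikes rise above it.
    """
    totals = counts.counts.sum(axis=0).astype(float)
    return counts.counts.astype(float) / totals
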