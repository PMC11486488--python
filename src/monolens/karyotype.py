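"""Coverage-based karyotyping: monosomy calls from binned read depth.

A whole chromosome present in one copy instead of two halves its
sequencing depth. Depth per fixed-size bin is normalized by the
genome-wide median bin depth (robust to a single halved chromosome, which
contributes well under 10% of bins), giving per-bin and per-chromosome
ratios on which calls are made:

* ``monosomic``  — chromosome mean ratio inside the monosomy band
  (default 0.35-0.65) and most bins in that band;
* ``euploid``    — the same test against the euploid band (0.85-1.15);
* ``segmental``  — a long contiguous run in one band with the remainder in
  the other (partial loss/gain);
* ``ambiguous``  — anything else.

For a monosomic call, a culture contaminated by a fraction ``f`` of
disomic revertants (endoreduplication of the remaining homolog) has
expected ratio ``r = 0.5 * (1 + f)``; the caller therefore reports
``f_hat = 2 r - 1`` clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "CoverageRatios",
    "KaryotypeCall",
    "read_coverage_table",
    "normalize_coverage",
    "call_karyotype",
    "calls_to_frame",
]

CALL_STATES = ("euploid", "monosomic", "segmental", "ambiguous")


@dataclass
class CoverageProfile:
    """Binned read depth for one sample.

    ``bins`` has columns chrom, start, end, reads with 0-based half-open
    coordinates tiling each chromosome without overlap.
    """

    sample_id: str
    bins: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "reads"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"coverage table lacks columns {sorted(missing)}")
        if (self.bins["reads"] < 0).any():
            raise ValueError("read counts must be non-negative")
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if np.any(ends[order][:-1] > starts[order][1:]):
                raise ValueError(f"bins overlap on chromosome {chrom}")


@dataclass
class CoverageRatios:
    """Median-normalized bin ratios plus per-chromosome mean ratios."""

    sample_id: str
    baseline: float
    bins: pd.DataFrame  # chrom, start, end, reads, ratio
    chrom_ratios: dict[str, float]


@dataclass
class KaryotypeCall:
    """Per-chromosome copy-state calls for one sample."""

    sample_id: str
    calls: dict[str, str]  # chrom -> state
    ratios: dict[str, float]  # chrom -> mean ratio
    revertant_fraction: dict[str, float]  # chrom -> f_hat, monosomic calls only

    @property
    def monosomic_chromosomes(self) -> list[str]:
        return [c for c, s in self.calls.items() if s == "monosomic"]


def read_coverage_table(path, sample_id: str = "sample") -> CoverageProfile:
    """Load a binned coverage TSV (chrom, start, end, reads)."""
    df = pd.read_csv(path, sep="\t")
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.median(widths))
    return CoverageProfile(sample_id=sample_id, bins=df, bin_size=bin_size)


def normalize_coverage(
    profile: CoverageProfile,
    baseline_stat: str = "median",
    blacklist: Sequence[str] | None = None,
) -> CoverageRatios:
    """Normalize bin depths by a robust genome-wide baseline.

    ``blacklist`` names chromosomes excluded from both the baseline and
    the output (mitochondrial genome, rDNA-bearing regions and similar
    high-copy territories distort depth ratios).
    """
    bins = profile.bins
    if blacklist:
        bins = bins[~bins["chrom"].isin(set(blacklist))]
    if bins.empty:
        raise ValueError("no bins left after blacklist filtering")
    depths = bins["reads"].to_numpy(dtype=float)
    if baseline_stat == "median":
        baseline = float(np.median(depths))
    elif baseline_stat == "mean":
        baseline = float(depths.mean())
    else:
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")
    if baseline <= 0:
        raise ValueError("baseline depth is zero; cannot form ratios")
    out = bins.copy()
    out["ratio"] = out["reads"] / baseline
    chrom_ratios = {
        str(chrom): float(grp["ratio"].mean())
        for chrom, grp in out.groupby("chrom", sort=False)
    }
    return CoverageRatios(
        sample_id=profile.sample_id,
        baseline=baseline,
        bins=out,
        chrom_ratios=chrom_ratios,
    )


def _smooth(values: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k-bin means (the trailing partial window kept)."""
    if k <= 1 or values.size <= k:
        return values
    n_full = values.size // k
    out = values[: n_full * k].reshape(n_full, k).mean(axis=1)
    if values.size % k:
        out = np.append(out, values[n_full * k :].mean())
    return out


def _in_band(values: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (values > band[0]) & (values < band[1])


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def call_karyotype(
    ratios: CoverageRatios,
    mono_band: tuple[float, float] = (0.35, 0.65),
    eu_band: tuple[float, float] = (0.85, 1.15),
    min_fraction_in_band: float = 0.8,
    smooth_bins: int = 10,
    segmental_min_run: float = 0.2,
) -> KaryotypeCall:
    """Classify every chromosome as euploid/monosomic/segmental/ambiguous.

    Band membership is evaluated on non-overlapping ``smooth_bins``-bin
    mean ratios: at ~80x depth and 1-kb bins the raw per-bin ratio noise
    straddles the band edges, while 10-kb aggregates keep a contaminated
    monosomic chromosome (ratio up to ~0.6 at 20% revertants) solidly
    inside the monosomy band. ``segmental`` requires a contiguous run of at least
    ``segmental_min_run`` of the chromosome in one band with at least
    ``min_fraction_in_band`` of the remaining bins in the other.
    """
    if not mono_band[0] < mono_band[1] <= eu_band[0] < eu_band[1]:
        raise ValueError("bands must be ordered and non-overlapping")
    calls: dict[str, str] = {}
    fhat: dict[str, float] = {}
    for chrom, grp in ratios.bins.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        smoothed = _smooth(grp["ratio"].to_numpy(dtype=float), smooth_bins)
        mean_ratio = ratios.chrom_ratios[str(chrom)]
        in_mono = _in_band(smoothed, mono_band)
        in_eu = _in_band(smoothed, eu_band)
        frac_mono = in_mono.mean()
        frac_eu = in_eu.mean()
        if frac_mono >= min_fraction_in_band and _in_band(
            np.array([mean_ratio]), mono_band
        )[0]:
            state = "monosomic"
        elif frac_eu >= min_fraction_in_band and _in_band(
            np.array([mean_ratio]), eu_band
        )[0]:
            state = "euploid"
        else:
            state = "ambiguous"
            n = smoothed.size
            min_run = max(1, int(np.ceil(segmental_min_run * n)))
            for run_mask, rest_mask in ((in_mono, in_eu), (in_eu, in_mono)):
                run = _longest_run(run_mask)
                if run >= min_run and run < n:
                    rest = rest_mask[~run_mask]
                    if rest.size and rest.mean() >= min_fraction_in_band:
                        state = "segmental"
                        break
        calls[str(chrom)] = state
        if state == "monosomic":
            fhat[str(chrom)] = float(np.clip(2.0 * mean_ratio - 1.0, 0.0, 1.0))
    return KaryotypeCall(
        sample_id=ratios.sample_id,
        calls=calls,
        ratios=dict(ratios.chrom_ratios),
        revertant_fraction=fhat,
    )


def calls_to_frame(call: KaryotypeCall) -> pd.DataFrame:
    """Flatten a KaryotypeCall into a tidy per-chromosome table."""
    rows = []
    for chrom, state in call.calls.items():
        rows.append(
            {
                "sample": call.sample_id,
                "chrom": chrom,
                "ratio": call.ratios[chrom],
                "call": state,
                "revertant_fraction": call.revertant_fraction.get(
                    chrom, np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
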