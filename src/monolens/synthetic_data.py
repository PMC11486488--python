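"""Synthetic data with known truth for every pipeline stage.

The generators emulate the three measurement layers of a monosomic-yeast
experiment:

* **Growth**: 96-well (8 x 12) plate layouts with medium-only blanks in
  the first and last wells and two designated control columns; OD600
  curves follow ``blank + A * min(2**(DR * t), K)`` — exponential doubling
  at rate DR with a saturation ceiling — under multiplicative lognormal
  read noise.
* **DNA coverage**: per-bin Poisson read depth (~80x) with the monosomic
  chromosome at ``0.5 * (1 + f)`` of the genome baseline, ``f`` being the
  fraction of disomic revertant cells contaminating the culture.
* **RNA counts**: negative-binomial gene counts with means proportional
  to a per-gene baseline times gene length, a dosage factor (default 0.5)
  on the monosomic chromosome, an indiscriminate upregulation of a
  ribosomal-protein gene set, and ERCC-style spike transcripts forming a
  requested fraction of each library.

A single global seed fans out to per-component child streams, so any one
layer can be regenerated bit-identically in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dosage import CountsTable
from .growth import GrowthCurve
from .karyotype import CoverageProfile
from . import reference

__all__ = [
    "TruthRecord",
    "PlateLayout",
    "gen_plate_layout",
    "simulate_growth",
    "simulate_coverage",
    "make_annotation",
    "simulate_counts",
    "synthetic_panel_tables",
    "write_od_table",
    "read_od_table",
    "write_coverage_table",
    "write_counts_table",
    "write_annotation",
    "write_truth",
]

ROWS = "ABCDEFGH"
N_COLS = 12
DEFAULT_CONTROL_COLUMNS = (3, 10)


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component child stream of one global seed."""
    return np.random.default_rng([seed, zlib.crc32(component.encode())])


@dataclass
class TruthRecord:
    """Ground truth shared by all generators.

    ``true_dr`` maps strain id -> doublings/hour. ``dosage_factor`` is the
    expression multiplier applied to genes on the monosomic chromosome
    (0.5 = no compensation); ``rp_upregulation`` multiplies the designated
    ribosomal-protein gene set in monosomic samples (the indiscriminate
    RP response seen under monosomy); ``revertant_fraction`` is the
    proportion of disomic revertant cells in the culture.
    """

    strain_ids: tuple[str, ...] = ()
    true_dr: dict[str, float] = field(default_factory=dict)
    monosomic_chromosome: str | None = None
    revertant_fraction: float = 0.0
    dosage_factor: float = 0.5
    rp_upregulation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.true_dr.values()):
            raise ValueError("true doubling rates must be >= 0")
        if not 0 <= self.revertant_fraction < 1:
            raise ValueError("revertant_fraction must be in [0, 1)")
        if self.dosage_factor <= 0:
            raise ValueError("dosage_factor must be positive")


@dataclass
class PlateLayout:
    """8 x 12 plate map: well -> (strain_id or None, well_class)."""

    plate_id: str
    wells: dict[str, tuple[str | None, str]]
    control_columns: tuple[int, int] = DEFAULT_CONTROL_COLUMNS

    def wells_of_class(self, well_class: str) -> list[str]:
        return [w for w, (_, c) in self.wells.items() if c == well_class]

    def strain_of(self, well: str) -> str | None:
        return self.wells[well][0]


def _all_wells() -> list[str]:
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


def gen_plate_layout(
    n_test_strains: int,
    n_controls: int,
    seed: int,
    plate_id: str = "P1",
    test_strain_ids: Sequence[str] | None = None,
    control_strain_ids: Sequence[str] | None = None,
    test_class: str = "test",
    control_columns: tuple[int, int] = DEFAULT_CONTROL_COLUMNS,
) -> PlateLayout:
    """Seeded plate layout: blanks in the corner wells, controls in two
    designated columns, test strains permuted over the remainder.

    Unassigned wells stay medium-only blanks.
    """
    capacity = len(ROWS) * N_COLS
    if n_test_strains + n_controls + 2 > capacity:
        raise ValueError(
            f"capacity exceeded: {n_test_strains} test + {n_controls} "
            f"control + 2 blank wells > {capacity}"
        )
    control_capacity = len(ROWS) * len(control_columns)
    if n_controls > control_capacity:
        raise ValueError(
            f"{n_controls} controls exceed the {control_capacity} wells of "
            f"control columns {control_columns}"
        )
    wells = _all_wells()
    blank_wells = {wells[0], wells[-1]}
    control_wells = [
        f"{r}{c}"
        for c in control_columns
        for r in ROWS
        if f"{r}{c}" not in blank_wells
    ][:n_controls]
    remaining = [
        w for w in wells if w not in blank_wells and w not in control_wells
    ]
    if n_test_strains > len(remaining):
        raise ValueError(
            f"{n_test_strains} test strains exceed the {len(remaining)} "
            "wells left outside blanks and control columns"
        )
    rng = child_rng(seed, f"layout:{plate_id}")
    test_wells = [remaining[i] for i in rng.permutation(len(remaining))[:n_test_strains]]

    if test_strain_ids is None:
        test_strain_ids = [f"del_{i:04d}" for i in range(n_test_strains)]
    if control_strain_ids is None:
        control_strain_ids = [f"ctrl_{i:02d}" for i in range(n_controls)]
    if len(test_strain_ids) != n_test_strains:
        raise ValueError("test_strain_ids length mismatch")
    if len(control_strain_ids) != n_controls:
        raise ValueError("control_strain_ids length mismatch")

    layout: dict[str, tuple[str | None, str]] = {
        w: (None, "blank") for w in wells
    }
    for w, s in zip(control_wells, control_strain_ids):
        layout[w] = (s, "control")
    for w, s in zip(sorted(test_wells, key=wells.index), test_strain_ids):
        layout[w] = (s, test_class)
    return PlateLayout(
        plate_id=plate_id, wells=layout, control_columns=control_columns
    )


def simulate_growth(
    layout: PlateLayout,
    truth: TruthRecord,
    noise_cv: float = 0.02,
    t_end: float = 12.0,
    dt: float = 0.5,
    blank_level: float = 0.08,
    inoculum_od: float = 0.05,
    ceiling: float = 1.6,
) -> list[GrowthCurve]:
    """OD curves for every well of a plate.

    Non-blank wells follow ``blank_level + A * min(2**(DR * t), K)`` with
    the strain's true DR; every reading is multiplied by a lognormal
    factor of unit mean and coefficient of variation ``noise_cv``. Blank
    wells carry the medium level and noise only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.arange(0.0, t_end + dt / 2, dt)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rng = child_rng(truth.seed, f"growth:{layout.plate_id}")
    curves: list[GrowthCurve] = []
    for well, (strain, well_class) in layout.wells.items():
        if well_class == "blank":
            od = np.full_like(times, blank_level)
        else:
            if strain not in truth.true_dr:
                raise ValueError(
                    f"strain {strain!r} in layout has no true DR in the "
                    "truth record"
                )
            dr = truth.true_dr[strain]
            od = blank_level + inoculum_od * np.minimum(
                np.exp2(dr * times), ceiling / inoculum_od
            )
        if noise_cv > 0:
            od = od * rng.lognormal(
                mean=-(sigma**2) / 2, sigma=sigma, size=times.size
            )
        curves.append(
            GrowthCurve(
                plate_id=layout.plate_id,
                well=well,
                strain_id=strain,
                well_class=well_class,
                times=times,
                od=od,
            )
        )
    return curves


def simulate_coverage(
    truth: TruthRecord,
    mean_depth: float = 80.0,
    bin_size: int = 1000,
    chrom_lengths: Mapping[str, int] | None = None,
    sample_id: str = "sample",
) -> CoverageProfile:
    """Poisson bin counts at ``mean_depth``, halved (plus revertant
    contribution) on the monosomic chromosome.

    Expected per-bin depth is ``mean_depth * 0.5 * (1 + f)`` on the lost
    chromosome — monosomic cells contribute one copy, the revertant
    fraction ``f`` two — and ``mean_depth`` elsewhere.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if chrom_lengths is None:
        chrom_lengths = reference.CHROM_LENGTHS
    rng = child_rng(truth.seed, f"coverage:{sample_id}")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, length)
        factor = 1.0
        if chrom == truth.monosomic_chromosome:
            factor = 0.5 * (1.0 + truth.revertant_fraction)
        reads = rng.poisson(mean_depth * factor, size=n_bins)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "reads": reads}
            )
        )
    return CoverageProfile(
        sample_id=sample_id,
        bins=pd.concat(rows, ignore_index=True),
        bin_size=bin_size,
    )


def make_annotation(
    chrom_lengths: Mapping[str, int] | None = None,
    gene_density: float = 1 / 2000.0,
    n_spikes: int = 92,
    n_rp: int = 140,
    mean_gene_length: float = 1300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic gene annotation: genes tiled along each chromosome.

    Gene counts per chromosome scale with length (default one gene per
    2 kb, ~6100 genes genome-wide); lengths are lognormal around
    ``mean_gene_length``; coordinates are 1-based inclusive. Spike
    transcripts get the pseudo-chromosome ``"spike"`` and ERCC-style ids;
    ``n_rp`` genes across the genome are flagged as the
    ribosomal-protein set.
    """
    if chrom_lengths is None:
        chrom_lengths = reference.CHROM_LENGTHS
    rng = child_rng(seed, "annotation")
    records = []
    for chrom, clen in chrom_lengths.items():
        n_genes = max(2, int(round(clen * gene_density)))
        lengths = np.round(
            rng.lognormal(np.log(mean_gene_length), 0.35, size=n_genes)
        ).astype(int)
        lengths = np.clip(lengths, 150, None)
        gaps = rng.integers(100, 1000, size=n_genes)
        starts = 1 + np.cumsum(gaps) + np.concatenate(
            [[0], np.cumsum(lengths[:-1])]
        )
        for i, (s, ln) in enumerate(zip(starts, lengths)):
            records.append(
                {
                    "gene_id": f"g{chrom}_{i:04d}",
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s + ln - 1),
                    "length": int(ln),
                    "is_spike": False,
                    "is_rp": False,
                }
            )
    ann = pd.DataFrame(records).set_index("gene_id")
    rp_idx = rng.choice(len(ann), size=min(n_rp, len(ann)), replace=False)
    ann.iloc[rp_idx, ann.columns.get_loc("is_rp")] = True
    if n_spikes:
        spike_lengths = np.round(
            rng.lognormal(np.log(800.0), 0.4, size=n_spikes)
        ).astype(int)
        spikes = pd.DataFrame(
            {
                "chrom": "spike",
                "start": 1,
                "end": spike_lengths,
                "length": spike_lengths,
                "is_spike": True,
                "is_rp": False,
            },
            index=pd.Index(
                [f"ERCC-{i:05d}" for i in range(1, n_spikes + 1)],
                name="gene_id",
            ),
        )
        ann = pd.concat([ann, spikes])
    return ann


def simulate_counts(
    truth: TruthRecord,
    annotation: pd.DataFrame,
    lib_size: float = 5e6,
    dispersion: float = 0.05,
    spike_fractions: Mapping[str, float] | None = None,
    samples: Mapping[str, str] | None = None,
    baseline_sigma: float = 0.10,
    baseline: Sequence[float] | None = None,
    spike_dispersion: float = 0.005,
) -> CountsTable:
    """Negative-binomial RNA counts with planted dosage effects.

    Per-gene means are ``baseline_i * length_i``, times
    ``truth.dosage_factor`` on the monosomic chromosome and
    ``truth.rp_upregulation`` on the RP set in monosomic samples, scaled
    so each sample's non-spike library is ``(1 - spike_fraction) *
    lib_size`` in expectation. Spike genes fill the requested fraction.
    ``dispersion`` is the NB dispersion alpha (variance ``mu + alpha *
    mu**2``) of cellular genes; 0 means noiseless diagnostic mode where
    counts equal their expectations exactly (possibly non-integer).
    Spike transcripts use ``spike_dispersion`` instead — spike-ins carry
    technical noise only, not biological replicate variance.

    ``baseline`` fixes per-gene baselines explicitly (scalar-broadcast);
    by default they are lognormal with sigma ``baseline_sigma``, a
    deliberately moderate heterogeneity chosen so chromosome-level dosage
    summaries are stable at realistic per-chromosome gene counts (real
    expression is far more dispersed; see the methods note).
    """
    if lib_size <= 0:
        raise ValueError("lib_size must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for col in ("chrom", "length"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks required column {col!r}")
    if samples is None:
        samples = {"ctrl_1": "control", "ctrl_2": "control", "ctrl_3": "control"}
        if truth.monosomic_chromosome is not None:
            mono = f"monosomic:{truth.monosomic_chromosome}"
            samples = {**samples, "mono_1": mono, "mono_2": mono, "mono_3": mono}
    spike_fractions = dict(spike_fractions or {})
    rng = child_rng(truth.seed, "counts")

    is_spike = annotation["is_spike"].astype(bool).to_numpy()
    genes = annotation.index
    n_genes = len(genes)
    if baseline is None:
        base = rng.lognormal(0.0, baseline_sigma, size=n_genes)
    else:
        base = np.broadcast_to(
            np.asarray(baseline, dtype=float), (n_genes,)
        ).copy()
    lengths = annotation["length"].to_numpy(dtype=float)
    on_mono = (
        (annotation["chrom"] == truth.monosomic_chromosome).to_numpy()
        if truth.monosomic_chromosome
        else np.zeros(n_genes, bool)
    )
    is_rp = annotation["is_rp"].astype(bool).to_numpy()
    spike_profile = rng.lognormal(0.0, 1.0, size=int(is_spike.sum()))

    data = {}
    for sample, condition in samples.items():
        f_s = spike_fractions.get(sample, 0.0)
        if not 0 <= f_s < 1:
            raise ValueError(f"spike fraction for {sample!r} must be in [0, 1)")
        mu = base * lengths
        if condition.startswith("monosomic"):
            mu = mu * np.where(on_mono, truth.dosage_factor, 1.0)
            mu = mu * np.where(is_rp, truth.rp_upregulation, 1.0)
        mu = np.where(is_spike, 0.0, mu)
        mu = mu / mu.sum() * lib_size * (1.0 - f_s)
        if f_s > 0:
            sp = spike_profile / spike_profile.sum() * lib_size * f_s
            mu[is_spike] = sp
        if dispersion == 0:
            counts = mu
        else:
            alpha = np.where(is_spike, spike_dispersion, dispersion)
            counts = np.zeros(n_genes)
            pos = mu > 0
            nb = pos & (alpha > 0)
            po = pos & (alpha == 0)
            n_param = np.empty(n_genes)
            n_param[nb] = 1.0 / alpha[nb]
            counts[nb] = rng.negative_binomial(
                n_param[nb], n_param[nb] / (n_param[nb] + mu[nb])
            )
            counts[po] = rng.poisson(mu[po])
        data[sample] = counts
    counts_df = pd.DataFrame(data, index=genes)
    return CountsTable(
        counts=counts_df,
        annotation=annotation,
        conditions=dict(samples),
    )


# ---------------------------------------------------------------------------
# Synthetic stand-in for the panel fitness source table
# ---------------------------------------------------------------------------

def synthetic_panel_tables(
    seed: int = 0,
    replicates: int = 4,
    noise_sd: float = 0.02,
    panel_size: int = reference.PANEL_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SYNTHETIC stand-in for the panel's per-strain fitness source table.

    The real experiment deposited a per-deletion replicate rDR table; this
    generator fabricates one with the same shape and the same published
    summaries: per-chromosome deviation sums reproduce the reference
    ``rDR_E`` values and monosomic replicate means reproduce the reference
    observed ``rDR_M`` values (see :mod:`monolens.reference`), for the
    eight strains with published numbers. Chromosomes without published
    summaries get plausible seeded values. Individual deletion effects and
    replicate noise are random — only the calibrated summaries are
    meaningful.

    Returns ``(deletions, monosomics)``: TSV-shaped frames with columns
    (deletion_id, chromosome, replicate, rdr) and (strain, replicate, rdr).
    """
    rng = child_rng(seed, "panel-tables")
    lengths = reference.CHROM_LENGTHS
    total_len = sum(lengths.values())
    # deletion counts per chromosome, proportional to length, summing to panel_size
    raw = {c: panel_size * ln / total_len for c, ln in lengths.items()}
    alloc = {c: max(3, int(round(v))) for c, v in raw.items()}
    while sum(alloc.values()) != panel_size:
        drift = 1 if sum(alloc.values()) < panel_size else -1
        c = max(
            alloc,
            key=lambda k: drift * (raw[k] - alloc[k]),
        )
        alloc[c] += drift

    predicted = dict(reference.PANEL_PREDICTED_RDR)
    observed = dict(reference.PANEL_OBSERVED_RDR)
    del_rows = []
    mono_rows = []
    for strain, chrom in reference.STRAIN_CHROMOSOME.items():
        n = alloc[chrom]
        target = predicted.get(strain)
        if target is None:
            target = float(rng.uniform(-1.2, 0.8))
        # per-deletion mean deviations around the per-chromosome average
        means = (target - 1.0) / n + rng.normal(0.0, 0.04, size=n)
        reps = means[:, None] + rng.normal(0.0, noise_sd, size=(n, replicates))
        # calibrate: shift so the sum of replicate-mean deviations is exact
        shift = ((target - 1.0) - reps.mean(axis=1).sum()) / n
        reps += shift
        for i in range(n):
            for r in range(replicates):
                del_rows.append(
                    {
                        "deletion_id": f"d{chrom}_{i:03d}",
                        "chromosome": chrom,
                        "replicate": r + 1,
                        "rdr": 1.0 + reps[i, r],
                    }
                )
        if strain in ("M7", "M12", "M13"):
            continue  # monosomics never isolated for these chromosomes
        obs = observed.get(strain)
        if obs is None:
            obs = float(rng.uniform(0.45, 0.9))
        mono = obs + rng.normal(0.0, noise_sd, size=replicates)
        mono += obs - mono.mean()
        for r in range(replicates):
            mono_rows.append(
                {"strain": strain, "replicate": r + 1, "rdr": mono[r]}
            )
    return pd.DataFrame(del_rows), pd.DataFrame(mono_rows)


# ---------------------------------------------------------------------------
# Plain-text writers/readers
# ---------------------------------------------------------------------------

def write_od_table(curves: Iterable[GrowthCurve], path) -> None:
    """TSV: plate, well, strain_id, well_class, time_hr, od."""
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append(
                {
                    "plate": c.plate_id,
                    "well": c.well,
                    "strain_id": "" if c.strain_id is None else c.strain_id,
                    "well_class": c.well_class,
                    "time_hr": t,
                    "od": od,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_od_table(path) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    curves = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=False):
        grp = grp.sort_values("time_hr")
        strain = grp["strain_id"].iloc[0]
        curves.append(
            GrowthCurve(
                plate_id=str(plate),
                well=str(well),
                strain_id=None if strain == "" else str(strain),
                well_class=str(grp["well_class"].iloc[0]),
                times=grp["time_hr"].to_numpy(float),
                od=grp["od"].to_numpy(float),
            )
        )
    return curves


def write_coverage_table(profile: CoverageProfile, path) -> None:
    """TSV: chrom, start, end, reads (0-based half-open bins)."""
    profile.bins.to_csv(path, sep="\t", index=False)


def write_counts_table(table: CountsTable, path) -> None:
    """TSV: gene_id x sample count matrix."""
    table.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """TSV: gene_id, chrom, start, end, length, is_spike, is_rp."""
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=list)
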