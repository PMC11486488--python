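"""Reference constants for the *S. cerevisiae* monosomy panel.

Chromosome lengths follow the R64-1-1 assembly (rounded to the nearest
kilobase; the karyotype and simulation code only needs them to set bin and
gene counts, not base-pair-exact coordinates).

``PANEL_PREDICTED_RDR`` and ``PANEL_OBSERVED_RDR`` hold the published
per-chromosome fitness summary for the monosomic panel: the no-epistasis
prediction ``rDR_E = 1 + sum(d_i)`` from the single-deletion load of each
chromosome, and the measured relative doubling rate of the corresponding
monosomic strain. They cover the eight strains for which both numbers were
printed. Monosomies of chromosomes VII, XII and XIII could not be isolated
(endoreduplication outpaces them, and XII carries the rDNA hotspot), so no
strain `M7`, `M12` or `M13` appears anywhere in the panel.
"""

from __future__ import annotations

# R64-1-1 nuclear chromosome lengths, bp (Roman-numeral naming I..XVI).
CHROM_LENGTHS: dict[str, int] = {
    "I": 230_000,
    "II": 813_000,
    "III": 317_000,
    "IV": 1_532_000,
    "V": 577_000,
    "VI": 270_000,
    "VII": 1_091_000,
    "VIII": 563_000,
    "IX": 440_000,
    "X": 746_000,
    "XI": 667_000,
    "XII": 1_078_000,
    "XIII": 924_000,
    "XIV": 784_000,
    "XV": 1_091_000,
    "XVI": 948_000,
}

ROMAN_ORDER = list(CHROM_LENGTHS)

#: Monosomic strain id -> chromosome lost (M4 lost chromosome IV, etc.).
STRAIN_CHROMOSOME: dict[str, str] = {
    f"M{i}": roman for i, roman in enumerate(ROMAN_ORDER, start=1)
}

#: Published no-epistasis predictions, rDR_E = 1 + sum d_i per chromosome.
#: Negative values are "effectively lethal" predictions and are kept as is.
PANEL_PREDICTED_RDR: dict[str, float] = {
    "M1": 0.85,
    "M2": -0.95,
    "M3": 0.66,
    "M8": 0.27,
    "M10": -0.82,
    "M11": -0.33,
    "M14": -0.04,
    "M16": -1.52,
}

#: Published measured rDR of the monosomic strains (same eight strains).
PANEL_OBSERVED_RDR: dict[str, float] = {
    "M1": 0.96,
    "M2": 0.60,
    "M3": 0.63,
    "M8": 0.61,
    "M10": 0.49,
    "M11": 0.60,
    "M14": 0.63,
    "M16": 0.58,
}

#: Candidate-panel set arithmetic: two published haploinsufficiency screens
#: flagged 184 and 404 genes (112 shared) out of ~5200; 5 strains were
#: unavailable and 3 more dropped, leaving the 468-strain deletion panel.
SCREEN_A_SIZE = 184
SCREEN_B_SIZE = 404
SCREEN_OVERLAP = 112
GENOME_GENE_COUNT = 5200
PANEL_EXCLUDED_MISSING = 5
PANEL_EXCLUDED_DROPPED = 3
PANEL_SIZE = 468
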