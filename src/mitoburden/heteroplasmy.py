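"""Heteroplasmic fraction (HF) and cohort allele-frequency banding.

Unlike nuclear loci, a cell carries hundreds to thousands of mtDNA copies,
so a mutant allele affects a continuous proportion of molecules.  The HF is
that proportion estimated from reads: mutant reads over total reads at the
site, expressed as a percentage.  Biochemical phenotypes typically appear
only above a mutant-load ("metabolic") threshold, taken here as 40% by
default.

Cohort carrier frequencies are banded into common (> 5%) versus
low-frequency alleles; a frequency of exactly 5% falls in the low-frequency
band (both bands are defined by strict inequalities, so the boundary is a
convention; it is configurable).
"""

from __future__ import annotations

from .model import AlleleObservation, MitoburdenError

#: Mutant-load threshold (percent) above which a biochemical effect is expected.
METABOLIC_THRESHOLD_PCT = 40.0

#: Cohort carrier-frequency threshold (percent) splitting common vs low-frequency.
COMMON_FREQUENCY_PCT = 5.0

COMMON = "common"
LOW_FREQUENCY = "low_frequency"


def compute_hf(obs: AlleleObservation) -> float:
    """Heteroplasmic fraction in percent: 100 * mutant_reads / total_reads."""
    if obs.total_reads <= 0:
        raise MitoburdenError("total_reads must be positive to compute an HF")
    return 100.0 * obs.mutant_reads / obs.total_reads


def hf_threshold_flag(hf: float, threshold_pct: float = METABOLIC_THRESHOLD_PCT) -> bool:
    """True iff the HF strictly exceeds the metabolic threshold."""
    return hf > threshold_pct


def frequency_band(
    carriers: int, cohort_n: int, threshold_pct: float = COMMON_FREQUENCY_PCT
) -> str:
    """Band a cohort carrier frequency: common iff 100*carriers/cohort_n > 5."""
    if cohort_n <= 0:
        raise MitoburdenError("cohort_n must be positive")
    if not 0 <= carriers <= cohort_n:
        raise MitoburdenError(f"carriers {carriers} outside [0, {cohort_n}]")
    return COMMON if 100.0 * carriers / cohort_n > threshold_pct else LOW_FREQUENCY
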