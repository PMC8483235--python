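"""Published sample accounting for the three UK COPD cohorts emulated here.

These constants transcribe the per-site and per-subgroup sample/patient
tallies reported for the COPDMAP+AERIS discovery set and the BEAT-COPD
validation set. They exist for conservation bookkeeping: the totals used
throughout the pipeline must equal the sums of the published strata, and
the sanity checks below recompute them rather than hard-coding totals.
"""

from __future__ import annotations

__all__ = [
    "DISCOVERY_SITE_SAMPLES",
    "DISCOVERY_SITE_PATIENTS",
    "DISCOVERY_ENDOTYPE_SAMPLES",
    "DISCOVERY_VISIT_TYPE_SAMPLES",
    "VALIDATION_VISIT_TYPE_SAMPLES",
    "VALIDATION_PATIENTS",
    "discovery_total_samples",
    "discovery_total_patients",
    "discovery_endotype_total",
    "validation_total_samples",
]

#: Discovery (COPDMAP + AERIS) sputum samples per clinical site.
DISCOVERY_SITE_SAMPLES = {
    "London": 300,
    "Leicester": 303,
    "Manchester": 180,
    "Southampton": 583,
}

#: Discovery patients per clinical site.
DISCOVERY_SITE_PATIENTS = {
    "Leicester": 100,
    "London": 128,
    "Manchester": 94,
    "Southampton": 101,
}

#: Discovery samples per sputum inflammatory subgroup (incomplete cell
#: counts leave a sample unassigned).
DISCOVERY_ENDOTYPE_SAMPLES = {
    "neutrophilic": 551,
    "eosinophilic": 189,
    "mixed": 187,
    "paucigranulocytic": 302,
    "unassigned": 137,
}

#: Discovery samples by visit type.
DISCOVERY_VISIT_TYPE_SAMPLES = {"stable": 920, "exacerbation": 446}

#: Validation (BEAT-COPD) samples by visit type.
VALIDATION_VISIT_TYPE_SAMPLES = {"stable": 203, "exacerbation": 137}

#: Validation cohort participants.
VALIDATION_PATIENTS = 87


def discovery_total_samples() -> int:
    """Total discovery samples recomputed from the per-site strata."""
    return sum(DISCOVERY_SITE_SAMPLES.values())


def discovery_total_patients() -> int:
    """Total discovery patients recomputed from the per-site strata."""
    return sum(DISCOVERY_SITE_PATIENTS.values())


def discovery_endotype_total() -> int:
    """Discovery samples recomputed across the four subgroups + unassigned."""
    return sum(DISCOVERY_ENDOTYPE_SAMPLES.values())


def validation_total_samples() -> int:
    """Total validation samples recomputed from the visit-type strata."""
    return sum(VALIDATION_VISIT_TYPE_SAMPLES.values())
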