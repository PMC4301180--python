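"""GO biological-process classes used to score regulator specialization.

Transcription-associated proteins (TAPs) are tabulated into two process
sides: regulation of development versus response to stimulus or stress.
Membership is decided from precomputed GO annotations: the development side
is GO:0032502 (developmental process) as provided, the stimulus/stress side
is GO:0050896 (response to stimulus) or GO:0006950 (response to stress).
Genes annotated to both sides form the mixed class.
"""

from __future__ import annotations

GO_DEVELOPMENTAL = "GO:0032502"
GO_RESPONSE_TO_STIMULUS = "GO:0050896"
GO_RESPONSE_TO_STRESS = "GO:0006950"

DEVELOPMENTAL_TERMS = frozenset({GO_DEVELOPMENTAL})
STIMULUS_STRESS_TERMS = frozenset({GO_RESPONSE_TO_STIMULUS, GO_RESPONSE_TO_STRESS})

DEVELOPMENTAL = "developmental"
STIMULUS_STRESS = "stimulus_or_stress"
BOTH = "both"
UNANNOTATED = "unannotated"
UNSPECIALIZED = "unspecialized"

PROCESS_CLASSES = (DEVELOPMENTAL, STIMULUS_STRESS)


def process_class(go_terms) -> str:
    """Classify a gene's GO term set into one of the four tabulation classes."""
    terms = set(go_terms)
    dev = bool(terms & DEVELOPMENTAL_TERMS)
    stim = bool(terms & STIMULUS_STRESS_TERMS)
    if dev and stim:
        return BOTH
    if dev:
        return DEVELOPMENTAL
    if stim:
        return STIMULUS_STRESS
    return UNANNOTATED
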