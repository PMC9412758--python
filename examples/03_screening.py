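"""Screen one patient against the hereditary-cancer criteria in both modes.

The family history is only actionable once the comment is read: the coded
fields say "CANCER" in an aunt, while the comment gives the site (breast)
and a diagnosis in her 30s — enough for the breast/ovarian criterion that
asks for a first- or second-degree relative with breast cancer at 45 or
younger.
"""

from fhhkit import FHHEntry, Mode, PatientProfile, screen_patient

profile = PatientProfile(
    patient_id="P7",
    entries=[
        FHHEntry("P7", "E1", condition_code="CANCER", relative_code="AUNT",
                 comment="breast ca, dx in 30s"),
        FHHEntry("P7", "E2", condition_code="DIABETES", relative_code="FATHER",
                 comment="insulin dependent"),
    ],
)

for mode in (Mode.STRUCTURED_ONLY, Mode.NLP_AUGMENTED):
    print(f"--- {mode.value}")
    for result in screen_patient(profile, mode):
        verdict = "ELIGIBLE" if result.eligible else "not eligible"
        criteria = ", ".join(result.matched_criteria) or "-"
        print(f"  {result.cohort.value:<15} {verdict:<13} criteria: {criteria}")

# Structured-only sees an unspecified cancer with no onset and finds
# nothing; the augmented mode reads the comment and fires BO1.  The
# non-cancer entry is filtered out before either mode runs.
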