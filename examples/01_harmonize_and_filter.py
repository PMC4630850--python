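"""Harmonize native tool vocabularies and apply the inclusion filter.

Each predictor names its classes differently; harmonization collapses
them onto {damaging, tolerated}.  The inclusion filter then keeps only
variants whose truth label is properly evidenced: pathogenic needs
functional or co-segregation support, benign needs functional support or
a population allele frequency above 1%.
"""

import consilico as c

for tool, label in [("PolyPhen-2", "Possibly damaging"), ("SNAP", "Non-neutral"),
                    ("PROVEAN", "Neutral"), ("SIFT", "Tolerated")]:
    call = c.harmonize_label(tool, label, c.DEFAULT_VOCABULARIES[tool])
    print(f"{tool:12s} {label!r:22s} -> {call}")

records = [
    c.VariantRecord("KCNQ1:p.R190Q", "KCNQ1", "pathogenic", "cosegregation"),
    c.VariantRecord("KCNQ1:p.P448R", "KCNQ1", "benign", "allele_frequency",
                    allele_frequency=0.02),
    c.VariantRecord("KCNH2:p.R176W", "KCNH2", "benign", "allele_frequency",
                    allele_frequency=0.005),
]
kept, rejected = c.apply_inclusion_filter(records)
print(f"\nkept {len(kept)} of {len(records)} variants")
for rec, reason in rejected:
    print(f"rejected {rec.variant_id}: {reason}")
# The 0.5% variant falls below the >1% frequency rule, so its benign
# label is not considered evidenced and it leaves the benchmark.
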