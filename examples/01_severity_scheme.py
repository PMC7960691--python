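"""Severity categories and disability weights.

Classifies a few better-ear pure-tone averages (dB) into the seven severity
categories and looks up the disability weights used to convert prevalence
into years lived with disability.
"""

from hearburden import DisabilityWeightTable, HealthState, SeverityScheme

scheme = SeverityScheme.default()
weights = DisabilityWeightTable.default()

for pta in (12.0, 27.5, 41.0, 72.0, 101.0):
    cat = scheme.classify(pta)
    w_plain = weights.weight(HealthState(cat, False)) if cat != "normal" else 0.0
    w_ring = weights.weight(HealthState(cat, True)) if cat != "normal" else 0.0
    print(f"PTA {pta:5.1f} dB -> {cat:18s} weight {w_plain:.3f} (with ringing {w_ring:.3f})")

# Each line shows the severity band a pure-tone average falls into and the
# disability weight of its two health states; one person-year lived at that
# state contributes exactly that many YLDs.
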