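"""Score the four self-report instruments for one participant.

PHQ-9 (depression, 9 items 0-3), GAD-7 (anxiety, 7 items 0-3), SWLS (life
satisfaction, 5 items 1-7) and QOLIBRI (brain-injury quality of life,
37 items 1-5, rescaled to 0-100).
"""

from rgsc import score_gad7, score_phq9, score_qolibri, score_swls

phq = score_phq9([2, 1, 2, 1, 1, 0, 2, 1, 1])
print(f"PHQ-9 total {phq.total} -> band '{phq.band}', dichotomy '{phq.binary}'")

gad = score_gad7([1, 1, 2, 0, 1, 1, 1])
print(f"GAD-7 total {gad.total} -> dichotomy '{gad.binary}'")

swls = score_swls([4, 5, 4, 3, 4])
print(f"SWLS total {swls.total} -> band '{swls.band}' (20 is the neutral point)")

qol = score_qolibri([3] * 20 + [4] * 17)
print(
    f"QOLIBRI raw {qol.raw} -> scaled {qol.scaled:.1f}/100; "
    f"low HRQoL (<60): {qol.low_hrqol}"
)

print(
    "\nThe PHQ-9 severity bands open at totals 5/10/15/20; the QOLIBRI "
    "scaled score is the linear map of the raw total from 37..185 onto "
    "0..100, with scores below 60 flagging impaired quality of life."
)
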