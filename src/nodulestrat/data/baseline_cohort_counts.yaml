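# Cumulative size-threshold counts at the participant level for a large
# UK lung-cancer-screening baseline LDCT cohort (one index solid nodule per
# participant; "below" is strict).  The 144 unsegmentable nodules carry a
# manual long-axis diameter only and are categorised by the 6 mm / 8 mm
# fallback diameter cut-offs in volume-scale counts.
n_nodule_participants: 5929
n_nodule_cancers: 228
n_no_nodule_participants: 4809
n_no_nodule_cancers: 37
unsegmentable_count: 144
bins:
- {threshold: 80.0, scale: mm3, participants_below: 3756, cancers_below: 30}
- {threshold: 100.0, scale: mm3, participants_below: 4183, cancers_below: 34}
- {threshold: 300.0, scale: mm3, participants_below: 5418, cancers_below: 76}
- {threshold: 5.0, scale: mm, participants_below: 1421, cancers_below: 15}
- {threshold: 6.0, scale: mm, participants_below: 2378, cancers_below: 21}
- {threshold: 8.0, scale: mm, participants_below: 4074, cancers_below: 51}
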