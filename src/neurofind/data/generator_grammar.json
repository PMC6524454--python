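{
  "indications": [
    "Headache",
    "Dizziness",
    "Syncope",
    "Memory concerns",
    "Fall from standing",
    "Visual disturbance",
    "Gait instability"
  ],
  "neutral_findings": [
    "The ventricles and sulci are within normal limits for age.",
    "The midline structures are in the expected position.",
    "The major intracranial flow voids are preserved.",
    "The paranasal sinuses and mastoid air cells are clear.",
    "Gray-matter differentiation is maintained.",
    "The calvarium is intact.",
    "The orbits are unremarkable."
  ],
  "negative_sbi": {
    "cues": ["No", "No evidence of", "No definite", "Without evidence of", "Negative for"],
    "modifiers": ["acute", "acute or subacute", "recent", "new"],
    "findings": ["infarct", "infarction", "territorial infarct", "embolic infarct"],
    "tails": [
      "",
      "is identified",
      "is seen",
      "is demonstrated on this examination",
      "in the brain parenchyma",
      "at this time"
    ],
    "site_b_templates": [
      "No acute infarct.",
      "No acute infarction.",
      "No acute or subacute infarct.",
      "No acute intracranial abnormality.",
      "No evidence of acute infarction.",
      "No evidence of acute territorial infarct.",
      "No acute infarct identified.",
      "No acute infarction is seen.",
      "No new infarct.",
      "No recent infarction.",
      "Negative for acute infarct.",
      "No acute embolic infarct."
    ]
  },
  "positive_sbi": {
    "modifiers": ["Chronic", "Old", "Remote", "Stable"],
    "findings": ["infarct", "lacunar infarct", "lacune", "infarction"],
    "anatomies": [
      "left basal ganglia",
      "right caudate nucleus",
      "left cerebellar hemisphere",
      "right frontal lobe",
      "left corona radiata",
      "right thalamus",
      "left putamen"
    ],
    "frames": [
      "{mod} {finding} in the {anatomy}.",
      "{mod} {finding} involving the {anatomy}.",
      "There is a {mod_lower} {finding} in the {anatomy}.",
      "A {mod_lower} {finding} is present in the {anatomy}."
    ],
    "unmodified_frames": [
      "Lacune in the {anatomy}.",
      "Punctate lacune within the {anatomy}."
    ]
  },
  "hedge_cues": ["Probable", "Possible"],
  "historical_sbi": [
    "History of remote infarct in the {anatomy}.",
    "Known old infarction in the {anatomy}."
  ],
  "confounder_sbi": [
    "There are bilateral intraparenchymal foci of susceptibility artifact in the right occipital lobe, right parietal lobe, right subinsular region and left frontal region.",
    "Scattered foci of susceptibility artifact in the left frontal region and right parietal lobe.",
    "Punctate focus of mineralization in the right frontal lobe.",
    "Small focus of signal dropout in the left caudate region without associated abnormality."
  ],
  "coreference_sbi": [
    [
      "Focal region of encephalomalacia and gliosis in the {anatomy}.",
      "The above findings are nonspecific but likely reflect remote ischemic change."
    ],
    [
      "There is volume loss with surrounding gliosis in the {anatomy}.",
      "The above abnormality most likely represents sequela of prior ischemia."
    ]
  ],
  "positive_wmd": {
    "severities": ["Mild", "Moderate", "Severe", "Extensive", "Scattered"],
    "frames": [
      "{sev} white matter microvascular ischemic changes.",
      "{sev} periventricular white matter microvascular ischemic changes.",
      "{sev} microvascular ischemic changes in the subcortical white matter.",
      "{sev} white matter signal changes consistent with leukoaraiosis.",
      "{sev} confluent white matter microvascular degenerative signal abnormality."
    ]
  },
  "negative_wmd": [
    "No significant white matter signal abnormality.",
    "No confluent white matter signal abnormality.",
    "No white matter signal change of significance.",
    "No abnormal white matter signal is identified."
  ],
  "exclusion_wmd": [
    "Scattered white matter degenerative changes.",
    "Multilevel degenerative changes of the visualized cervical spine."
  ],
  "impressions_neutral": [
    "As described above.",
    "Findings as above.",
    "As detailed in the findings section."
  ]
}
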