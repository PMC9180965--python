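{
 "agreement3": {
  "OD": {
   "DISCORDANT_1_1_1": {
    "eyes": 2,
    "images": 5
   },
   "MAJORITY_2_1": {
    "eyes": 26,
    "images": 66
   },
   "UNANIMOUS_3_0": {
    "eyes": 30,
    "images": 73
   }
  },
  "OS": {
   "DISCORDANT_1_1_1": {
    "eyes": 1,
    "images": 2
   },
   "MAJORITY_2_1": {
    "eyes": 28,
    "images": 67
   },
   "UNANIMOUS_3_0": {
    "eyes": 29,
    "images": 74
   }
  },
  "both": {
   "DISCORDANT_1_1_1": {
    "eyes": 3,
    "images": 7
   },
   "MAJORITY_2_1": {
    "eyes": 54,
    "images": 133
   },
   "UNANIMOUS_3_0": {
    "eyes": 59,
    "images": 147
   }
  }
 },
 "agreement4": {
  "P1_1_1_1": 0,
  "P2_1_1_AI_IN_PAIR": 0,
  "P2_1_1_AI_SINGLETON": 3,
  "P2_2": 13,
  "P3_1_AI_SINGLETON": 5,
  "P3_1_AI_WITH_MAJORITY": 23,
  "P4_0": 14
 },
 "distribution_4pt_by_patient": {
  "counts": {
   "0": 43,
   "1": 6,
   "2": 7,
   "3": 2
  },
  "percentages": {
   "0": 74.14,
   "1": 10.34,
   "2": 12.07,
   "3": 3.45
  },
  "total": 58
 },
 "distribution_5pt_by_eye": {
  "counts": {
   "0": 91,
   "1": 11,
   "2": 11,
   "3": 1,
   "4": 2
  },
  "percentages": {
   "0": 78.45,
   "1": 9.48,
   "2": 9.48,
   "3": 0.86,
   "4": 1.72
  },
  "total": 116
 },
 "exclusion_flow": {
  "n_analyzed": 58,
  "n_excluded_ai_only_ungradable": 11,
  "n_excluded_human_quality": 11,
  "n_incomplete": 0,
  "n_total": 80,
  "n_ungradable_all": 0
 },
 "full_agreement_eyes": {
  "0": {
   "eyes": 48,
   "images": 117
  },
  "1": {
   "eyes": 4,
   "images": 9
  },
  "2": {
   "eyes": 6,
   "images": 18
  },
  "3": {
   "eyes": 1,
   "images": 3
  },
  "4": {
   "eyes": 0,
   "images": 0
  }
 },
 "full_agreement_patients": {
  "0": 11,
  "1": 4,
  "2": 2,
  "3": 2
 },
 "kappa": {
  "mean_pairwise": {
   "grader1": 0.3117833537693767,
   "grader2": 0.3953459005978466,
   "grader3": 0.38298544308400606
  },
  "pairwise": {
   "grader1|grader2": 0.32414381128321723,
   "grader1|grader3": 0.2994228962555362,
   "grader2|grader3": 0.4665479899124759
  },
  "vs_final": {
   "grader1": 0.38397993804395925,
   "grader2": 0.7708333333333333,
   "grader3": 0.52875
  }
 },
 "kappa_weighting": "none",
 "majority_eyes": {
  "0": {
   "eyes": 43,
   "images": 107
  },
  "1": {
   "eyes": 5,
   "images": 13
  },
  "2": {
   "eyes": 4,
   "images": 9
  },
  "3": {
   "eyes": 0,
   "images": 0
  },
  "4": {
   "eyes": 2,
   "images": 4
  }
 },
 "n_graders": 3,
 "rdr": {
  "ai_nonreferable_disagreements": 2,
  "ai_referable_disagreements": 5,
  "eye_full_agreement": 111,
  "eye_majority": 5,
  "full_agreement_ai_disagreements": 7,
  "majority_ai_against_majority": 1,
  "majority_ai_with_majority": 3,
  "n_eyes": 116,
  "n_patients": 58,
  "patient_full_agreement": 54,
  "patient_majority": 4
 },
 "rdr_cutoff": 2
}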