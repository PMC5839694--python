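{
 "version": "AQ-50 standard scoring key v1",
 "response_codes": {
  "1": "strongly_agree",
  "2": "slightly_agree",
  "3": "slightly_disagree",
  "4": "strongly_disagree"
 },
 "items": {
  "item_01": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_02": {
   "subscale": "attention_switching",
   "keyed_direction": "agree_is_autistic"
  },
  "item_03": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_04": {
   "subscale": "attention_switching",
   "keyed_direction": "agree_is_autistic"
  },
  "item_05": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_06": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_07": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_08": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_09": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_10": {
   "subscale": "attention_switching",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_11": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_12": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_13": {
   "subscale": "social_skills",
   "keyed_direction": "agree_is_autistic"
  },
  "item_14": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_15": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_16": {
   "subscale": "attention_switching",
   "keyed_direction": "agree_is_autistic"
  },
  "item_17": {
   "subscale": "communication",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_18": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_19": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_20": {
   "subscale": "imagination",
   "keyed_direction": "agree_is_autistic"
  },
  "item_21": {
   "subscale": "imagination",
   "keyed_direction": "agree_is_autistic"
  },
  "item_22": {
   "subscale": "social_skills",
   "keyed_direction": "agree_is_autistic"
  },
  "item_23": {
   "subscale": "attention_to_detail",
   "keyed_direction": "agree_is_autistic"
  },
  "item_24": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_25": {
   "subscale": "attention_switching",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_26": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_27": {
   "subscale": "communication",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_28": {
   "subscale": "attention_to_detail",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_29": {
   "subscale": "attention_to_detail",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_30": {
   "subscale": "attention_to_detail",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_31": {
   "subscale": "communication",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_32": {
   "subscale": "attention_switching",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_33": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_34": {
   "subscale": "attention_switching",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_35": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_36": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_37": {
   "subscale": "attention_switching",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_38": {
   "subscale": "communication",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_39": {
   "subscale": "communication",
   "keyed_direction": "agree_is_autistic"
  },
  "item_40": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_41": {
   "subscale": "imagination",
   "keyed_direction": "agree_is_autistic"
  },
  "item_42": {
   "subscale": "imagination",
   "keyed_direction": "agree_is_autistic"
  },
  "item_43": {
   "subscale": "attention_switching",
   "keyed_direction": "agree_is_autistic"
  },
  "item_44": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_45": {
   "subscale": "social_skills",
   "keyed_direction": "agree_is_autistic"
  },
  "item_46": {
   "subscale": "attention_switching",
   "keyed_direction": "agree_is_autistic"
  },
  "item_47": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_48": {
   "subscale": "social_skills",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_49": {
   "subscale": "attention_to_detail",
   "keyed_direction": "disagree_is_autistic"
  },
  "item_50": {
   "subscale": "imagination",
   "keyed_direction": "disagree_is_autistic"
  }
 }
}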