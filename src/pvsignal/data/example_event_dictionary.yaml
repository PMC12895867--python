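# Synthetic fixture event dictionary for tests and examples.
#
# Real analyses require user-supplied PT lists derived from a licensed
# MedDRA release (SMQ "Embolic and thrombotic events", 20000081, plus
# literature-based subtype lists).  The lists below are a small illustrative
# subset and are NOT a MedDRA extract.
smq_id: "20000081"
categories:
  VTE:
    - PULMONARY EMBOLISM
    - PULMONARY THROMBOSIS
    - DEEP VEIN THROMBOSIS
    - VENOUS THROMBOSIS
    - JUGULAR VEIN THROMBOSIS
  ATE:
    - MYOCARDIAL INFARCTION
    - ACUTE MYOCARDIAL INFARCTION
    - CEREBRAL INFARCTION
    - CEREBROVASCULAR ACCIDENT
    - ARTERIAL THROMBOSIS
  unspecified_mixed:
    - EMBOLISM
    - THROMBOSIS
    - THROMBOEMBOLIC EVENT
subtypes:
  PE:
    - PULMONARY EMBOLISM
    - PULMONARY THROMBOSIS
  MI:
    - MYOCARDIAL INFARCTION
    - ACUTE MYOCARDIAL INFARCTION
  cerebral_ATE:
    - CEREBRAL INFARCTION
    - CEREBROVASCULAR ACCIDENT
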