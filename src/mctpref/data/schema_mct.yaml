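# Canonical descriptive system for the multi-cancer test choice experiment.
# Seven attributes with level counts (4, 4, 2, 4, 2, 4, 2); 2048 profiles.
# PPV is shown only to the public PPV arm, NPV only to the NPV arm; GPs see all.
attributes:
  - name: ppv
    coding: categorical
    levels: [20, 40, 60, 80]
    reference_level: 80
    arm_visibility: ppv_arm
    monotone: increasing
    wording:
      gp: "Risk of cancer after a positive test"
      public: "Test gets it wrong when it tells us there is a cancer"
  - name: npv
    coding: categorical
    levels: [96.0, 99.0, 99.5, 99.9]
    reference_level: 99.9
    arm_visibility: npv_arm
    monotone: increasing
    wording:
      gp: "Risk of cancer after a negative test"
      public: "Test gets it wrong when it tells us there is not a cancer"
  - name: waiting
    coding: categorical
    levels: ["1 week", "1-2 weeks"]
    reference_level: "1 week"
    monotone: decreasing
    wording:
      gp: "Waiting time for test results"
      public: "Waiting time for test results"
  - name: cancers
    coding: continuous
    levels: [1, 5, 10, 25]
    monotone: increasing
    wording:
      gp: "Number of cancer sites tested"
      public: "Number of cancers tested for"
  - name: site
    coding: categorical
    levels: ["no", "yes"]
    reference_level: "no"
    monotone: increasing
    wording:
      gp: "Can the test identify the site?"
      public: "Test detects type of cancer?"
  - name: form
    coding: categorical
    levels: [blood, faecal, urine, breath]
    reference_level: blood
    monotone: none
    wording:
      gp: "Form of the test"
      public: "Form of the test"
  - name: early
    coding: categorical
    levels: ["no", "yes"]
    reference_level: "no"
    monotone: increasing
    wording:
      gp: "Can the test detect the stage of cancer?"
      public: "Test can detect cancer at an early stage?"
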