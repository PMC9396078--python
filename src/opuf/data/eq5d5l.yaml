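name: EQ-5D-5L
dimensions:
  - code: MO
    name: Mobility
    levels:
      - I have no problems in walking about
      - I have slight problems in walking about
      - I have moderate problems in walking about
      - I have severe problems in walking about
      - I am unable to walk about
  - code: SC
    name: Self-Care
    levels:
      - I have no problems washing or dressing myself
      - I have slight problems washing or dressing myself
      - I have moderate problems washing or dressing myself
      - I have severe problems washing or dressing myself
      - I am unable to wash or dress myself
  - code: UA
    name: Usual Activities
    levels:
      - I have no problems doing my usual activities
      - I have slight problems doing my usual activities
      - I have moderate problems doing my usual activities
      - I have severe problems doing my usual activities
      - I am unable to do my usual activities
  - code: PD
    name: Pain/Discomfort
    levels:
      - I have no pain or discomfort
      - I have slight pain or discomfort
      - I have moderate pain or discomfort
      - I have severe pain or discomfort
      - I have extreme pain or discomfort
  - code: AD
    name: Anxiety/Depression
    levels:
      - I am not anxious or depressed
      - I am slightly anxious or depressed
      - I am moderately anxious or depressed
      - I am severely anxious or depressed
      - I am extremely anxious or depressed
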