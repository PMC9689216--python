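# Default topic lexicon for keyword panels from health-industry news
# coverage: four broad topics with representative (overlapping) keyword
# sets.  Users analysing other corpora should supply their own lexicon.
1:
  label: industry development
  keywords: [Industry, Employment, Retirement, Talents, Reform, Facilities,
             Production, Science and technology, Innovation, Guarantee]
2:
  label: health care
  keywords: [Patient, Medicine, Distribution, Doctor, Sales, Hospital,
             Insurance, Healthy, Culture, Configuration, Institutional system,
             Open]
3:
  label: financial market
  keywords: [Finance, Financial bonds, Risk, Market, Policy provisions,
             Disclosure, Contract, Insurance, Retirement]
4:
  label: industry management
  keywords: [Economy, Deliberation, Conference, Society, Risk, IPO, Finance,
             Capital, Law, Corporate enterprise, Management construction,
             Directors, Policy provisions, Disclosure, Medicine]
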