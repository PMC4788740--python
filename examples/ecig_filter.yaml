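# Synthetic demonstration filter emulating the structure of an
# e-cigarette topic filter: device / brand / behavior keyword categories,
# a co-occurrence exclusion (atomizer + perfume reads as a perfume
# bottle), and a promotional-account handle rule.  This keyword list is
# NOT an authoritative research filter.
name: ecig-demo
keywords:
  device:
    - surface: e-cig
    - surface: e-cigs
    - surface: ecig
    - surface: atomizer
    - {surface: vape pen, mode: phrase}
  brand:
    - blucig
    - vapestick
    - cloudpen
    - nicomist
  behavior:
    - vaping
    - {surface: "#vaping", mode: hashtag}
  exclusion-partner:
    - perfume
  handle:
    - {surface: "@blupromo", mode: handle}
rule:
  any:
    [e-cig, e-cigs, ecig, atomizer, vape pen,
     blucig, vapestick, cloudpen, nicomist,
     vaping, "#vaping"]
exclusions:
  - [atomizer, perfume]
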