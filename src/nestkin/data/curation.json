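[
  {
    "nest": "7",
    "locus": "A14",
    "raw": "2102/14",
    "curated": "210/214",
    "reason": "separator shifted one character in the published cell; fragment sizes 210 and 214 are consistent with the allele range of this locus"
  }
]
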