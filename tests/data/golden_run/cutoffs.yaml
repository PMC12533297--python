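endpoint: os
source: learn
tlnd: 104.22450903688568
tlnv: 48.650025327508295
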