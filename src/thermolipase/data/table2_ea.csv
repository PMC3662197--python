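enzyme,ea_k1_kj_mol,ea_k2_kj_mol
SP14,93.72,125.29
SP22,171.58,185.85
SP29,125.24,80.47
SP73,93.56,83.19
SP75,60.96,165.09
SP76,66.00,85.26
SP79,67.92,91.24
SP83,185.06,115.04
SP93,147.11,165.59
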