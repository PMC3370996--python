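{
 "ALA": 100.1702,
 "ARG": 158.237,
 "ASN": 129.1911,
 "ASP": 129.1911,
 "CYS": 100.1702,
 "GLN": 158.237,
 "GLU": 158.237,
 "GLY": 71.1243,
 "HIS": 158.237,
 "ILE": 129.1911,
 "LEU": 129.1911,
 "LYS": 158.237,
 "MET": 158.237,
 "PHE": 158.237,
 "PRO": 100.1702,
 "SER": 100.1702,
 "THR": 100.1702,
 "TRP": 158.237,
 "TYR": 158.237,
 "VAL": 100.1702
}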