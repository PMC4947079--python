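{
 "table1_xinjiang_uigur.csv": "fbb1287b9b34774f0f4fa07b33d5d83dbfeaa622406fac98e135b58c7e93e96c",
 "table2_da_matrix.csv": "9805b69426968a40d46a6a80a3b60ad0d084aefe1838a222d44ef73101240103"
}
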