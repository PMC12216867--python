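4f2adff425d9a6608b52b5b94a8277ad2b289c295931dbb351f26eb53695be0c  joback_groups.csv
8fe6c73f2d9384ab487460363367703647f1e46595594570ceb67c5f4778814c  melting_properties.csv
df64471c5ffcd10a605a207caab277a59b66ae5df583e8fe29a28da12e0ff88b  phsc_parameters.csv
c55f90a1664e3721556503107b1d35c2db123667221a291a2ccb4ddf623aa83c  sugar_descriptors.csv
c614a08cecce16ff6f97612d43c9c03747699b3cd4024496c17d35be91143e83  ann_printed_weights.json
e0fee7a6f4d260609c9b315e976ac36076f56625476fec25e011be6e71dbf955  group_assignments.json
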