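{
 "table1.tsv": "c988581ed0072bd27d31e6cf6bb129b6441743cea3058f9459883710ed5028ee",
 "table2.tsv": "a7afbe8e19c2c7a3a692d0f08041d940c739a5c61b82c2908b376f63ce5ceaa9",
 "table3.tsv": "2b3d3212cc222d6c97f33aa499a8642f9a43580cbd2a3ade7790a659da9fd8ad",
 "cohort.tsv": "066b7297d9d67f7927091f9be9d4607931733b756ed9dcccec8438516a8e25e8",
 "retnet_snapshot.txt": "0ce6e814a9f1b8bf4dd7cc2fe43c3f2a7f3d0229636ffd3717ea3e0963fe9b20",
 "str_markers_synthetic.tsv": "8c3a25d05d7c89d64e7dc16b0b797bd8d1dcffd8c31aa34f4bf84b5e36d0bb2d",
 "x_genes_synthetic.tsv": "2039f963d1366a5eb173e4c43760d363c18016dda4cfd32e0a26977a53d01fea"
}
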