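{
 "bead_diameters.csv": "e8e079c13e06930380fc46f6edb586a2edc9235bcfd646a8cce2e9243fbc731f",
 "circularity.csv": "7090b2c1a251617bc022dd83631e5fbea7de7ac2f8c02934e46d2f75c3a87cca",
 "ct_distances.csv": "a5f54c4a4d3bb39d86285ac0f99f7d46c0d4a37534288e715f8b142519e3e566",
 "geometries.yaml": "6cfa116c3f768ed5d11bc2dbee414232d8bafba968b62df9bcb0b53028278efa",
 "printed_results.json": "30418c15f7f85951a3ddebb577a92b585f702badd5b3b7e58eaf95d7b60226ff",
 "system_errors.csv": "e784081eb5a831984793020b4b4baba8a7daa776b7e3309de15373d750ee638b"
}
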