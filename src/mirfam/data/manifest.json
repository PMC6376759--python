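{
 "table1.tsv": {
  "rows": 26,
  "sha256": "2a98aa876d47e2c394c3962fd02a45a989c0ff2633d070486e4221cd348baeb0"
 },
 "table2.tsv": {
  "rows": 20,
  "sha256": "aa1306fc782dea82432e5344c20a12a37a25b44dc8e6c853db6482e13a9cc350"
 },
 "table3.tsv": {
  "rows": 45,
  "sha256": "a9d7458631f3cdb46a0560280faed45df3e85f72f07b2fcc236724b7303677ff"
 }
}
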