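# Reference coordinate files

Some acceptance tests validate geometry against published distance tables
for deposited structures. They look here for standard wwPDB files named
`<ID>.pdb` (for example `2CRT.pdb`, `1HRC.pdb`, `1UBQ.pdb`, `5RSA.pdb`,
`1APC.pdb`). Download them from https://files.rcsb.org/download/<ID>.pdb
and drop them in this directory; the tests fail with a clear message when
a file is absent. The candidate-count test additionally needs an
experimental residue-specific dG_HX table as `2CRT_dghx.tsv`
(tab-separated: residue, chain, dG_hx).
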