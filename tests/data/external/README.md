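# External inputs for the deposited-entry reproduction tests

These published files are not redistributed with the package. To run
`tests/test_acceptance.py::TestDepositedEntryReproductions`, place here:

- `4jt6.pdb` — crystal structure of the native substrate propeller
- `6qb8.cif` — deposited chaperonin–substrate complex model (with ADP)
- `mlst8_intralinks.csv` — the 8 substrate intramolecular cross-links
  from the study's source-data pLink output (any dialect the parser
  sniffs: flat Protein/Position columns or a pLink2 `Proteins` column)
- `equatorial_links.csv` — the 48 equatorial-domain cross-link subset
- `6qb8_chain_map.tsv` — protein -> chain/offset table for the complex
  (columns: protein, chains, offset)

Without them those four tests fail with a missing-input message; all
other tests are self-contained.
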