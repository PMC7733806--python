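# Deposited structures

The crystal-structure comparisons operate on the deposited PDB entries

- `3n8g` — wild-type SERCA1a, Ca2-E1 with AMPPCP
- `6rb2` — the E340A mutant, Ca2-E1 with AMPPCP
- `1t5t` — Ca2-E1 with ADP and AlF4- (phosphoryl-transfer transition-state mimic)
- `4h1w` — Mg-E1 (Ca2+-free) form

These entries are not redistributed with the package. Populate this
directory with `python scripts/fetch_structures.py` (network access to
files.rcsb.org required); the tests that need them report a clear failure
message when the files are absent.
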