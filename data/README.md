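# Optional reference data

The full-data reproduction test (`tests/test_acceptance.py::TestFullDataReproduction`)
expects the published 147-species x 28-locality Mediterranean amphipod
incidence matrix at

    data/incidence_147x28.tsv

in delimited-text form: species as rows, localities as columns, first column
species names, header row locality codes, cells 0/1.  The file is third-party
supplementary material and is not redistributed here; the test fails with an
explanatory message while it is absent.
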