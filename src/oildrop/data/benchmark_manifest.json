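{
  "description": "Benchmark units for the published RD survey of soluble, domain-swapped, ligand-binding and fibrillar proteins. Reference RD values are the printed ones; entries marked approximate have unit definitions reconstructed from figure captions and prose rather than stated residue lists. Structures are fetched on demand (report --fetch); nothing here is bundled.",
  "contact_cutoff": 5.0,
  "ligand": {"1A3N": "HEM"},
  "entries": [
    {"table": 1, "structure": "4UR4", "label": "complete chain", "unit": "A", "envelope_source": "self", "reference_rd": 0.289, "approximate": false},
    {"table": 1, "structure": "6JK4", "label": "complete chain", "unit": "A", "envelope_source": "self", "reference_rd": 0.489, "approximate": false},
    {"table": 1, "structure": "4UR6", "label": "dimer", "unit": "A+B", "envelope_source": "self", "reference_rd": 0.638, "approximate": false},
    {"table": 1, "structure": "4UR6", "label": "chain A", "unit": "A", "envelope_source": "self", "reference_rd": 0.298, "approximate": false},
    {"table": 1, "structure": "4UR6", "label": "chain B", "unit": "B", "envelope_source": "self", "reference_rd": 0.280, "approximate": false},
    {"table": 1, "structure": "1C8A", "label": "complete chain (two domains)", "unit": "A", "envelope_source": "self", "reference_rd": 0.659, "approximate": false},
    {"table": 1, "structure": "1C8A", "label": "Dom1", "unit": "A:1-54", "envelope_source": "self", "reference_rd": 0.293, "approximate": true, "note": "domains separated by the 55-72 linker loop; boundary reconstructed"},
    {"table": 1, "structure": "1C8A", "label": "Dom2", "unit": "A:73-134", "envelope_source": "self", "reference_rd": 0.280, "approximate": true, "note": "domains separated by the 55-72 linker loop; boundary reconstructed"},
    {"table": 2, "structure": "2CO2", "label": "pilin domain 48-170", "unit": "A:48-170", "envelope_source": "self", "reference_rd": 0.472, "approximate": true},
    {"table": 2, "structure": "2CO2", "label": "incorporated N-terminal 27-45", "unit": "B:27-45", "envelope_source": "self", "reference_rd": 0.725, "approximate": true},
    {"table": 2, "structure": "2CO2", "label": "complex", "unit": "A:48-170+B:27-45", "envelope_source": "self", "reference_rd": 0.456, "approximate": true},
    {"table": 2, "structure": "3CRF", "label": "chain A", "unit": "A", "envelope_source": "self", "reference_rd": 0.509, "approximate": false},
    {"table": 2, "structure": "3CRF", "label": "chain C", "unit": "C", "envelope_source": "self", "reference_rd": 0.731, "approximate": false},
    {"table": 2, "structure": "3CRF", "label": "complex A+C", "unit": "A+C", "envelope_source": "self", "reference_rd": 0.500, "approximate": false},
    {"table": 2, "structure": "2J6R", "label": "chain A", "unit": "A", "envelope_source": "self", "reference_rd": 0.669, "approximate": false},
    {"table": 2, "structure": "2J6R", "label": "chain A (no 24-31) with B (24-31)", "unit": null, "envelope_source": "self", "reference_rd": 0.662, "approximate": true, "note": "requires an exclusion selector; define manually from the deposited numbering"},
    {"table": 3, "structure": "1A3N", "label": "complex", "unit": "A+B+C+D", "envelope_source": "self", "reference_rd": 0.726, "approximate": false},
    {"table": 3, "structure": "1A3N", "label": "chain A (alpha, individual)", "unit": "A", "envelope_source": "self", "reference_rd": 0.506, "approximate": false, "partners": "B+C+D"},
    {"table": 3, "structure": "1A3N", "label": "chain B (beta, individual)", "unit": "B", "envelope_source": "self", "reference_rd": 0.427, "approximate": false, "partners": "A+C+D"},
    {"table": 4, "structure": "4QDS", "label": "dimer", "unit": "A+B", "envelope_source": "self", "reference_rd": 0.716, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain A in dimer", "unit": "A", "envelope_source": "parent", "parent": "A+B", "reference_rd": 0.702, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain B in dimer", "unit": "B", "envelope_source": "parent", "parent": "A+B", "reference_rd": 0.729, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain A individual 272-452", "unit": "A:272-452", "envelope_source": "self", "reference_rd": 0.614, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain B individual 272-452", "unit": "B:272-452", "envelope_source": "self", "reference_rd": 0.645, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain A individual 272-433", "unit": "A:272-433", "envelope_source": "self", "reference_rd": 0.510, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "chain B individual 272-433", "unit": "B:272-433", "envelope_source": "self", "reference_rd": 0.474, "approximate": false},
    {"table": 4, "structure": "4QDS", "label": "interface domain 434-451 A+B", "unit": "A:434-451+B:434-451", "envelope_source": "self", "reference_rd": 0.419, "approximate": false},
    {"table": 5, "structure": "1HPW", "label": "globular monomer", "unit": "A", "envelope_source": "self", "reference_rd": 0.422, "approximate": false, "fragments": "header"},
    {"table": 5, "structure": "2PIL", "label": "pilin monomer", "unit": "A", "envelope_source": "self", "reference_rd": 0.609, "approximate": false, "fragments": "header"},
    {"table": 5, "structure": "3J1R", "label": "filament complex", "unit": null, "envelope_source": "self", "reference_rd": 0.873, "approximate": true, "note": "all chains; enumerate from the deposited assembly"},
    {"table": 5, "structure": "5VXY", "label": "21-chain pilin complex", "unit": null, "envelope_source": "self", "reference_rd": 0.803, "approximate": true, "note": "all chains; enumerate from the deposited assembly"}
  ]
}
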