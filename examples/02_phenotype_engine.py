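"""Build a phenotype matrix from coded clinical events.

Uses a six-person hand-written event table to show the main phenotype types:
a phecode-style code group with control exclusions, a composite case/control
definition mixing hospital codes and prescriptions, a quantitative trait from
repeated primary-care measurements, a drug-response delta, and an
age-of-onset progression phenotype.
"""

from pathlib import Path

from phewaskit import core, phenotypes

HERE = Path(__file__).parent
GOLDEN = HERE.parent / "tests" / "data" / "golden"

participants = core.read_participants(str(GOLDEN / "participants.tsv"))
events = core.read_events(str(GOLDEN / "events.tsv"))
defs, code_sets = phenotypes.load_definitions(str(GOLDEN / "definitions.yaml"))
code_map = phenotypes.read_code_group_map(str(GOLDEN / "code_map.tsv"))

matrix, log = phenotypes.build_phenotype_matrix(
    defs, code_sets, code_map, events, participants,
    phenotypes.BuildOptions(code_group_min_count=2),
)

print("phenotype matrix (1=case, 0=control, NaN=missing/excluded):")
print(matrix.values.to_string())
print()
print("generation log:")
print(log.to_string(index=False))
print()
print("Notes: P3 is an asthma case, so the phecode convention removes them")
print("from the COPD control pool (NaN in CG_COPD); the composite CMP_RESP")
print("accepts either one hospital COPD code or two prescription events;")
print("CMP_RESP_ONSET is the age in years at the first qualifying event.")
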