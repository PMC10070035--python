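from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phewaskit import core, phenotypes, synth

GOLDEN = Path(__file__).parent / "data" / "golden"


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return GOLDEN


@pytest.fixture(scope="session")
def golden_inputs():
    participants = core.read_participants(str(GOLDEN / "participants.tsv"))
    events = core.read_events(str(GOLDEN / "events.tsv"))
    defs, code_sets = phenotypes.load_definitions(str(GOLDEN / "definitions.yaml"))
    code_map = phenotypes.read_code_group_map(str(GOLDEN / "code_map.tsv"))
    return participants, events, defs, code_sets, code_map


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-person synthetic cohort with two SNPs and one measured trait."""
    spec = synth.CohortSpec(
        n_participants=400,
        female_fraction=0.5,
        variants=[synth.VariantSpec("rs1", maf=0.3), synth.VariantSpec("rs2", maf=0.1)],
        event_templates=[synth.EventTemplate("J44.1", "ICD10", "hospital", rate=0.4)],
        measure_templates=[synth.MeasureTemplate("NA_BLOOD", 140.0, 3.0, visits=3)],
        seed=11,
    )
    return synth.generate_cohort(spec)


def binary_design(y, x, covars=None):
    """Shorthand for building a single-predictor design from arrays."""
    from phewaskit.association import build_design

    idx = pd.RangeIndex(len(y))
    cov = pd.DataFrame(covars, index=idx) if covars is not None else None
    return build_design(pd.Series(np.asarray(y, float), index=idx),
                        pd.DataFrame({"x": np.asarray(x, float)}, index=idx),
                        cov)
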