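import numpy as np
import pytest

from adattn.cohort import CohortTable
from adattn.schema import FeatureSchema, FeatureSpec, default_schema

_CAT_OF = {
    "G1_blood": "blood_chemistry",
    "G2_biochem": "biochemical",
    "G3_endocrine": "endocrine_immune",
    "G4_lifestyle": "lifestyle",
}


def make_schema(groups: dict[str, list[str]], direct: list[str] = ()) -> FeatureSchema:
    """Small ad-hoc schema: group → member names, plus DIRECT markers."""
    specs = [
        FeatureSpec(name, _CAT_OF[g], g, "continuous", (0.0, 1.0))
        for g, names in groups.items()
        for name in names
    ]
    specs += [FeatureSpec(n, "neurological", "DIRECT", "continuous", (0.0, 1.0)) for n in direct]
    return FeatureSchema(tuple(specs))


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def tiny_schema():
    return make_schema(
        {
            "G1_blood": ["a1", "a2", "a3"],
            "G2_biochem": ["b1", "b2"],
            "G3_endocrine": ["c1", "c2"],
            "G4_lifestyle": ["d1"],
        },
        direct=["B2MG", "MMSE"],
    )


def make_table(values, feature_names, mask=None, ids=None) -> CohortTable:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    if ids is None:
        ids = [f"P{i}" for i in range(values.shape[0])]
    return CohortTable(ids, list(feature_names), values, np.asarray(mask, dtype=bool))
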