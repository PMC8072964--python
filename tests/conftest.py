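import pytest

from flavorisk import (
    CompoundTable,
    ExposureParams,
    load_compound_table,
)
from flavorisk.core import Compound, Matrix


@pytest.fixture(scope="session")
def compounds() -> CompoundTable:
    return load_compound_table()


@pytest.fixture(scope="session")
def default_params() -> ExposureParams:
    return ExposureParams()


@pytest.fixture(scope="session")
def simple_compound() -> Compound:
    """A compound with round-number limits for hand-checkable censoring."""
    return Compound(
        name="Menthol",
        cas_rn="89-78-1",
        dnel_mg_per_m3=8.17,
        lod_ng_per_ml={m: 0.123 for m in Matrix},
        loq_ng_per_ml={m: 0.41 for m in Matrix},
    )


@pytest.fixture(scope="session")
def simple_table(simple_compound) -> CompoundTable:
    return CompoundTable([simple_compound])
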