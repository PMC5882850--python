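import pytest
from hypothesis import settings

from optoxr.construct import CodonUsageTable
from optoxr.fixtures import make_7tm, make_parent_chimera_set

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mouse_table():
    return CodonUsageTable.mouse()


@pytest.fixture(scope="session")
def truth_21_15():
    """Synthetic 7TM protein with uniform TM length 21 and loop length 15."""
    return make_7tm(3, tm_len_range=(21, 21), loop_len_range=(15, 15))


@pytest.fixture(scope="session")
def bundle():
    """Parent/chimera scaffold: backbone, target, full intracellular swap."""
    return make_parent_chimera_set(3)
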