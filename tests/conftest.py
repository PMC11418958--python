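import numpy as np
import pytest

from neuroglyc import fdg, synth
from neuroglyc import transport as tr


@pytest.fixture(scope="session")
def aif() -> fdg.ArterialInput:
    """Noise-free synthetic arterial input over 60 min."""
    return synth.gen_arterial_input()


@pytest.fixture(scope="session")
def frames() -> tuple[np.ndarray, np.ndarray]:
    """(starts, durations) of the 25-frame 60-min scheme, in minutes."""
    durations = np.asarray(synth.DEFAULT_FRAME_SCHEME)
    return synth._frame_starts(durations), durations


@pytest.fixture(scope="session")
def gray() -> tr.TissueModel:
    return tr.gray_matter()


@pytest.fixture(scope="session")
def gray_steady(gray) -> tr.SteadyStateResult:
    return tr.solve_steady_state(gray, tr.EUGLYCEMIA)
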