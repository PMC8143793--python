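import numpy as np
import pytest

from fibrosim import membrane as mb


@pytest.fixture(scope="session")
def limit_cycles():
    """Converged limit-cycle runs for the two remodeled variants (shared)."""
    out = {}
    for variant in ("afib", "fibrotic"):
        state, trace, info = mb.pace_to_limit_cycle(mb.make_model(variant))
        out[variant] = {"state": state, "trace": trace, "info": info}
    return out


@pytest.fixture(scope="session")
def strip_cvs():
    """Healthy-strip effective CVs at 200 um (shared by several tests)."""
    from fibrosim.reproduce import strip_cv

    return {"longitudinal": strip_cv("longitudinal"),
            "transverse": strip_cv("transverse")}
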