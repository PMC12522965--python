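import pytest

from icdcea.parameters import default_parameter_set


@pytest.fixture(scope="session")
def default_params():
    return default_parameter_set()


@pytest.fixture()
def zero_sd_params(default_params):
    """Defaults with every distribution degenerated to its mean."""
    ps = default_params
    for pid in list(ps.rows):
        spec = ps.rows[pid].spec
        if not spec.is_fixed:
            ps = ps.with_parameter(pid, spec.mean)
    return ps
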