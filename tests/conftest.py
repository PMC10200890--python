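import pytest

import karyoploid as kp


@pytest.fixture(scope="session")
def ack():
    return kp.build_ack()


@pytest.fixture(scope="session")
def post_wgd(ack):
    return kp.apply_wgd(ack)


@pytest.fixture(scope="session")
def catolobus():
    return kp.catolobus_karyotype()


@pytest.fixture(scope="session")
def catolobus_snapshots():
    return kp.replay(kp.catolobus_scenario())
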