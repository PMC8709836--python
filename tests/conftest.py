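import warnings

import pytest

from karyopool import fixtures


@pytest.fixture(scope="session")
def fx():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fixtures.load_fixtures(warn=False)


@pytest.fixture(scope="session")
def pool_by_arm(fx):
    from karyopool.bandmap import group_by_arm

    grouped = {
        arm: [m for m in maps if m.mapped]
        for arm, maps in group_by_arm(fx.pool).items()
    }
    return {arm: maps for arm, maps in grouped.items() if maps}
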