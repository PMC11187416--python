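import pytest

import mirferm as mf


@pytest.fixture(scope="session")
def glucose_template():
    return mf.default_template("glucose")


@pytest.fixture(scope="session")
def glutamate_template():
    return mf.default_template("glutamate")


@pytest.fixture(scope="session")
def default_controllers():
    return {
        "glucose": mf.ControllerConfig(),
        "glutamate": mf.ControllerConfig(),
    }


@pytest.fixture(scope="session")
def auto_runlog(default_controllers):
    """Noiseless 48-h fully automated run under the default plant."""
    return mf.run_closed_loop(
        mf.PlantParams(), mf.NOISELESS, default_controllers,
        mf.ControlRegime(mode="auto"), seed=3,
    )


@pytest.fixture(scope="session")
def regime_comparison(default_controllers):
    """Shared noiseless manual/semi/auto comparison (one plant, one seed)."""
    return mf.compare_regimes(
        mf.PlantParams(), mf.NOISELESS, default_controllers,
        regimes={
            "manual": mf.ControlRegime(mode="manual"),
            "semi": mf.ControlRegime(mode="semi"),
            "auto": mf.ControlRegime(mode="auto"),
        },
        seed=1,
    )
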