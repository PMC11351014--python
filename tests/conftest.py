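import pytest
from hypothesis import settings

from molregistry import Registry, SystemConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def registry(tmp_path):
    """A fresh default-configured registry in a temp directory."""
    return Registry.init(str(tmp_path / "reg.db"))


@pytest.fixture
def conformer_registry(tmp_path):
    """A fresh registry in registerConformers mode."""
    return Registry.init(
        str(tmp_path / "conf.db"), config=SystemConfig(register_conformers=True)
    )


@pytest.fixture
def charge_parent_registry(tmp_path):
    """A registry standardizing every submission to its charge parent."""
    return Registry.init(
        str(tmp_path / "cp.db"),
        config=SystemConfig(standardization=("sanitize", "charge_parent")),
    )
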