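import pytest

from trimersim import (
    calibrated_avidity,
    colon_median_system,
    enhanced_molecule,
    reference_molecule,
)


@pytest.fixture(scope="session")
def avidity_window() -> float:
    """Crosslinking avidity calibrated against the exposure-window anchor."""
    return calibrated_avidity("window-anchor")


@pytest.fixture(scope="session")
def avidity_tc() -> float:
    """Crosslinking avidity calibrated against the trimer-count anchor."""
    return calibrated_avidity("tc-anchor")


@pytest.fixture(scope="session")
def ref_mol(avidity_window):
    """Reference molecule (FAP KD 0.7 nM) at the window-anchored avidity."""
    return reference_molecule(avidity_window)


@pytest.fixture(scope="session")
def enh_mol(avidity_window):
    """10-fold enhanced FAP affinity (KD 0.07 nM), same avidity."""
    return enhanced_molecule(avidity_window)


@pytest.fixture(scope="session")
def colon_system():
    """In vitro well at the colon-median FAP with the dynamic 4-1BB pulse."""
    return colon_median_system()
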