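import pytest

from rltkit import biodist, synth
from rltkit.nuclide import lu177


@pytest.fixture(scope="session")
def nuc():
    """Packaged Lu-177 constants (T1/2 = 6.73 d = 161.52 h)."""
    return lu177()


@pytest.fixture(scope="session")
def zero_noise_table(nuc):
    """Zero-noise worksheets -> %IA/g table for the LNCaP preset, seed 42."""
    sheets = synth.simulate_worksheets(cfg=synth.SimulationConfig(seed=42))
    per_animal = [
        (w.nominal_time_h, biodist.percent_ia_per_gram(w, nuc)) for w in sheets
    ]
    return biodist.summarize(per_animal)
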