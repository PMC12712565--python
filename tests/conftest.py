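import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from notegate.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded synthetic corpus shared across tests."""
    cfg = SynthConfig(n_cases=3, notes_per_case=4, features_per_case=6, seed=7)
    notes, features, gold = generate_corpus(cfg)
    return cfg, notes, features, gold
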