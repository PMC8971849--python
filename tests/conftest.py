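import numpy as np
import pytest

from intronscan.model import StructuredAlignment
from intronscan.profiles import train, tstat
from intronscan.synth import FixtureSpec, make_model


@pytest.fixture
def toy_model():
    """Hand-written 3-element model: single strand, hairpin helix with a
    variable loop, single strand, separated by variable spacers."""
    tokens = "1 1 1 1 . . 2 2 2 . . . 2 2 2 . . 3 3 3 3".split()
    # rows built blockwise: 4 + 2 + 3 + 3 + 3 + 2 + 4 columns = 21
    rows = [
        ("s1", "GAUU" + "CA" + "GGC" + "AUG" + "GCC" + "UC" + "AGUA"),
        ("s2", "GAUU" + "C-" + "GGC" + "AU-" + "GCC" + "U-" + "AGUA"),
        ("s3", "GACU" + "-A" + "GGU" + "A--" + "GCC" + "UC" + "AGUA"),
        ("s4", "GAUU" + "CA" + "CGC" + "CUG" + "GCG" + "AC" + "AGAA"),
    ]
    return StructuredAlignment.from_sequences("toy", rows, tokens)


@pytest.fixture
def toy_profiles(toy_model):
    return train(toy_model, on_warning=lambda m: None)


@pytest.fixture
def toy_tstats(toy_model, toy_profiles):
    return tstat(toy_profiles, toy_model)


def small_spec(seed, **kw):
    """Desk-scale fixture spec used by the oracle-equivalence tests."""
    defaults = dict(
        seed=seed,
        layout=("ss", "helix", "ss"),
        pseudoknot=False,
        ss_len_range=(5, 8),
        helix_len_range=(4, 6),
        var_region_range=(2, 6),
        conservation=0.9,
        n_training=10,
        background_length=3000,
        name=f"fx{seed}",
    )
    defaults.update(kw)
    return FixtureSpec(**defaults)


@pytest.fixture
def fixture_model():
    spec = small_spec(42)
    model, pset = make_model(spec)
    return spec, model, pset
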