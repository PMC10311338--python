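import pytest

from adenpredict import synthgen


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """Toy profile HMM + threaded sequences + ground-truth signature table."""
    out = tmp_path_factory.mktemp("toyfix")
    return synthgen.generate_toy_profile_and_sequences(out, n_match_states=50, seed=3)


@pytest.fixture(scope="session")
def strong_motif_dataset():
    """8 balanced classes, 40/class, 12 motif positions at full strength."""
    spec = synthgen.SynthSpec.balanced(8, 40, n_motif=12, motif_strength=1.0, seed=7)
    return synthgen.generate(spec)


@pytest.fixture(scope="session")
def planted_blob_dataset():
    """10 tight, well-separated signature classes for clustering checks."""
    spec = synthgen.SynthSpec.balanced(
        10, 30, n_motif=34, motif_strength=0.9, seed=5
    )
    return synthgen.generate(spec)
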