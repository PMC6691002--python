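import warnings

import pytest

from nlrcensus import motifs, synthetic

warnings.filterwarnings("ignore", category=FutureWarning)

SEED = synthetic.DEFAULT_SEED


@pytest.fixture(scope="session")
def motif_defs():
    return motifs.load_motif_config()


@pytest.fixture(scope="session")
def clean_proteome():
    """Mutation-free synthetic proteome with all forms planted."""
    return synthetic.synth_proteome(
        n_per_category=12, mutation_rate=0.0, seed=SEED, n_atypical=6, n_decoys=6
    )


@pytest.fixture(scope="session")
def clean_signatures(clean_proteome, motif_defs):
    sigs = {}
    for rec in clean_proteome.records:
        sig = motifs.locate_nbarc(rec, motif_defs)
        if sig is not None:
            sigs[rec.id] = sig
    return sigs
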