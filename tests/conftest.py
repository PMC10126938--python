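import numpy as np
import pytest

import stlfl
from stlfl.epochs import EpochSet


@pytest.fixture(scope="session")
def rcp_paradigm():
    return stlfl.build_paradigm("RCP", 5, seed=7)


@pytest.fixture(scope="session")
def high_snr_rcp(rcp_paradigm):
    """A small, strongly separable matrix-speller session with its epochs."""
    cfg = stlfl.SyntheticConfig(seed=11, n_channels=12, fs=240.0,
                                n_characters=6, snr_db=10.0)
    session = stlfl.simulate_session(rcp_paradigm, cfg)
    epochs = stlfl.session_to_epochs(session, 0.667)
    return session, epochs


@pytest.fixture(scope="session")
def decimated_rcp(high_snr_rcp):
    """The high-SNR session's epochs after decimation to 40 Hz (T=26)."""
    from stlfl.preprocessing import decimate

    _, epochs = high_snr_rcp
    return decimate(epochs, 6)


def make_epochs(data, labels, fs=100.0, codes=None, chars=None, reps=None):
    """Assemble an EpochSet with default bookkeeping for unit tests."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        codes=np.ones(n, dtype=int) if codes is None else np.asarray(codes),
        char_index=np.zeros(n, dtype=int) if chars is None else np.asarray(chars),
        repetition_index=np.zeros(n, dtype=int) if reps is None else np.asarray(reps),
        fs=fs,
    )


@pytest.fixture
def toy_scalar_epochs():
    """1-channel, 1-sample epochs: class1 = {0, 2}, class2 = {4, 6}."""
    data = np.array([0.0, 2.0, 4.0, 6.0]).reshape(4, 1, 1)
    return make_epochs(data, [1, 1, 2, 2])


def random_schedule_epochs(rng, paradigm, n_characters):
    """Epoch bookkeeping (dummy data) for a valid flash schedule + truth."""
    codes_all, chars, reps, labels = [], [], [], []
    truth = [paradigm.alphabet[i]
             for i in rng.integers(0, len(paradigm.alphabet), n_characters)]
    for ci, symbol in enumerate(truth):
        tgt = set(paradigm.target_codes(symbol))
        for rep in range(paradigm.n_repetitions):
            for code in rng.permutation(paradigm.codes):
                codes_all.append(int(code))
                chars.append(ci)
                reps.append(rep)
                labels.append(1 if int(code) in tgt else 2)
    n = len(codes_all)
    ep = make_epochs(np.zeros((n, 1, 1)), labels, codes=codes_all,
                     chars=chars, reps=reps)
    return ep, truth
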