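import numpy as np
import pytest

from chemobarcode import Catalog, synthetic_signature_reference
from chemobarcode.catalogs import CHANNELS_96


@pytest.fixture(scope="session")
def reference():
    return synthetic_signature_reference()


def mixture_catalog(reference, weights: dict[str, float], n: int, rng=None) -> Catalog:
    """Multinomial catalog of size n drawn from a signature mixture.

    With rng=None the expected (noiseless, fractional) catalog is
    returned instead of a random draw.
    """
    w = np.zeros(reference.n_signatures)
    for name, value in weights.items():
        w[reference.names.index(name)] = value
    probs = reference.matrix @ (w / w.sum())
    if rng is None:
        return Catalog(CHANNELS_96, n * probs)
    return Catalog(CHANNELS_96, rng.multinomial(n, probs))
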